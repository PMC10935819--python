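"""Deterministic pixel-level refinement of predicted structure masks.

The chain mirrors how crisp document pages are cleaned up after a neural
mask prediction: binarize the page by its mean intensity, strip long
horizontal/vertical table lines with a Hough transform, dilate the ink so
atom-symbol glyphs join their bonds, flood mask coverage outward through
connected ink while deleting mask pixels with no ink support, drop regions
too small to be structures, and crop the survivors from the original page.

All masks are {0,1} uint8 arrays, coordinates are 0-based row-major and
bounding boxes half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import dilation as _sk_dilation
from skimage.transform import probabilistic_hough_line
from skimage.draw import line as _draw_line
from skimage.measure import label as _sk_label


@dataclass
class Region:
    """One connected component of a refined mask."""

    pixels: np.ndarray  # (n, 2) array of (row, col)
    bbox: tuple[int, int, int, int]  # half-open (row0, col0, row1, col1)
    pixel_count: int


@dataclass
class RefineConfig:
    min_region_px: int = 400          # at 512x512; scaled by area elsewhere
    ref_size: int = 512
    dilation_kernel_frac: float = 0.01  # square side = frac * max(H, W), min 3
    prob_threshold: float = 0.5
    connectivity: int = 8             # 4 or 8; 8 suits diagonal bond strokes
    hough_min_len_frac: float = 0.5   # min line length as fraction of page dim
    hough_line_gap: int = 3
    hough_angle_tol_deg: float = 2.0
    line_clear_width: int = 3
    crop_pad: int = 4

    def __post_init__(self):
        if self.min_region_px <= 0:
            raise ValueError("min_region_px must be positive")
        if not (0 < self.prob_threshold < 1):
            raise ValueError("prob_threshold must lie in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def _label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    return _sk_label(mask > 0, connectivity=1 if connectivity == 4 else 2)


def _as_binary(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask must contain only 0/1 values")
    return arr.astype(np.uint8)


# ------------------------------------------------------------------ basics

def binarize_image(gray_page: np.ndarray) -> np.ndarray:
    """Ink map: 1 where the pixel is darker than the page mean.

    The adaptive mean threshold suppresses non-white backgrounds and light
    scan artifacts. A constant page yields an all-zero ink map.
    """
    page = np.asarray(gray_page, dtype=np.float64)
    if page.ndim != 2:
        raise ValueError("binarize_image expects a single-channel page")
    return (page < page.mean()).astype(np.uint8)


def threshold_prob_mask(prob_map: np.ndarray, cfg: RefineConfig) -> np.ndarray:
    """Binarize a foreground-probability map; probability ties keep the pixel."""
    prob = np.asarray(prob_map, dtype=np.float64)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    return (prob >= cfg.prob_threshold).astype(np.uint8)


def dilation_kernel_side(shape: tuple[int, int], cfg: RefineConfig) -> int:
    return max(3, round(cfg.dilation_kernel_frac * max(shape)))


def dilate_mask(mask: np.ndarray, cfg: RefineConfig) -> np.ndarray:
    """Square dilation with a kernel scaled to the image size (5 px at 512)."""
    mask = _as_binary(mask)
    side = dilation_kernel_side(mask.shape, cfg)
    return _sk_dilation(mask, np.ones((side, side), dtype=bool)).astype(np.uint8)


# ------------------------------------------------------------- line removal

def remove_straight_lines(mask: np.ndarray, cfg: RefineConfig) -> np.ndarray:
    """Erase long straight horizontal/vertical lines (table rules).

    A probabilistic Hough transform restricted to angles within
    ``hough_angle_tol_deg`` of 0/90 degrees finds segments at least
    ``hough_min_len_frac`` of the matching page dimension long; pixels in a
    thin band along each detected segment are cleared. Diagonal strokes are
    never targeted. No-op when nothing is detected.
    """
    mask = _as_binary(mask)
    if mask.sum() == 0:
        return mask.copy()
    h, w = mask.shape
    tol = np.deg2rad(cfg.hough_angle_tol_deg)
    # skimage's theta is the angle of the line's normal: 0 -> vertical line,
    # pi/2 -> horizontal line
    thetas = np.concatenate(
        [np.linspace(-tol, tol, 7), np.linspace(np.pi / 2 - tol, np.pi / 2 + tol, 7)]
    )
    min_len = int(round(cfg.hough_min_len_frac * min(h, w)))
    segments = probabilistic_hough_line(
        mask.astype(bool), threshold=10, line_length=min_len,
        line_gap=cfg.hough_line_gap, theta=thetas, rng=0,
    )
    out = mask.copy()
    half = cfg.line_clear_width // 2
    for (c0, r0), (c1, r1) in segments:
        dr, dc = abs(r1 - r0), abs(c1 - c0)
        horizontal = dc >= dr
        span = dc if horizontal else dr
        dim = w if horizontal else h
        if span + 1 < int(round(cfg.hough_min_len_frac * dim)):
            continue
        rr, cc = _draw_line(r0, c0, r1, c1)
        for off in range(-half, half + 1):
            if horizontal:
                r_off = np.clip(rr + off, 0, h - 1)
                out[r_off, cc] = 0
            else:
                c_off = np.clip(cc + off, 0, w - 1)
                out[rr, c_off] = 0
    return out


# ------------------------------------------------------- flood-fill update

def update_mask(ink: np.ndarray, seed_mask: np.ndarray, cfg: RefineConfig) -> np.ndarray:
    """Grow and shrink a seed mask against the page's ink.

    From every seed pixel the neighbour search collects adjacent ink pixels
    until non-ink is reached, which amounts to: keep exactly the ink
    connected components (at ``cfg.connectivity``) that the seed touches.
    Seed pixels lying on background are deleted. Idempotent.
    """
    ink = _as_binary(ink)
    seed = _as_binary(seed_mask)
    if ink.shape != seed.shape:
        raise ValueError("ink and seed mask shapes differ")
    labels = _label(ink, cfg.connectivity)
    touched = np.unique(labels[seed > 0])
    touched = touched[touched != 0]
    if touched.size == 0:
        return np.zeros_like(ink)
    return np.isin(labels, touched).astype(np.uint8)


def scaled_min_region(shape: tuple[int, int], cfg: RefineConfig) -> int:
    """Small-structure threshold, area-scaled from the 512x512 anchor."""
    h, w = shape
    return int(round(cfg.min_region_px * (h * w) / (cfg.ref_size**2)))


def filter_small_regions(mask: np.ndarray, cfg: RefineConfig) -> np.ndarray:
    """Remove connected components smaller than the scaled pixel threshold.

    Components at exactly the threshold are retained. Idempotent.
    """
    mask = _as_binary(mask)
    labels = _label(mask, cfg.connectivity)
    if labels.max() == 0:
        return np.zeros_like(mask)
    counts = np.bincount(labels.ravel())
    keep = counts >= scaled_min_region(mask.shape, cfg)
    keep[0] = False
    return keep[labels].astype(np.uint8)


# ---------------------------------------------------------------- regions

def extract_regions(
    mask: np.ndarray, cfg: RefineConfig, grouping: np.ndarray | None = None
) -> list[Region]:
    """Maximal connected components of a mask, sorted by (row0, col0).

    ``grouping`` optionally supplies an alternative label image (same shape)
    used to group mask pixels into entities — the pipeline passes dilated-ink
    labels here so an atom symbol detached from its bond stays in the same
    region as the rest of the structure.
    """
    mask = _as_binary(mask)
    labels = grouping if grouping is not None else _label(mask, cfg.connectivity)
    if labels.shape != mask.shape:
        raise ValueError("grouping labels shape differs from mask")
    regions: list[Region] = []
    ids = np.unique(labels[mask > 0])
    for lab in ids[ids != 0]:
        sel = (labels == lab) & (mask > 0)
        rows, cols = np.nonzero(sel)
        if rows.size == 0:
            continue
        regions.append(
            Region(
                pixels=np.column_stack([rows, cols]),
                bbox=(int(rows.min()), int(cols.min()),
                      int(rows.max()) + 1, int(cols.max()) + 1),
                pixel_count=int(rows.size),
            )
        )
    regions.sort(key=lambda r: (r.bbox[0], r.bbox[1]))
    return regions


def crop_structures(
    original_page: np.ndarray,
    regions: list[Region],
    cfg: RefineConfig,
    mask_shape: tuple[int, int] | None = None,
) -> list[np.ndarray]:
    """Crop each region's padded bbox from the original page (colors kept).

    When the mask was computed at a different resolution than the page,
    ``mask_shape`` triggers scaling of region coordinates back to page
    resolution. Crops are clipped to the page bounds.
    """
    page = np.asarray(original_page)
    ph, pw = page.shape[:2]
    sy = sx = 1.0
    if mask_shape is not None and tuple(mask_shape) != (ph, pw):
        sy = ph / mask_shape[0]
        sx = pw / mask_shape[1]
    crops = []
    for reg in regions:
        r0, c0, r1, c1 = reg.bbox
        r0 = max(0, int(np.floor(r0 * sy)) - cfg.crop_pad)
        c0 = max(0, int(np.floor(c0 * sx)) - cfg.crop_pad)
        r1 = min(ph, int(np.ceil(r1 * sy)) + cfg.crop_pad)
        c1 = min(pw, int(np.ceil(c1 * sx)) + cfg.crop_pad)
        crops.append(page[r0:r1, c0:c1].copy())
    return crops


# ----------------------------------------------------------- full pipeline

@dataclass
class RefinedMask:
    mask: np.ndarray                 # ink-supported refined mask
    regions: list[Region]            # grouped entities, post size filter
    ink: np.ndarray                  # line-free binarized page ink
    grouping: np.ndarray             # dilated-ink labels used for grouping


def refine_mask(
    gray_page: np.ndarray, prob_map: np.ndarray, cfg: RefineConfig | None = None
) -> RefinedMask:
    """Full refinement of one page's predicted probability map.

    Steps: binarize page -> remove table lines from ink -> threshold and
    line-clean the predicted mask -> dilate both (the ink dilation closes
    gaps between atom symbols and bonds) -> keep dilated-ink components
    touched by the seed -> trim the grown mask back to true ink -> drop
    entities below the scaled 400-px threshold.
    """
    cfg = cfg or RefineConfig()
    ink = binarize_image(gray_page)
    ink = remove_straight_lines(ink, cfg)
    seed = threshold_prob_mask(prob_map, cfg)
    seed = remove_straight_lines(seed, cfg)
    seed = dilate_mask(seed, cfg)
    ink_d = dilate_mask(ink, cfg)
    grown = update_mask(ink_d, seed, cfg)
    refined = (grown & ink).astype(np.uint8)
    grouping = _label(ink_d, cfg.connectivity)
    regions = [
        r for r in extract_regions(refined, cfg, grouping=grouping)
        if r.pixel_count >= scaled_min_region(refined.shape, cfg)
    ]
    keep = np.zeros_like(refined)
    for r in regions:
        keep[r.pixels[:, 0], r.pixels[:, 1]] = 1
    return RefinedMask(mask=keep, regions=regions, ink=ink, grouping=grouping)


def random_erode(mask: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Delete a random fraction of mask pixels (used to stress recovery)."""
    mask = _as_binary(mask)
    rows, cols = np.nonzero(mask)
    n_drop = int(round(fraction * rows.size))
    if n_drop == 0:
        return mask.copy()
    drop = rng.choice(rows.size, size=n_drop, replace=False)
    out = mask.copy()
    out[rows[drop], cols[drop]] = 0
    return out
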