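"""Synthetic document-page generation with pixel-exact structure masks.

Pages emulate patent/journal layouts: 1-6 individually placed drug-like
molecules (15-28 heavy atoms) or one dense multi-molecule cluster (250-300
total atoms, hydrogens included), optional non-molecular negative figures,
optional table-style grid lines around structures, and paragraph-like text
decoration. Depictions are drawn with RDKit, randomly rotated within 0-30
degrees, and composited onto white-background pages. The companion mask is 1
exactly at molecule ink pixels; negatives, grids and text never enter it.

Composited ink is clamped to intensity <= INK_CLAMP so that the ground-truth
mask coincides with a mean-threshold binarization of the page (crisp printed
documents rather than noisy scans; see the methods note).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from rdkit import Chem
from rdkit.Chem.Draw import rdMolDraw2D
from skimage.transform import rotate as _sk_rotate

from .library import MoleculeSpec, annotate_smiles, load_library

# ink pixels are composited at intensity <= INK_CLAMP; pixels lighter than
# BACKGROUND_THRESHOLD in a raw RDKit render count as background
INK_CLAMP = 200
BACKGROUND_THRESHOLD = 250


class SynthesisError(RuntimeError):
    pass


class NoEligibleMoleculesError(SynthesisError):
    """Raised when library filtering leaves nothing to draw from."""


class PlacementError(SynthesisError):
    def __init__(self, asset_id: str):
        super().__init__(f"could not place asset {asset_id!r} without overlap")
        self.asset_id = asset_id


class DepictionError(SynthesisError):
    def __init__(self, molecule_id: str, reason: str):
        super().__init__(f"failed to depict molecule {molecule_id!r}: {reason}")
        self.molecule_id = molecule_id


@dataclass
class RenderedDepiction:
    """A rendered structure bitmap with its exact ink mask.

    ``bitmap`` is grayscale uint8 with white (255) background; ``ink_mask``
    is a same-shape {0,1} array marking depiction pixels. ``angle`` is the
    rotation already applied, in degrees.
    """

    bitmap: np.ndarray
    ink_mask: np.ndarray
    angle: float = 0.0
    line_thickness: int = 1
    asset_id: str = ""

    def __post_init__(self):
        if self.bitmap.shape != self.ink_mask.shape:
            raise ValueError("bitmap and ink_mask shapes differ")


@dataclass
class Placement:
    asset_id: str
    kind: str  # molecule | negative | gridline
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    has_grid: bool = False
    angle: float = 0.0
    pixel_count: int = 0


@dataclass
class PageMaskPair:
    page: np.ndarray  # uint8 grayscale
    mask: np.ndarray  # uint8 {0,1}
    placements: list[Placement]
    seed: int
    route: str = "single"
    # per-molecule pasted ink, [(paste_row0, paste_col0, ink_array), ...];
    # lets callers verify mask == union of molecule ink exactly
    molecule_inks: list[tuple[int, int, np.ndarray]] = field(default_factory=list)


@dataclass
class SynthesisConfig:
    """Generator conditions. Atom-count, placement-count and rotation bounds
    follow the study conditions; geometry knobs (margins, canvas scale,
    decoration probabilities) are the generator's own defaults."""

    n_pages: int = 10
    min_heavy: int = 15
    max_heavy: int = 28
    min_cluster_atoms: int = 250
    max_cluster_atoms: int = 300
    max_mols_per_page: int = 6
    max_rotation_deg: float = 30.0
    thickness_range: tuple[int, int] = (1, 3)
    grid_prob: float = 0.3
    negative_prob: float = 0.5
    cluster_prob: float = 0.15
    text_prob: float = 0.6
    page_size: tuple[int, int] = (512, 512)
    margin: int = 10  # clearance enforced between placed assets, px
    grid_pad: int = 6  # gap between a structure bbox and its grid rectangle
    single_canvas_base: int = 170  # render canvas = base + canvas_per_heavy*heavy
    canvas_per_heavy: int = 3
    cluster_frag_base: int = 110     # render canvas base for cluster fragments
    cluster_frag_per_heavy: int = 2
    cluster_spacing: int = 8  # gap between packed cluster fragments, px
    min_ink_px: int = 520     # re-render small depictions until this many ink px
    max_place_tries: int = 120
    base_page_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.min_heavy > self.max_heavy:
            raise ValueError("empty heavy-atom range")
        if self.min_cluster_atoms > self.max_cluster_atoms:
            raise ValueError("empty cluster atom range")
        if self.thickness_range[0] > self.thickness_range[1]:
            raise ValueError("empty thickness range")
        if min(self.page_size) < 512:
            raise ValueError("page_size must be at least 512 in each dimension")
        if not (1 <= self.max_mols_per_page):
            raise ValueError("max_mols_per_page must be >= 1")
        if not (0 <= self.max_rotation_deg <= 360):
            raise ValueError("max_rotation_deg out of range")


# ---------------------------------------------------------------- selection

def select_single_molecules(
    library: list[MoleculeSpec],
    cfg: SynthesisConfig,
    rng: np.random.Generator,
    n: int | None = None,
) -> list[MoleculeSpec]:
    """Sample molecules for one page, without replacement.

    Eligible records are single-fragment molecules whose heavy-atom count
    lies in ``[cfg.min_heavy, cfg.max_heavy]``. When ``n`` is omitted the
    per-page count is drawn uniformly from 1..max_mols_per_page.
    """
    if not library:
        raise ValueError("molecule library is empty")
    eligible = [
        m
        for m in library
        if not m.is_multi_fragment and cfg.min_heavy <= m.heavy_atoms <= cfg.max_heavy
    ]
    if not eligible:
        raise NoEligibleMoleculesError(
            f"no eligible molecules with {cfg.min_heavy} <= heavy atoms <= {cfg.max_heavy}"
        )
    if n is None:
        n = int(rng.integers(1, cfg.max_mols_per_page + 1))
    n = min(n, len(eligible))
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in idx]


def select_cluster_record(
    library: list[MoleculeSpec], cfg: SynthesisConfig, rng: np.random.Generator
) -> MoleculeSpec:
    """Pick one multi-fragment cluster record with total atom count
    (hydrogens included) in ``[cfg.min_cluster_atoms, cfg.max_cluster_atoms]``."""
    eligible = [
        m
        for m in library
        if m.is_multi_fragment
        and cfg.min_cluster_atoms <= m.total_atoms <= cfg.max_cluster_atoms
    ]
    if not eligible:
        raise NoEligibleMoleculesError(
            "no eligible cluster records with total atoms in "
            f"[{cfg.min_cluster_atoms}, {cfg.max_cluster_atoms}]"
        )
    return eligible[int(rng.integers(len(eligible)))]


# ---------------------------------------------------------------- rendering

def _tight_crop(bitmap: np.ndarray, ink: np.ndarray, pad: int = 3):
    rows = np.any(ink, axis=1)
    cols = np.any(ink, axis=0)
    if not rows.any():
        return bitmap, ink
    r0, r1 = np.where(rows)[0][[0, -1]]
    c0, c1 = np.where(cols)[0][[0, -1]]
    r0 = max(0, r0 - pad)
    c0 = max(0, c0 - pad)
    r1 = min(bitmap.shape[0], r1 + 1 + pad)
    c1 = min(bitmap.shape[1], c1 + 1 + pad)
    return bitmap[r0:r1, c0:c1], ink[r0:r1, c0:c1]


def render_depiction(
    mol: MoleculeSpec,
    thickness: int,
    rng: np.random.Generator | None = None,
    canvas: int | None = None,
    cfg: SynthesisConfig | None = None,
) -> RenderedDepiction:
    """Draw a molecule with RDKit at the requested bond line thickness.

    The bitmap is cropped tight to its ink (plus a small pad), composited on
    white, and ink intensities are clamped to <= INK_CLAMP so pages binarize
    exactly. Multi-fragment records draw all fragments on one shared canvas,
    mimicking clustered structures.
    """
    cfg = cfg or SynthesisConfig()
    if canvas is None:
        if mol.is_multi_fragment:
            canvas = 352  # whole-record draw; fragments share one canvas
        else:
            canvas = cfg.single_canvas_base + cfg.canvas_per_heavy * mol.heavy_atoms
    try:
        rdmol = mol.to_mol()
        drawer = rdMolDraw2D.MolDraw2DCairo(canvas, canvas)
        opts = drawer.drawOptions()
        opts.bondLineWidth = int(thickness)
        rdMolDraw2D.PrepareAndDrawMolecule(drawer, rdmol)
        drawer.FinishDrawing()
        png = drawer.GetDrawingText()
    except Exception as exc:  # RDKit raises a zoo of types
        raise DepictionError(mol.id, str(exc)) from exc
    bitmap = np.array(Image.open(io.BytesIO(png)).convert("L"), dtype=np.uint8)
    ink = (bitmap < BACKGROUND_THRESHOLD).astype(np.uint8)
    if ink.sum() == 0:
        raise DepictionError(mol.id, "render produced no ink pixels")
    bitmap = np.where(ink > 0, np.minimum(bitmap, INK_CLAMP), 255).astype(np.uint8)
    bitmap, ink = _tight_crop(bitmap, ink)
    return RenderedDepiction(
        bitmap=bitmap, ink_mask=ink, angle=0.0, line_thickness=int(thickness),
        asset_id=mol.id,
    )


def rotate_depiction(dep: RenderedDepiction, angle: float) -> RenderedDepiction:
    """Rotate a depiction and its ink mask by the same transform.

    Bitmap uses bilinear resampling, the ink mask nearest-neighbour (so it
    stays binary); the canvas grows to hold the rotated content and is filled
    with white. Angles outside [0, 30] degrees are rejected.
    """
    if not (0.0 <= angle <= 30.0):
        raise ValueError(f"rotation angle {angle} outside [0, 30] degrees")
    if angle == 0.0:
        return RenderedDepiction(
            bitmap=dep.bitmap.copy(), ink_mask=dep.ink_mask.copy(), angle=0.0,
            line_thickness=dep.line_thickness, asset_id=dep.asset_id,
        )
    ink = _sk_rotate(
        dep.ink_mask.astype(float), angle, resize=True, order=0, cval=0.0,
        preserve_range=True,
    )
    ink = (ink > 0.5).astype(np.uint8)
    bitmap = _sk_rotate(
        dep.bitmap.astype(float), angle, resize=True, order=1, cval=255.0,
        preserve_range=True,
    )
    # keep the composited convention: ink dark, everything else pure white
    bitmap = np.where(ink > 0, np.minimum(bitmap, INK_CLAMP), 255.0)
    bitmap, ink = _tight_crop(bitmap.astype(np.uint8), ink)
    return RenderedDepiction(
        bitmap=bitmap, ink_mask=ink, angle=float(angle),
        line_thickness=dep.line_thickness, asset_id=dep.asset_id,
    )


# ------------------------------------------------------- negatives and text

def render_negative(rng: np.random.Generator, size: int = 110) -> RenderedDepiction:
    """Synthesize a small non-molecular figure (bar chart, scatter, or blob).

    These stand in for scraped negative figures from patents and papers; they
    appear on pages but never in masks.
    """
    bitmap = np.full((size, size), 255, dtype=np.uint8)
    style = int(rng.integers(3))
    if style == 0:  # bar chart with axes
        bitmap[-8:-6, 6:-6] = 40
        bitmap[6:-6, 6:8] = 40
        nbars = int(rng.integers(3, 7))
        width = (size - 24) // nbars
        for b in range(nbars):
            h = int(rng.integers(size // 5, size - 20))
            c0 = 12 + b * width
            bitmap[-8 - h : -8, c0 : c0 + max(3, width - 4)] = 90
    elif style == 1:  # scatter of dots
        for _ in range(int(rng.integers(25, 60))):
            r = int(rng.integers(4, size - 4))
            c = int(rng.integers(4, size - 4))
            bitmap[r - 2 : r + 2, c - 2 : c + 2] = 60
    else:  # filled blob (western-blot-like band)
        r0 = int(rng.integers(size // 4, size // 2))
        h = int(rng.integers(8, size // 4))
        c0 = int(rng.integers(4, size // 3))
        w = int(rng.integers(size // 3, size - c0 - 4))
        bitmap[r0 : r0 + h, c0 : c0 + w] = 80
    ink = (bitmap < BACKGROUND_THRESHOLD).astype(np.uint8)
    bitmap, ink = _tight_crop(bitmap, ink)
    return RenderedDepiction(bitmap=bitmap, ink_mask=ink, asset_id="negative")


def render_text_block(rng: np.random.Generator, cfg: SynthesisConfig) -> RenderedDepiction:
    """Paragraph-like decoration: rows of short dark runs standing in for
    body text. Placed on pages as a non-molecular asset, never in masks."""
    h, w = cfg.page_size
    bh = int(rng.integers(30, 90))
    bw = int(rng.integers(w // 3, w - 60))
    block = np.full((bh, bw), 255, dtype=np.uint8)
    r = 0
    while r < bh - 3:
        c = 0
        while c < bw - 8:
            run = min(int(rng.integers(8, 30)), bw - c)
            block[r : r + 3, c : c + run] = int(rng.integers(40, 120))
            c += run + int(rng.integers(4, 10))
        r += 8
    ink = (block < BACKGROUND_THRESHOLD).astype(np.uint8)
    return RenderedDepiction(bitmap=block, ink_mask=ink, asset_id="text")


def make_base_page(cfg: SynthesisConfig, rng: np.random.Generator) -> np.ndarray:
    """Molecule-free base page: a user-supplied scan when ``base_page_dir``
    is set, a plain white page otherwise. Structures are only placed on
    all-white areas of it."""
    h, w = cfg.page_size
    if cfg.base_page_dir:
        candidates = sorted(
            q for q in Path(cfg.base_page_dir).iterdir()
            if q.suffix.lower() in {".png", ".jpg", ".jpeg"}
        )
        if candidates:
            pick = candidates[int(rng.integers(len(candidates)))]
            img = Image.open(pick).convert("L").resize((w, h))
            return np.array(img, dtype=np.uint8)
    return np.full((h, w), 255, dtype=np.uint8)


def _render_sized(
    mol: MoleculeSpec, thickness: int, cfg: SynthesisConfig,
    base_canvas: int | None = None,
) -> RenderedDepiction:
    """Render, bumping thickness/canvas until the depiction carries at least
    ``cfg.min_ink_px`` ink pixels (small fragments would otherwise fall under
    the small-structure filter threshold downstream)."""
    if base_canvas is None:
        base_canvas = cfg.single_canvas_base + cfg.canvas_per_heavy * mol.heavy_atoms
    canvas = base_canvas
    for attempt in range(4):
        dep = render_depiction(mol, thickness, cfg=cfg, canvas=canvas)
        if int(dep.ink_mask.sum()) >= cfg.min_ink_px:
            return dep
        thickness += 1
        canvas = int(base_canvas * (1.2 ** (attempt + 1)))
    return dep


@dataclass
class _Packed:
    """A packed cluster composite plus per-fragment relative placements."""

    dep: RenderedDepiction
    sub: list[Placement]  # bboxes relative to composite origin


def pack_cluster(
    fragments: list[RenderedDepiction], spacing: int, cluster_id: str
) -> _Packed:
    """Shelf-pack fragment depictions into one composite with small gaps,
    mimicking a multi-molecule cluster drawn with fragment coordinates in
    close proximity."""
    order = sorted(range(len(fragments)), key=lambda i: -fragments[i].bitmap.shape[0])
    total_area = sum(f.bitmap.shape[0] * f.bitmap.shape[1] for f in fragments)
    target_w = max(
        int(np.sqrt(total_area) * 1.3),
        max(f.bitmap.shape[1] for f in fragments) + spacing,
    )
    shelves: list[list[int]] = [[]]
    shelf_w = [0]
    for i in order:
        w = fragments[i].bitmap.shape[1]
        if shelf_w[-1] + w + spacing > target_w and shelves[-1]:
            shelves.append([])
            shelf_w.append(0)
        shelves[-1].append(i)
        shelf_w[-1] += w + spacing
    height = sum(
        max(fragments[i].bitmap.shape[0] for i in shelf) + spacing for shelf in shelves
    )
    width = max(shelf_w)
    bitmap = np.full((height, width), 255, dtype=np.uint8)
    ink = np.zeros((height, width), dtype=np.uint8)
    sub: list[Placement] = []
    r = 0
    for shelf in shelves:
        c = 0
        shelf_h = max(fragments[i].bitmap.shape[0] for i in shelf)
        for i in shelf:
            f = fragments[i]
            fh, fw = f.bitmap.shape
            bitmap[r : r + fh, c : c + fw] = np.minimum(
                bitmap[r : r + fh, c : c + fw], f.bitmap
            )
            ink[r : r + fh, c : c + fw] |= f.ink_mask
            rows, cols = np.nonzero(f.ink_mask)
            sub.append(
                Placement(
                    asset_id=f"{cluster_id}#{i}", kind="molecule",
                    bbox=(r + int(rows.min()), c + int(cols.min()),
                          r + int(rows.max()) + 1, c + int(cols.max()) + 1),
                    angle=f.angle, pixel_count=int(f.ink_mask.sum()),
                )
            )
            c += fw + spacing
        r += shelf_h + spacing
    comp_bitmap, comp_ink = bitmap, ink
    composite = RenderedDepiction(
        bitmap=comp_bitmap, ink_mask=comp_ink, asset_id=cluster_id
    )
    return _Packed(dep=composite, sub=sub)


# -------------------------------------------------------------- composition

def _boxes_clash(a, b, margin):
    ar0, ac0, ar1, ac1 = a
    br0, bc0, br1, bc1 = b
    return not (
        ar1 + margin <= br0 or br1 + margin <= ar0
        or ac1 + margin <= bc0 or bc1 + margin <= ac0
    )


def compose_page(
    base_page: np.ndarray,
    assets: list[tuple[str, RenderedDepiction]],
    cfg: SynthesisConfig,
    rng: np.random.Generator,
) -> PageMaskPair:
    """Place assets on a molecule-free page and build the exact mask.

    ``assets`` is a list of (kind, depiction) with kind "molecule" or
    "negative". Placement is rejection sampling: a paste rectangle must lie
    on an all-white page area and keep ``cfg.margin`` px clearance from every
    earlier asset. Molecule ink enters the mask; negatives and grid lines do
    not. Raises :class:`PlacementError` naming the first asset that cannot be
    placed.
    """
    page = base_page.copy()
    h, w = page.shape
    mask = np.zeros_like(page, dtype=np.uint8)
    placements: list[Placement] = []
    paste_boxes: list[tuple[int, int, int, int]] = []
    molecule_inks: list[tuple[int, int, np.ndarray]] = []

    for asset in assets:
        kind, dep, *rest = asset
        sub = rest[0] if rest else None
        dh, dw = dep.bitmap.shape
        if dh > h or dw > w:
            raise PlacementError(dep.asset_id)
        placed = False
        for _ in range(cfg.max_place_tries):
            r0 = int(rng.integers(0, h - dh + 1))
            c0 = int(rng.integers(0, w - dw + 1))
            box = (r0, c0, r0 + dh, c0 + dw)
            if any(_boxes_clash(box, other, cfg.margin) for other in paste_boxes):
                continue
            gp = cfg.grid_pad + 3  # reserve room for an eventual grid rectangle
            rr0, cc0 = max(0, r0 - gp), max(0, c0 - gp)
            rr1, cc1 = min(h, r0 + dh + gp), min(w, c0 + dw + gp)
            if not np.all(base_page[rr0:rr1, cc0:cc1] == 255):
                continue
            placed = True
            break
        if not placed:
            raise PlacementError(dep.asset_id)

        region = page[r0 : r0 + dh, c0 : c0 + dw]
        page[r0 : r0 + dh, c0 : c0 + dw] = np.minimum(region, dep.bitmap)
        ink_rows, ink_cols = np.nonzero(dep.ink_mask)
        tight = (
            r0 + int(ink_rows.min()), c0 + int(ink_cols.min()),
            r0 + int(ink_rows.max()) + 1, c0 + int(ink_cols.max()) + 1,
        )
        has_grid = False
        if kind == "molecule":
            mask[r0 : r0 + dh, c0 : c0 + dw] |= dep.ink_mask
            molecule_inks.append((r0, c0, dep.ink_mask.copy()))
            if sub is None and rng.random() < cfg.grid_prob:
                has_grid = True
                _draw_grid(page, tight, cfg, rng)
        if sub is not None:
            for sp in sub:
                placements.append(
                    Placement(
                        asset_id=sp.asset_id, kind=sp.kind,
                        bbox=(r0 + sp.bbox[0], c0 + sp.bbox[1],
                              r0 + sp.bbox[2], c0 + sp.bbox[3]),
                        angle=sp.angle, pixel_count=sp.pixel_count,
                    )
                )
        else:
            placements.append(
                Placement(
                    asset_id=dep.asset_id, kind=kind, bbox=tight, has_grid=has_grid,
                    angle=dep.angle, pixel_count=int(dep.ink_mask.sum()),
                )
            )
        paste_boxes.append(box)

    return PageMaskPair(
        page=page, mask=mask, placements=placements, seed=-1,
        molecule_inks=molecule_inks,
    )


def _draw_grid(page: np.ndarray, bbox, cfg: SynthesisConfig, rng) -> None:
    """Table-style grid rectangle around a structure's padded bbox, 1-2 px."""
    h, w = page.shape
    width = int(rng.integers(1, 3))
    r0 = max(0, bbox[0] - cfg.grid_pad - width)
    c0 = max(0, bbox[1] - cfg.grid_pad - width)
    r1 = min(h, bbox[2] + cfg.grid_pad + width)
    c1 = min(w, bbox[3] + cfg.grid_pad + width)
    page[r0 : r0 + width, c0:c1] = 0
    page[r1 - width : r1, c0:c1] = 0
    page[r0:r1, c0 : c0 + width] = 0
    page[r0:r1, c1 - width : c1] = 0


# ----------------------------------------------------------------- dataset

def synthesize_pages(
    cfg: SynthesisConfig, library: list[MoleculeSpec] | None = None
):
    """Yield ``cfg.n_pages`` deterministic :class:`PageMaskPair` objects."""
    cfg.validate()
    library = library if library is not None else load_library()
    rng = np.random.default_rng(cfg.seed)
    for page_idx in range(cfg.n_pages):
        page_seed = int(rng.integers(2**31))
        yield _synthesize_one(cfg, library, page_seed)


def _synthesize_one(
    cfg: SynthesisConfig, library: list[MoleculeSpec], page_seed: int
) -> PageMaskPair:
    rng = np.random.default_rng(page_seed)
    route = "cluster" if rng.random() < cfg.cluster_prob else "single"
    base = make_base_page(cfg, rng)
    assets: list[tuple[str, RenderedDepiction]] = []
    tmin, tmax = cfg.thickness_range
    if route == "cluster":
        try:
            rec = select_cluster_record(library, cfg, rng)
            frags = [
                annotate_smiles(f"{rec.id}#{k}", smi)
                for k, smi in enumerate(rec.smiles.split("."))
            ]
            rendered = []
            for f in frags:
                thickness = int(rng.integers(tmin, tmax + 1))
                dep = _render_sized(
                    f, thickness, cfg,
                    base_canvas=cfg.cluster_frag_base
                    + cfg.cluster_frag_per_heavy * f.heavy_atoms,
                )
                dep = rotate_depiction(dep, float(rng.uniform(0, cfg.max_rotation_deg)))
                rendered.append(dep)
            packed = pack_cluster(rendered, cfg.cluster_spacing, rec.id)
            assets.append(("molecule", packed.dep, packed.sub))
        except NoEligibleMoleculesError:
            route = "single"
    if route == "single":
        mols = select_single_molecules(library, cfg, rng)
        for m in mols:
            thickness = int(rng.integers(tmin, tmax + 1))
            dep = _render_sized(m, thickness, cfg)
            dep = rotate_depiction(dep, float(rng.uniform(0, cfg.max_rotation_deg)))
            assets.append(("molecule", dep))
    if rng.random() < cfg.negative_prob:
        for i in range(int(rng.integers(1, 3))):
            neg = render_negative(rng)
            neg.asset_id = f"negative{i}"
            assets.append(("negative", neg))
    if route == "single" and rng.random() < cfg.text_prob:
        for i in range(int(rng.integers(1, 4))):
            txt = render_text_block(rng, cfg)
            txt.asset_id = f"text{i}"
            assets.append(("negative", txt))

    # bounded retries: drop an unplaceable asset and recompose, but never
    # drop the last molecule
    while True:
        try:
            pair = compose_page(base, assets, cfg, np.random.default_rng(page_seed + 1))
            break
        except PlacementError as exc:
            keep = [a for a in assets if a[1].asset_id != exc.asset_id]
            if sum(1 for a in keep if a[0] == "molecule") < 1:
                raise
            assets = keep
    pair.seed = page_seed
    pair.route = route
    return pair


def generate_dataset(
    cfg: SynthesisConfig,
    out_dir: str | Path,
    library: list[MoleculeSpec] | None = None,
) -> list[dict]:
    """Write pages/NNNN.png, masks/NNNN.png (0/255) and manifest.jsonl.

    Identical (cfg, seed) produce bit-identical files. Returns the manifest
    as a list of dicts (one per page).
    """
    out_dir = Path(out_dir)
    (out_dir / "pages").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    for i, pair in enumerate(synthesize_pages(cfg, library)):
        page_file = f"pages/{i:04d}.png"
        mask_file = f"masks/{i:04d}.png"
        Image.fromarray(pair.page).save(out_dir / page_file)
        Image.fromarray((pair.mask * 255).astype(np.uint8)).save(out_dir / mask_file)
        manifest.append(
            {
                "page": i,
                "page_file": page_file,
                "mask_file": mask_file,
                "seed": pair.seed,
                "route": pair.route,
                "placements": [asdict(p) for p in pair.placements],
            }
        )
    with open(out_dir / "manifest.jsonl", "w") as fh:
        for rec in manifest:
            fh.write(json.dumps(rec) + "\n")
    return manifest


def load_manifest(data_dir: str | Path) -> list[dict]:
    """Read a dataset manifest written by :func:`generate_dataset`."""
    path = Path(data_dir) / "manifest.jsonl"
    return [json.loads(line) for line in path.read_text().splitlines() if line.strip()]
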