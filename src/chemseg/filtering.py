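"""Post-hoc rejection of non-chemical segments (false-positive filter).

The shipped default scorer is a documented closed-form heuristic on ink
density and aspect ratio; structure depictions on white backgrounds occupy a
characteristic low-density band (sparse strokes over mostly white paper),
whereas filled figures (blots, charts, solid graphics) are much denser and
blank crops carry no ink at all. A learned classifier can be plugged in
through the same callable interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

# log-normal density band parameters: center and log-width of the ink
# fraction typical of structure depictions, measured on rendered molecules
DENSITY_CENTER = 0.07
DENSITY_LOG_SIGMA = 1.0
ASPECT_SOFT_LIMIT = 4.0
DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class FilterVerdict:
    is_structure: bool
    score: float
    method: str  # "heuristic" or "learned"


def score_segment_heuristic(
    crop_image: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> FilterVerdict:
    """Score one cropped segment with the closed-form heuristic.

    score = exp(-(ln(d / 0.07))^2 / 2) * min(1, 4 / aspect), where d is the
    crop's ink fraction (pixels darker than the crop mean) and aspect the
    long/short side ratio. Ink-free crops score 0; near-solid crops fall far
    above the density band and score near 0. Deterministic.
    """
    crop = np.asarray(crop_image, dtype=np.float64)
    if crop.ndim == 3:
        crop = crop @ np.array([0.299, 0.587, 0.114])
    if crop.size == 0:
        raise ValueError("zero-area crop")
    density = float((crop < crop.mean()).mean())
    if density <= 0.0:
        return FilterVerdict(False, 0.0, "heuristic")
    h, w = crop.shape
    aspect = max(h, w) / max(min(h, w), 1)
    density_term = np.exp(
        -((np.log(density / DENSITY_CENTER)) ** 2) / (2 * DENSITY_LOG_SIGMA**2)
    )
    aspect_term = min(1.0, ASPECT_SOFT_LIMIT / aspect)
    score = float(density_term * aspect_term)
    return FilterVerdict(score >= threshold, score, "heuristic")


def filter_segments(
    segments: Sequence,
    scorer: Callable[[np.ndarray], FilterVerdict] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[list, list]:
    """Partition segments into (kept, rejected) by the scorer.

    ``segments`` holds crop images or (payload, crop) tuples; ordering is
    preserved and every input lands in exactly one list. Rejected entries are
    (segment, "non-molecule") pairs.
    """
    if scorer is None:
        scorer = lambda crop: score_segment_heuristic(crop, threshold)
    kept, rejected = [], []
    for seg in segments:
        crop = seg[1] if isinstance(seg, tuple) else seg
        verdict = scorer(crop)
        if verdict.score >= threshold:
            kept.append(seg)
        else:
            rejected.append((seg, "non-molecule"))
    return kept, rejected
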