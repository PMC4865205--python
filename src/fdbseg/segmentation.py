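r"""From feature image to region of interest (ROI).

Binarization keeps pixels whose feature value reaches ``C * max(f_tilde)``
(an adaptive, intensity-relative threshold, so the chain is invariant to
positive rescaling of the input).  The binary ridge stripes are then fused by
a two-scale morphological vote: around each pixel an ``s x s`` cell and its
eight neighboring cells (offsets in {-s, 0, s}^2) are examined; a cell
"passes" when it contains at least ``s^2 / t`` foreground pixels, and the
pixel becomes foreground when at least ``b`` of the nine cells pass.  Unlike
plain closing, the cell occupancy requirement prevents a thin bridge of noise
from connecting the print to background clutter.  Finally the largest
8-connected component is kept and its convex hull (pixel centers inside the
hull polygon, boundary included) is the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .errors import ParameterError
from .params import FDBParams
from .transform import fdb_feature_image

__all__ = [
    "MorphologyParams",
    "binarize",
    "two_scale_morphology",
    "largest_component_hull",
    "segment_feature",
    "segment",
]

# feature maxima at or below this are round-off, not texture (inputs are in [0,1])
DEGENERATE_FEATURE_MAX = 1e-9

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class MorphologyParams:
    """Cell size s (odd), occupancy divisor t and required cell count b."""

    s: int = 9
    t: float = 5.0
    b: int = 6

    def __post_init__(self) -> None:
        if self.s < 3 or self.s % 2 == 0:
            raise ParameterError(f"s must be odd and >= 3, got {self.s}")
        if self.t <= 1.0:
            raise ParameterError(f"t must exceed 1, got {self.t}")
        if not 1 <= self.b <= 9:
            raise ParameterError(f"b must lie in 1..9, got {self.b}")


def binarize(feature: np.ndarray, C: float) -> np.ndarray:
    """Threshold the feature image at C times its maximum (>= rule)."""
    feature = np.asarray(feature, dtype=float)
    if not np.all(np.isfinite(feature)):
        raise ParameterError("feature image contains non-finite values")
    if not 0.0 < C < 1.0:
        raise ParameterError(f"C must lie in (0, 1), got {C}")
    return feature >= C * float(feature.max())


def _box_counts(mask: np.ndarray, s: int) -> np.ndarray:
    """Exact integer count of foreground pixels in the s x s cell centered at
    each pixel, with pixels outside the image counting as background."""
    r = s // 2
    padded = np.pad(mask.astype(np.int64), r, mode="constant")
    # summed-area table with a leading zero row/column
    sat = np.zeros((padded.shape[0] + 1, padded.shape[1] + 1), dtype=np.int64)
    np.cumsum(padded, axis=0, out=sat[1:, 1:])
    np.cumsum(sat[1:, 1:], axis=1, out=sat[1:, 1:])
    h, w = mask.shape
    return (
        sat[s : s + h, s : s + w]
        - sat[0:h, s : s + w]
        - sat[s : s + h, 0:w]
        + sat[0:h, 0:w]
    )


def two_scale_morphology(mask: np.ndarray, morph: MorphologyParams) -> np.ndarray:
    """Cell-and-block vote: pixel is foreground iff >= b of the 9 cells at
    offsets {-s,0,s}^2 around it contain >= s^2/t foreground pixels."""
    mask = np.asarray(mask, dtype=bool)
    s = morph.s
    if s >= min(mask.shape):
        raise ParameterError(f"cell size {s} must be smaller than both image dimensions {mask.shape}")
    occupancy = s * s / morph.t
    # cells centered outside the image still count their in-image white
    # pixels, so evaluate cell occupancy on an s-extended (zero-padded) domain
    extended = np.pad(mask, s, mode="constant")
    cell_pass = (_box_counts(extended, s) >= occupancy).astype(np.int64)
    h, w = mask.shape
    votes = np.zeros((h, w), dtype=np.int64)
    for dr in (-s, 0, s):
        for dc in (-s, 0, s):
            votes += cell_pass[s + dr : s + dr + h, s + dc : s + dc + w]
    return votes >= morph.b


def _rasterize_hull(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Fill every pixel whose center lies in (or on) the convex hull of the
    given (row, col) points."""
    out = np.zeros(shape, dtype=bool)
    try:
        hull = ConvexHull(points.astype(float))
    except QhullError:
        # degenerate (collinear or single-point) component: keep it as-is
        out[points[:, 0], points[:, 1]] = True
        return out
    r0, c0 = points.min(axis=0)
    r1, c1 = points.max(axis=0)
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    centers = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    # hull.equations: a . x + c <= 0 inside; tolerance keeps boundary pixels
    vals = centers @ hull.equations[:, :2].T + hull.equations[:, 2]
    inside = np.all(vals <= 1e-9, axis=1).reshape(rr.shape)
    out[r0 : r1 + 1, c0 : c1 + 1] = inside
    return out


def largest_component_hull(mask: np.ndarray) -> np.ndarray:
    """Keep the largest 8-connected foreground component; return the filled
    convex hull of its pixel set.  An empty mask yields an empty ROI."""
    mask = np.asarray(mask, dtype=bool)
    labels, count = ndimage.label(mask, structure=_EIGHT)
    if count == 0:
        return np.zeros_like(mask)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    points = np.argwhere(labels == int(np.argmax(sizes)))
    return _rasterize_hull(points, mask.shape)


def segment_feature(feature: np.ndarray, params: FDBParams) -> np.ndarray:
    """Morphological tail of the pipeline: binarize -> two-scale morphology ->
    largest-component hull, applied to a precomputed feature image.

    A feature image with no positive response (up to round-off) or an empty
    post-morphology mask yields an empty ROI.
    """
    feature = np.asarray(feature, dtype=float)
    if float(feature.max()) <= DEGENERATE_FEATURE_MAX:
        return np.zeros(feature.shape, dtype=bool)
    mask = binarize(feature, params.C)
    mask = two_scale_morphology(mask, MorphologyParams(s=params.s, t=params.t, b=params.b))
    if not mask.any():
        return np.zeros(mask.shape, dtype=bool)
    return largest_component_hull(mask)


def segment(
    image: np.ndarray,
    params: FDBParams,
    synthesis: str = "filter",
    use_shrinkage: bool = True,
) -> np.ndarray:
    """Full pipeline: feature image -> binarize -> morphology -> hull ROI."""
    feature = fdb_feature_image(image, params, synthesis=synthesis, use_shrinkage=use_shrinkage)
    return segment_feature(feature, params)
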