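r"""Synthetic fingerprint-like fixtures with exact ground truth.

Generates oscillatory ridge patterns inside a known elliptical ROI on a flat
background, optionally degraded by white noise and by artifact models drawn
from the failure modes real sensors exhibit: a *ghost print* (an attenuated
second pattern left on the sensor surface outside the true ROI), *dry breaks*
(patchy loss of ridge contrast as with a dry finger) and *structure noise*
(large-scale smooth intensity blobs).  Ridges follow one of three orientation
fields: constant direction, concentric arcs around a core, or a smoothly
rotating direction.  The ground-truth mask is the ROI ellipse itself, exact
by construction, so measured segmentation error is attributable to the
algorithm alone.

All randomness flows from the single ``seed`` field of :class:`SynthSpec`;
a fixed seed gives bit-identical images and byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .io import write_gray, write_mask

__all__ = ["SynthSpec", "make_fingerprint", "make_suite"]

WAVELENGTHS = (4.0, 8.0, 12.0, 20.0)
FIELDS = ("constant", "concentric", "smooth")


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic fingerprint image.

    ``wavelength`` is the inter-ridge distance in pixels (valid 3-25);
    ``roi`` is (center_row, center_col, semi_axis_row, semi_axis_col,
    rotation_radians); ``artifacts`` may contain ``ghost_print``,
    ``dry_breaks`` and ``structure_noise`` sub-dicts.
    """

    shape: tuple[int, int] = (192, 192)
    wavelength: float = 12.0
    orientation_field: str = "constant"
    theta: float = 0.5
    roi: tuple[float, float, float, float, float] | None = None
    amplitude: float = 0.5
    noise_sigma: float = 0.0
    artifacts: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 3.0 <= self.wavelength <= 25.0:
            raise ParameterError(f"wavelength must lie in [3, 25] px, got {self.wavelength}")
        if self.orientation_field not in FIELDS:
            raise ParameterError(f"orientation_field must be one of {FIELDS}")
        if self.amplitude <= 0:
            raise ParameterError(f"amplitude must be positive, got {self.amplitude}")
        if self.noise_sigma < 0:
            raise ParameterError(f"noise_sigma must be non-negative, got {self.noise_sigma}")
        unknown = set(self.artifacts) - {"ghost_print", "dry_breaks", "structure_noise"}
        if unknown:
            raise ParameterError(f"unknown artifact keys: {sorted(unknown)}")

    def roi_tuple(self) -> tuple[float, float, float, float, float]:
        if self.roi is not None:
            return self.roi
        h, w = self.shape
        return (h / 2.0, w / 2.0, 0.40 * h, 0.32 * w, 0.3)


def _ellipse_mask(shape, center_r, center_c, ax_r, ax_c, rot) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    dr, dc = rr - center_r, cc - center_c
    u = dr * np.cos(rot) + dc * np.sin(rot)
    v = -dr * np.sin(rot) + dc * np.cos(rot)
    return (u / ax_r) ** 2 + (v / ax_c) ** 2 <= 1.0


def _phase(spec: SynthSpec) -> np.ndarray:
    h, w = spec.shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    if spec.orientation_field == "constant":
        return cc * np.cos(spec.theta) + rr * np.sin(spec.theta)
    cr, ccen, *_ = spec.roi_tuple()
    if spec.orientation_field == "concentric":
        # ridges are arcs around a core placed above the ROI center
        core_r, core_c = cr - 0.2 * h, ccen
        return np.hypot(rr - core_r, cc - core_c)
    # smooth: direction rotates gently across the image width
    local = spec.theta + 0.35 * (cc - ccen) / w
    return (cc - ccen) * np.cos(local) + (rr - cr) * np.sin(local)


def _ridge_pattern(phase: np.ndarray, wavelength: float) -> np.ndarray:
    return np.cos(2.0 * np.pi * phase / wavelength)


def make_fingerprint(spec: SynthSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one synthetic fingerprint; returns (image in [0,1], truth mask)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    truth = _ellipse_mask(spec.shape, *spec.roi_tuple())
    ridges = _ridge_pattern(_phase(spec), spec.wavelength)

    contrast = np.full(spec.shape, spec.amplitude / 2.0)
    dry = spec.artifacts.get("dry_breaks")
    if dry:
        # patchy contrast loss: smooth random field thresholded at quantile p
        p = float(dry.get("prob", 0.3))
        fieldmap = ndimage.gaussian_filter(rng.standard_normal(spec.shape), sigma=6.0)
        contrast = contrast * (fieldmap > np.quantile(fieldmap, p))

    image = np.full(spec.shape, 0.5)
    image[truth] += (contrast * ridges)[truth]

    ghost = spec.artifacts.get("ghost_print")
    if ghost:
        att = float(ghost.get("attenuation", 0.6))
        dr, dc = ghost.get("offset", (int(0.3 * h), int(0.33 * w)))
        cr, cc, ar, ac, rot = spec.roi_tuple()
        gmask = _ellipse_mask(spec.shape, cr + dr, cc + dc, 0.55 * ar, 0.55 * ac, rot) & ~truth
        gphase = np.roll(np.roll(_phase(spec), 7, axis=0), -5, axis=1)
        image[gmask] += (att * spec.amplitude / 2.0) * _ridge_pattern(gphase, spec.wavelength)[gmask]

    blobs = spec.artifacts.get("structure_noise")
    if blobs:
        strength = float(blobs.get("strength", 0.15))
        smooth = ndimage.gaussian_filter(rng.standard_normal(spec.shape), sigma=12.0)
        image += strength * smooth / max(float(np.abs(smooth).max()), 1e-12)

    if spec.noise_sigma > 0:
        image += rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    return np.clip(image, 0.0, 1.0), truth


def _tier_kwargs(difficulty: str, index: int) -> dict:
    # tiers are nested: each adds degradation on top of the previous one,
    # so difficulty (and expected segmentation error) increases monotonically
    if difficulty == "clean":
        return {"noise_sigma": 0.02, "artifacts": {}}
    if difficulty == "noisy":
        return {"noise_sigma": 0.08, "artifacts": {}}
    if difficulty == "artifacts":
        arts: dict = {"structure_noise": {"strength": 0.15}}
        if index % 2 == 0:
            arts["ghost_print"] = {"attenuation": 0.6}
        if index % 3 == 0:
            arts["dry_breaks"] = {"prob": 0.3}
        return {"noise_sigma": 0.08, "artifacts": arts}
    raise ParameterError(f"difficulty must be clean|noisy|artifacts, got {difficulty!r}")


def make_suite(n_images: int, difficulty: str, seed: int, out_dir: str | Path):
    """Write ``n_images`` image/mask pairs plus a TSV manifest; returns the
    :class:`~fdbseg.evaluation.DatasetManifest`.

    Images cycle through wavelengths {4, 8, 12, 20} px and the three
    orientation fields; ROI geometry varies mildly per image.
    """
    from .evaluation import DatasetManifest  # local import avoids a cycle

    if n_images < 1:
        raise ParameterError(f"n_images must be >= 1, got {n_images}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    pairs = []
    for i in range(n_images):
        sub = int(master.integers(0, 2**31 - 1))
        geom = np.random.default_rng(sub)
        h = w = 192
        roi = (
            h / 2.0 + float(geom.uniform(-8, 8)),
            w / 2.0 + float(geom.uniform(-8, 8)),
            float(geom.uniform(0.34, 0.42)) * h,
            float(geom.uniform(0.27, 0.34)) * w,
            float(geom.uniform(-0.5, 0.5)),
        )
        spec = SynthSpec(
            shape=(h, w),
            wavelength=WAVELENGTHS[i % len(WAVELENGTHS)],
            orientation_field=FIELDS[i % len(FIELDS)],
            theta=float(geom.uniform(0.0, np.pi)),
            roi=roi,
            amplitude=0.5,
            seed=sub,
            **_tier_kwargs(difficulty, i),
        )
        image, truth = make_fingerprint(spec)
        img_path = out_dir / f"{difficulty}_{i:03d}.png"
        mask_path = out_dir / f"{difficulty}_{i:03d}_mask.png"
        write_gray(img_path, image)
        write_mask(mask_path, truth)
        pairs.append((img_path, mask_path))
    manifest = DatasetManifest(pairs=pairs, split="test", database=f"synthetic-{difficulty}")
    manifest.write(out_dir / f"{difficulty}_manifest.tsv")
    return manifest
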