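r"""Shrinkage operators for subband coefficients.

Soft-thresholding ``T(x, beta) = x/|x| * max(|x| - beta, 0)`` is the
pipeline's operator: it is the proximal map of ``beta * ||.||_1``, i.e. the
minimizer of ``beta*|u| + 0.5*(u - x)^2``, shrinks magnitudes while keeping
phase, and among the classical shrinkage rules it produces the sparsest
output.  Hard, semi-soft and nonlinear (garrote) rules are provided as
comparison operators only; they never enter the segmentation pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

KINDS = ("soft", "hard", "semisoft", "nonlinear")


@dataclass(frozen=True)
class ThresholdSpec:
    """Shrinkage rule selector: kind, primary threshold beta, and for the
    semi-soft rule the upper knee beta2 (defaults to 2*beta)."""

    kind: str = "soft"
    beta: float = 0.0
    beta2: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ParameterError(f"threshold kind must be one of {KINDS}, got {self.kind!r}")
        if self.beta < 0:
            raise ParameterError(f"beta must be non-negative, got {self.beta}")
        if self.kind == "semisoft":
            b2 = 2.0 * self.beta if self.beta2 is None else self.beta2
            if b2 <= self.beta:
                raise ParameterError(f"semisoft requires beta2 > beta, got beta2={b2}")

    @property
    def upper(self) -> float:
        return 2.0 * self.beta if self.beta2 is None else self.beta2


def _phase(x: np.ndarray, mag: np.ndarray) -> np.ndarray:
    # x/|x| with the removable singularity at 0 set to 0
    out = np.zeros_like(x)
    nz = mag > 0
    out[nz] = x[nz] / mag[nz]
    return out


def soft_threshold(x: np.ndarray, beta: float) -> np.ndarray:
    """Soft shrinkage: reduce |x| by beta, clip at 0, preserve sign/phase."""
    if beta < 0:
        raise ParameterError(f"beta must be non-negative, got {beta}")
    x = np.asarray(x)
    mag = np.abs(x)
    return _phase(x, mag) * np.maximum(mag - beta, 0.0)


def comparison_thresholds(x: np.ndarray, spec: ThresholdSpec) -> np.ndarray:
    """Apply the selected shrinkage rule.

    hard: identity above beta, 0 at or below; semisoft: 0 below beta, linear
    ramp to the identity between beta and beta2, identity above; nonlinear
    (garrote): x * max(1 - beta^2/x^2, 0).
    """
    x = np.asarray(x)
    beta = spec.beta
    mag = np.abs(x)
    if spec.kind == "soft":
        return soft_threshold(x, beta)
    if spec.kind == "hard":
        return np.where(mag > beta, x, np.zeros_like(x))
    if spec.kind == "semisoft":
        b2 = spec.upper
        ramp = _phase(x, mag) * (b2 / (b2 - beta)) * (mag - beta)
        out = np.where(mag <= beta, np.zeros_like(x), ramp)
        return np.where(mag >= b2, x, out)
    # nonlinear garrote
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(mag > 0, 1.0 - beta**2 / np.where(mag > 0, mag, 1.0) ** 2, 0.0)
    return x * np.maximum(gain, 0.0)
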