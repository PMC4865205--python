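"""Parameter containers for the factorized directional bandpass (FDB) pipeline.

The pipeline has ten tunables.  Four are spectral: the Butterworth bandpass
order ``gamma`` and cutoffs ``omega_L``/``omega_H`` (radians per sample), and
the directional-Hilbert (angularpass) order ``n`` together with the number of
orientations ``L``.  One, ``C``, sets both the adaptive shrinkage level
``beta = C * max|c_l|`` and the relative binarization threshold.  Three drive
the two-scale morphology: cell size ``s``, occupancy divisor ``t`` (a cell
passes when it holds at least ``s**2 / t`` foreground pixels) and the number
``b`` of passing cells required among the 3x3 cell neighborhood.  ``pad`` is
the mirror-boundary width in pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

from .errors import ParameterError

VARIANTS = ("bilinear", "original")


@dataclass(frozen=True)
class FDBParams:
    """Full parameter set of the FDB segmentation pipeline.

    Defaults for ``n``, ``L``, ``s``, ``b``, the cutoffs and the pad width are
    the method's fixed operating point for 500 DPI adult fingerprints; ``C``,
    ``gamma`` and ``t`` are the sensor-trained triple and default to the
    center of their trained ranges.
    """

    C: float = 0.05
    n: int = 20
    L: int = 16
    gamma: int = 2
    omega_L: float = 0.3
    omega_H: float = 1.0
    s: int = 9
    t: float = 5.0
    b: int = 6
    pad: int = 15
    variant: str = "bilinear"

    def __post_init__(self) -> None:
        if not 0.0 < self.C < 1.0:
            raise ParameterError(f"C must lie in (0, 1), got {self.C}")
        if self.n < 1 or int(self.n) != self.n:
            raise ParameterError(f"Hilbert order n must be a positive integer, got {self.n}")
        if self.L < 1 or int(self.L) != self.L:
            raise ParameterError(f"orientation count L must be a positive integer, got {self.L}")
        if self.gamma < 1 or int(self.gamma) != self.gamma:
            raise ParameterError(f"Butterworth order gamma must be a positive integer, got {self.gamma}")
        if not 0.0 < self.omega_L < self.omega_H <= math.pi:
            raise ParameterError(
                f"cutoffs must satisfy 0 < omega_L < omega_H <= pi, got ({self.omega_L}, {self.omega_H})"
            )
        if self.s < 3 or self.s % 2 == 0:
            raise ParameterError(f"cell size s must be odd and >= 3, got {self.s}")
        if self.t <= 1.0:
            raise ParameterError(f"morphology divisor t must exceed 1, got {self.t}")
        if not 1 <= self.b <= 9:
            raise ParameterError(f"block count b must lie in 1..9, got {self.b}")
        if self.pad < 0:
            raise ParameterError(f"pad width must be non-negative, got {self.pad}")
        if self.variant not in VARIANTS:
            raise ParameterError(f"variant must be one of {VARIANTS}, got {self.variant!r}")

    def replace(self, **kwargs) -> "FDBParams":
        """Return a copy with the given fields replaced (validated)."""
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kwargs)
        return FDBParams(**current)
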