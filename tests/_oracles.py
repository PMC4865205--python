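"""Independent brute-force oracles shared between test modules."""

import numpy as np


def naive_two_scale(mask: np.ndarray, s: int, t: float, b: int) -> np.ndarray:
    """Per-pixel 9-block loop oracle for the two-scale morphology
    (zero padding outside the image)."""
    h, w = mask.shape
    m = mask.astype(int)
    r = s // 2
    out = np.zeros((h, w), dtype=bool)
    thresh = s * s / t
    for k1 in range(h):
        for k2 in range(w):
            passing = 0
            for o1 in (-s, 0, s):
                for o2 in (-s, 0, s):
                    lo1, hi1 = k1 + o1 - r, k1 + o1 + r + 1
                    lo2, hi2 = k2 + o2 - r, k2 + o2 + r + 1
                    block = m[max(lo1, 0) : max(hi1, 0), max(lo2, 0) : max(hi2, 0)]
                    if block.sum() >= thresh:
                        passing += 1
            out[k1, k2] = passing >= b
    return out
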