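r"""Segmentation error metric, dataset evaluation and parameter training.

The per-image error is the fraction of misclassified pixels against a
ground-truth mask:

    Err = (M_f + M_b) / (N1 * N2),

where ``M_f`` counts true-foreground pixels labeled background and ``M_b``
true-background pixels labeled foreground.  Dataset scores are the unweighted
mean of per-image Err.  Training is an exhaustive grid search over the
sensor-dependent triple (C, gamma, t) with the remaining parameters fixed,
minimizing mean training error; ties go to the lexicographically smallest
(C, gamma, t).
"""

from __future__ import annotations

import csv
import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .io import read_gray, read_mask
from .params import FDBParams
from .segmentation import segment, segment_feature
from .transform import fdb_feature_image

__all__ = [
    "EvalResult",
    "DatasetManifest",
    "error_rate",
    "evaluate_dataset",
    "grid_search_params",
    "DEFAULT_GRID",
]

logger = logging.getLogger(__name__)

# training ranges bounding the per-sensor trained values
DEFAULT_GRID = {
    "C": [0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09],
    "gamma": [1, 2, 3, 4],
    "t": [4, 5, 6, 7],
}


@dataclass(frozen=True)
class EvalResult:
    """Pixel confusion counts and the per-image error rate."""

    Mf: int
    Mb: int
    N1: int
    N2: int

    @property
    def err(self) -> float:
        return (self.Mf + self.Mb) / (self.N1 * self.N2)


@dataclass
class DatasetManifest:
    """Paired image/ground-truth paths, as a plain-text TSV on disk."""

    pairs: list
    split: str = "test"
    database: str = ""

    def write(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            for img, mask in self.pairs:
                fh.write(f"{img}\t{mask}\n")

    @classmethod
    def read(cls, path: str | Path, split: str = "test", database: str = "") -> "DatasetManifest":
        pairs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                img, mask = line.split("\t")
                pairs.append((Path(img), Path(mask)))
        return cls(pairs=pairs, split=split, database=database)


def error_rate(estimated: np.ndarray, truth: np.ndarray) -> EvalResult:
    """Exact pixel-count confusion between an estimated and a true mask."""
    estimated = np.asarray(estimated, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if estimated.shape != truth.shape:
        raise ParameterError(f"mask shapes differ: {estimated.shape} vs {truth.shape}")
    Mf = int(np.count_nonzero(truth & ~estimated))
    Mb = int(np.count_nonzero(~truth & estimated))
    n1, n2 = estimated.shape
    return EvalResult(Mf=Mf, Mb=Mb, N1=n1, N2=n2)


def evaluate_dataset(
    manifest: DatasetManifest,
    params: FDBParams,
    report_csv: str | Path | None = None,
    mask_polarity: str = "auto",
):
    """Segment every image in the manifest and score it against its mask.

    Returns ``(rows, mean_err)`` where each row is a dict with the database,
    image path, confusion counts and per-image Err; unreadable pairs are
    logged and excluded.  ``report_csv`` optionally writes the rows plus a
    summary line.
    """
    rows = []
    for img_path, mask_path in manifest.pairs:
        try:
            image = read_gray(img_path)
            truth = read_mask(mask_path, polarity=mask_polarity)
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            logger.warning("skipping unreadable pair (%s, %s): %s", img_path, mask_path, exc)
            continue
        res = error_rate(segment(image, params), truth)
        rows.append(
            {
                "db": manifest.database,
                "image": str(img_path),
                "Mf": res.Mf,
                "Mb": res.Mb,
                "N1": res.N1,
                "N2": res.N2,
                "err": res.err,
            }
        )
    if not rows:
        raise ParameterError("no evaluable image/mask pairs in manifest")
    mean_err = float(np.mean([r["err"] for r in rows]))
    if report_csv is not None:
        _write_report(report_csv, rows, mean_err)
    return rows, mean_err


def _write_report(path: str | Path, rows: list, mean_err: float) -> None:
    fieldnames = ["db", "image", "Mf", "Mb", "N1", "N2", "err"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        for row in rows:
            writer.writerow({**row, "err": f"{row['err']:.6f}"})
        writer.writerow(
            {"db": rows[0]["db"], "image": "MEAN", "Mf": "", "Mb": "", "N1": "", "N2": "", "err": f"{mean_err:.6f}"}
        )


def grid_search_params(
    manifest: DatasetManifest,
    grid: dict | None = None,
    base: FDBParams | None = None,
    mask_polarity: str = "auto",
) -> tuple[FDBParams, float]:
    """Exhaustive search over (C, gamma, t) minimizing mean training error.

    ``grid`` maps "C", "gamma", "t" to value lists (defaults to the trained
    ranges); the other parameters come from ``base``.  Returns the winning
    parameter set and its training error; ties break to the smallest
    (C, gamma, t) in lexicographic order.
    """
    if not manifest.pairs:
        raise ParameterError("training manifest is empty")
    grid = dict(DEFAULT_GRID if grid is None else grid)
    for key in ("C", "gamma", "t"):
        if not grid.get(key):
            raise ParameterError(f"grid must provide a non-empty value list for {key!r}")
    base = base or FDBParams()
    data = [
        (read_gray(img), read_mask(mask, polarity=mask_polarity))
        for img, mask in manifest.pairs
    ]
    best: tuple[FDBParams, float] | None = None
    # t only enters the morphology stage, so the feature image is computed
    # once per (C, gamma) and re-thresholded for every t
    for C in sorted(grid["C"]):
        for gamma in sorted(grid["gamma"]):
            feats = [
                fdb_feature_image(image, base.replace(C=float(C), gamma=int(gamma)))
                for image, _ in data
            ]
            for t in sorted(grid["t"]):
                params = base.replace(C=float(C), gamma=int(gamma), t=float(t))
                errs = [
                    error_rate(segment_feature(feat, params), truth).err
                    for feat, (_, truth) in zip(feats, data)
                ]
                mean_err = float(np.mean(errs))
                if best is None or mean_err < best[1]:
                    best = (params, mean_err)
    assert best is not None
    return best
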