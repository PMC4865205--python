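"""Train the sensor-dependent parameters and evaluate on a held-out suite.

The triple (C, gamma, t) is sensor-dependent and is learned by exhaustive
grid search minimizing the mean segmentation error on a training suite; the
remaining parameters (n=20, L=16, s=9, b=6, cutoffs 0.3/1.0, pad 15) stay
fixed.  The trained parameters are then scored on a fresh test suite.
"""

import tempfile
from pathlib import Path

from fdbseg import FDBParams, evaluate_dataset, grid_search_params, make_suite

workdir = Path(tempfile.mkdtemp(prefix="fdbseg_example_"))

train = make_suite(4, "clean", seed=101, out_dir=workdir / "train")
grid = {"C": [0.05, 0.07, 0.09], "gamma": [1, 2], "t": [5.0, 7.0]}
best, train_err = grid_search_params(train, grid=grid)
print(f"trained parameters: C={best.C}, gamma={best.gamma}, t={best.t}")
print(f"training mean Err = {train_err:.4f}")

test = make_suite(8, "clean", seed=1, out_dir=workdir / "test")
rows, mean_err = evaluate_dataset(test, best, report_csv=workdir / "report.csv")
print(f"held-out mean Err over {len(rows)} images = {mean_err:.4f}")
print(f"untrained defaults for comparison: "
      f"{evaluate_dataset(test, FDBParams())[1]:.4f}")
print(f"per-image report written to {workdir / 'report.csv'}")
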