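"""One-off calibration of the synthetic generator's ilr covariance.

Finds a diagonal between-person ilr covariance (MVPA-first pivot basis) such
that simulated per-part hour SDs across persons match the study targets
(sleep 1.1, sedentary 1.1, standing 0.84, LPA 0.31, MVPA 0.42 h/day).
Common random numbers keep the objective smooth for the optimizer.  The
resulting variances are frozen as constants in coda24.synthetic; re-run this
script only if the targets change.

Usage: python scripts/calibrate_generator.py
"""

import numpy as np
from scipy.optimize import least_squares

from coda24.composition import (
    DEFAULT_LABELS,
    close,
    ilr_inverse_array,
    ilr_pivot,
    pivot_order,
)

PART_MEAN_HOURS = np.array([7.95, 10.5, 2.79, 1.15, 1.35])
PART_SD_HOURS = np.array([1.1, 1.1, 0.84, 0.31, 0.42])

ORDER = pivot_order("mvpa")
MU = ilr_pivot(
    close(dict(zip(DEFAULT_LABELS, PART_MEAN_HOURS * 60.0))), ORDER
).coords

rng = np.random.default_rng(20240901)
EPS = rng.standard_normal((200_000, 4))  # common random numbers
PERM = [ORDER.labels.index(lab) for lab in DEFAULT_LABELS]


def simulated_sds(log_v: np.ndarray) -> np.ndarray:
    z = MU + EPS * np.exp(0.5 * log_v)
    hours = ilr_inverse_array(z, total=24.0)[:, PERM]
    return hours.std(axis=0)


res = least_squares(
    lambda lv: simulated_sds(lv) - PART_SD_HOURS,
    x0=np.log(np.full(4, 0.05)),
    method="lm",
)
v = np.exp(res.x)
sds = simulated_sds(res.x)
print("converged:", res.success, "| cost:", res.cost)
print("ilr variances (mvpa-first basis):", np.array2string(v, precision=6))
print("achieved part SDs [h]:", np.array2string(sds, precision=3))
print("targets            [h]:", PART_SD_HOURS)
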