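"""Synthetic participant-day data with the structure the analysis assumes.

The study's participant-level data are not publicly deposited, so every
stage of the pipeline is exercised on simulated data with the same
statistical anatomy: ~199 participants contributing 3-22 days each, 5-part
daily compositions whose person-level means and spreads match the published
sample characteristics, and daily outcomes driven by the very multilevel
model the package fits --

    y_t = beta0 + betaB' zB + betaW' zW_t + gamma' c_t + phi * y_{t-1}
          + u0_i + uW_i' zW_t + sigma * eps_t

sampled sequentially so the previous-day lag term is coherent.  Person-level
ilr means are MVN around the sample center; day-level deviations are MVN
around zero; compositions come back through the inverse ilr map, so every
day closes to 1440 min by construction.

The generator records its generating values verbatim (:class:`TrueParameters`)
so parameter-recovery experiments can score bias, RMSE and interval coverage
against a known truth.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import (
    DEFAULT_LABELS,
    DEFAULT_TOTAL,
    close,
    ilr_inverse_array,
    ilr_pivot,
    pivot_order,
)
from .decomposition import decompose, part_columns
from .model import ModelSpec, build_design, fit

__all__ = [
    "BETWEEN_ILR_VARIANCES",
    "PART_MEAN_HOURS",
    "OUTCOME_TARGETS",
    "GeneratorConfig",
    "TrueParameters",
    "generate",
    "recovery_experiment",
]

#: Per-part mean hours/day of the emulated sample (sleep, sedentary,
#: standing, LPA, MVPA).
PART_MEAN_HOURS: tuple[float, ...] = (7.95, 10.5, 2.79, 1.15, 1.35)

#: Between-person ilr variances (MVPA-first pivot basis), calibrated once by
#: scripts/calibrate_generator.py so that simulated per-part hour SDs across
#: persons approximate the sample targets (1.1, 1.1, 0.84, 0.31, 0.42 h).
BETWEEN_ILR_VARIANCES: tuple[float, ...] = (0.076834, 0.029683, 0.020180, 0.144507)

#: Daily outcome calibration targets: marginal mean and SD on their native
#: 0-100 scales.
OUTCOME_TARGETS: dict[str, tuple[float, float]] = {
    "valence": (65.69, 12.2),
    "energetic_arousal": (56.25, 12.0),
    "calmness": (60.87, 12.8),
    "working_memory": (88.55, 9.0),
}

_LAG_COEF = 0.3
_TAU0_FRAC = 0.6  # share of marginal SD attributed to stable person differences


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs for the simulator.

    Effects (``beta_between``, ``beta_within``: map outcome -> length-(D-1)
    vector in the MVPA-first pivot basis) default to zero; the outcome then
    reduces to a lag-1 Gaussian process around its target mean.  Covariances
    must be positive definite.
    """

    n_participants: int = 199
    days_range: tuple[int, int] = (3, 22)
    days_fixed: int | None = None
    labels: tuple[str, ...] = DEFAULT_LABELS
    part_mean_hours: tuple[float, ...] = PART_MEAN_HOURS
    between_ilr_cov: np.ndarray = field(
        default_factory=lambda: np.diag(BETWEEN_ILR_VARIANCES)
    )
    within_ilr_cov: np.ndarray = field(
        default_factory=lambda: np.diag(BETWEEN_ILR_VARIANCES)
    )
    outcome_targets: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(OUTCOME_TARGETS)
    )
    beta_between: Mapping[str, np.ndarray] = field(default_factory=dict)
    beta_within: Mapping[str, np.ndarray] = field(default_factory=dict)
    lag_coef: float = _LAG_COEF
    tau0_frac: float = _TAU0_FRAC
    tau_within_frac: float = 0.04  # random-slope SD as a share of outcome SD
    missing_outcome_rate: float = 0.05
    age_mean: float = 35.84
    age_sd: float = 10.7
    age_range: tuple[float, float] = (20.0, 65.0)
    p_female: float = 0.553
    bmi_mean: float = 23.97
    bmi_sd: float = 3.3
    # non-wear concentrated under the 4-h slack so every generated day stays
    # a valid >= 20-h wear day (the emulated sample contains only valid days)
    nonwear_mean_h: float = 3.6
    nonwear_sd_h: float = 0.5
    total: float = DEFAULT_TOTAL
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("between_ilr_cov", "within_ilr_cov"):
            cov = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, cov)
            try:
                np.linalg.cholesky(cov + 1e-15 * np.eye(cov.shape[0]))
            except np.linalg.LinAlgError:
                raise ValueError(f"{name} is not positive semi-definite") from None
        if not 0 <= self.missing_outcome_rate <= 1:
            raise ValueError("missing_outcome_rate must be in [0, 1]")
        if not 0 <= self.p_female <= 1:
            raise ValueError("p_female must be in [0, 1]")
        if min(self.part_mean_hours) <= 0:
            raise ValueError("part means must be positive")
        if abs(self.lag_coef) >= 1:
            raise ValueError("lag coefficient must be in (-1, 1) for stationarity")


@dataclass(frozen=True)
class TrueParameters:
    """Generating values, echoed verbatim for recovery scoring.

    All compositional coefficients are in the MVPA-first pivot basis and on
    the *conditional* (lag-adjusted) scale -- exactly what the fitted model
    estimates.
    """

    order_labels: tuple[str, ...]
    mu_between: np.ndarray
    between_ilr_cov: np.ndarray
    within_ilr_cov: np.ndarray
    beta_between: dict[str, np.ndarray]
    beta_within: dict[str, np.ndarray]
    lag_coef: float
    tau0: dict[str, float]
    tau_within: dict[str, np.ndarray]
    sigma: dict[str, float]
    outcome_means: dict[str, float]


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """Square-root factor of a PSD matrix; exact zeros stay exact."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(cov)
        return V * np.sqrt(np.clip(w, 0.0, None))


def generate(config: GeneratorConfig) -> tuple[pd.DataFrame, TrueParameters]:
    """Simulate a participant-day table in the package's CSV dialect.

    Returns the long-format table (one row per participant-day) and the
    generating parameters.  Seeded runs are bit-reproducible.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_participants
    order = pivot_order("mvpa", config.labels)
    k = len(config.labels) - 1
    mu_B = ilr_pivot(
        close(dict(zip(config.labels, np.array(config.part_mean_hours) * 60.0)),
              config.total),
        order,
    ).coords

    if config.days_fixed is not None:
        n_days = np.full(m, config.days_fixed)
    else:
        lo, hi = config.days_range
        n_days = rng.integers(lo, hi + 1, size=m)
    total_rows = int(n_days.sum())
    pid_codes = np.repeat(np.arange(m), n_days)

    LB = _psd_factor(config.between_ilr_cov)
    LW = _psd_factor(config.within_ilr_cov)
    zB = mu_B + rng.standard_normal((m, k)) @ LB.T
    zW = rng.standard_normal((total_rows, k)) @ LW.T
    minutes_order = ilr_inverse_array(zB[pid_codes] + zW, total=config.total)
    # back from pivot order to canonical label order
    perm = [order.labels.index(lab) for lab in config.labels]
    minutes = minutes_order[:, perm]

    age = np.clip(
        rng.normal(config.age_mean, config.age_sd, m), *config.age_range
    )
    sex = np.where(rng.random(m) < config.p_female, "female", "male")
    bmi = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, m), 15.0, 45.0)
    nonwear = np.clip(
        rng.normal(config.nonwear_mean_h, config.nonwear_sd_h, total_rows),
        0.1, 3.99,
    )
    wear = 24.0 - nonwear

    phi = config.lag_coef
    beta_B: dict[str, np.ndarray] = {}
    beta_W: dict[str, np.ndarray] = {}
    tau0: dict[str, float] = {}
    tau_W: dict[str, np.ndarray] = {}
    sigma: dict[str, float] = {}
    outcome_cols: dict[str, np.ndarray] = {}

    day_start = np.concatenate([[0], np.cumsum(n_days)])
    for name, (mu_y, sd_y) in config.outcome_targets.items():
        bB = np.asarray(config.beta_between.get(name, np.zeros(k)), float)
        bW = np.asarray(config.beta_within.get(name, np.zeros(k)), float)
        # conditional-scale variance components chosen so the marginal mean
        # and SD land near the targets (see docs/methods.md)
        t0 = config.tau0_frac * sd_y * (1 - phi)
        tw = np.full(k, config.tau_within_frac * sd_y)
        sg = np.sqrt(max(sd_y**2 * (1 - config.tau0_frac**2), 1e-12) * (1 - phi**2))
        beta_B[name], beta_W[name] = bB, bW
        tau0[name], tau_W[name], sigma[name] = t0, tw, sg

        u0 = rng.normal(0.0, t0, m)
        uW = rng.standard_normal((m, k)) * tw
        # person-level constant of the conditional process
        const = mu_y * (1 - phi) + bB @ (zB - mu_B).T + u0
        slope = bW + uW  # (m, k)
        daily = np.einsum("rk,rk->r", zW, slope[pid_codes])
        eps = rng.standard_normal(total_rows)
        y = np.empty(total_rows)
        for i in range(m):
            s, e = day_start[i], day_start[i + 1]
            mean_i = const[i] / (1 - phi)
            y[s] = mean_i + daily[s] + sg / np.sqrt(1 - phi**2) * eps[s]
            for t in range(s + 1, e):
                y[t] = const[i] + daily[t] + phi * y[t - 1] + sg * eps[t]
        if config.missing_outcome_rate > 0:
            y[rng.random(total_rows) < config.missing_outcome_rate] = np.nan
        outcome_cols[name] = y

    df = pd.DataFrame(
        {
            "pid": [f"p{c + 1:03d}" for c in pid_codes],
            "day": np.concatenate([np.arange(1, d + 1) for d in n_days]),
        }
    )
    for j, col in enumerate(part_columns(config.labels)):
        df[col] = minutes[:, j]
    df["wear_h"] = wear
    df["walk_detected"] = 1
    df["n_ratings"] = np.clip(rng.poisson(4.4, total_rows), 1, 6)
    for name, y in outcome_cols.items():
        df[name] = y
    df["age"] = age[pid_codes]
    df["sex"] = sex[pid_codes]
    df["bmi"] = bmi[pid_codes]

    truth = TrueParameters(
        order_labels=order.labels,
        mu_between=mu_B,
        between_ilr_cov=config.between_ilr_cov.copy(),
        within_ilr_cov=config.within_ilr_cov.copy(),
        beta_between=beta_B,
        beta_within=beta_W,
        lag_coef=phi,
        tau0=tau0,
        tau_within=tau_W,
        sigma=sigma,
        outcome_means={n: t[0] for n, t in config.outcome_targets.items()},
    )
    return df, truth


def recovery_experiment(
    config: GeneratorConfig,
    replicates: int,
    fit_spec: ModelSpec,
    outcome: str | None = None,
) -> pd.DataFrame:
    """Repeatedly simulate + refit; score recovery of the generating values.

    For each monitored parameter (compositional coefficients, lag
    coefficient, residual SD) the report carries the truth, mean bias, RMSE,
    95%-CI coverage and the rate at which the CI excluded zero, across the
    converged replicates.  Non-converged replicates are counted and excluded
    from coverage.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    outcome = outcome or fit_spec.outcome
    k = len(config.labels) - 1
    seeds = np.random.SeedSequence(config.seed).spawn(replicates)
    records: list[dict] = []
    n_nonconverged = 0
    for r, ss in enumerate(seeds):
        gen_seed, fit_seed = (int(s % (2**31)) for s in ss.generate_state(2))
        cfg_r = GeneratorConfig(
            **{**config.__dict__, "seed": gen_seed}
        )
        data, truth = generate(cfg_r)
        dec = decompose(data, fit_spec.order, config.labels)
        design = build_design(dec, ModelSpec(**{**fit_spec.__dict__, "outcome": outcome}))
        spec_r = ModelSpec(**{**fit_spec.__dict__, "outcome": outcome, "seed": fit_seed})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws, diag = fit(design, spec_r)
        if not diag.converged:
            n_nonconverged += 1
            continue
        truths = {
            **{f"betaB[{j + 1}]": truth.beta_between[outcome][j] for j in range(k)},
            **{f"betaW[{j + 1}]": truth.beta_within[outcome][j] for j in range(k)},
            "lag_coef": truth.lag_coef,
            "sigma": truth.sigma[outcome],
        }
        samples = {
            **{f"betaB[{j + 1}]": draws.stacked("beta_between")[:, j] for j in range(k)},
            **{f"betaW[{j + 1}]": draws.stacked("beta_within")[:, j] for j in range(k)},
            "lag_coef": draws.stacked("gamma")[:, list(draws.covariate_names).index(f"{outcome}_lag")],
            "sigma": draws.stacked("sigma"),
        }
        for param, tv in truths.items():
            x = samples[param]
            lo, hi = np.percentile(x, [2.5, 97.5])
            records.append(
                {
                    "replicate": r,
                    "parameter": param,
                    "truth": tv,
                    "estimate": float(x.mean()),
                    "lower": float(lo),
                    "upper": float(hi),
                    "covered": bool(lo <= tv <= hi),
                    "significant": bool(lo > 0 or hi < 0),
                }
            )
    if not records:
        raise RuntimeError("no replicate converged; cannot score recovery")
    det = pd.DataFrame(records)
    summary = (
        det.groupby("parameter", sort=False)
        .apply(
            lambda g: pd.Series(
                {
                    "truth": g["truth"].iloc[0],
                    "mean_bias": (g["estimate"] - g["truth"]).mean(),
                    "rmse": np.sqrt(((g["estimate"] - g["truth"]) ** 2).mean()),
                    "coverage": g["covered"].mean(),
                    "significance_rate": g["significant"].mean(),
                    "n_converged": len(g),
                    "n_nonconverged": n_nonconverged,
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    return summary
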