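"""Bayesian multilevel regression of daily outcomes on ilr coordinates.

The model regresses a daily outcome (affect valence, energetic arousal,
calmness, or working-memory accuracy) on the between-person and
within-person ilr pivot coordinates of the 24-h behavior composition,
adjusting for baseline covariates (age, sex, BMI), daily wear time and the
previous-day outcome:

    y_ij ~ Normal( beta0 + betaB' zB_i + betaW' zW_ij + gamma' c_ij
                   + u0_i + uW_i' zW_ij,  sigma )

with a random intercept u0_i and random within-composition slopes uW_i per
participant, jointly Gaussian with a full covariance matrix.  Priors are
weakly informative and scale with sd(y); see :class:`PriorConfig`.
Convergence is gated on split-chain R-hat < 1.05 and bulk effective sample
size > 400 for every population-level parameter.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _gibbs
from .composition import PivotOrder, pivot_order, rotation_matrix
from .decomposition import between_columns, within_columns

__all__ = [
    "RHAT_MAX",
    "ESS_MIN",
    "PriorConfig",
    "ModelSpec",
    "PosteriorDraws",
    "Diagnostics",
    "build_design",
    "fit",
    "summarize",
]

RHAT_MAX = 1.05
ESS_MIN = 400.0

DEFAULT_COVARIATES = ("age", "sex", "bmi", "wear_h", "lag")


@dataclass(frozen=True)
class PriorConfig:
    """Weakly-informative prior scales, all relative to sd(y).

    beta ~ N(0, (beta_scale * sd_y)^2), intercept centered at mean(y);
    sigma ~ half-t(sigma_df, sd_scale * sd_y); the random-effect covariance
    gets a scaled inverse-Wishart prior with marginally uniform correlations
    and heavy-tailed SD margins of scale sd_scale * sd_y.
    """

    beta_scale: float = 10.0
    sd_scale: float = 2.5
    sigma_df: float = 3.0


@dataclass(frozen=True)
class ModelSpec:
    """What to fit and how to sample.

    ``covariates`` may include the pseudo-covariate ``"lag"`` (previous-day
    outcome, built by :func:`build_design` from day adjacency).
    """

    outcome: str
    order: PivotOrder = field(default_factory=lambda: pivot_order("mvpa"))
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    seed: int = 0
    priors: PriorConfig = field(default_factory=PriorConfig)
    random_effects: bool = True

    def __post_init__(self) -> None:
        if self.iterations <= self.warmup:
            raise ValueError("iterations must exceed warmup")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")


def build_design(decomposed: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """One row per usable participant-day, ready for :func:`fit`.

    Columns, in order: ``pid, day, y``, between ilr ``bz1..bz{D-1}``, within
    ilr ``wz1..wz{D-1}``, then the spec's covariates.  The ``lag`` covariate
    is the same participant's outcome on the *previous calendar day*
    (``day - 1``); a precomputed ``{outcome}_lag`` column takes precedence
    (used for prospective alignment).  First observed days therefore drop,
    as do rows with any missing field.  Sex is coded as a 0/1 indicator;
    continuous covariates are mean-centered (centering shifts only the
    intercept, never compositional coefficients or substitution contrasts).
    """
    if spec.outcome not in decomposed.columns:
        raise ValueError(f"outcome {spec.outcome!r} not in data")
    order = decomposed.attrs.get("pivot_order")
    if order is not None and tuple(order.labels) != tuple(spec.order.labels):
        raise ValueError(
            f"data decomposed with pivot order {order.labels}, spec wants "
            f"{spec.order.labels}; re-run decompose"
        )
    D = spec.order.n_parts
    bc, wc = between_columns(D), within_columns(D)
    df = decomposed.copy()

    cov_cols: list[str] = []
    for cov in spec.covariates:
        if cov == "lag":
            lag_col = f"{spec.outcome}_lag"
            if lag_col not in df.columns:
                prev = df[["pid", "day", spec.outcome]].copy()
                prev["day"] = prev["day"] + 1
                prev = prev.rename(columns={spec.outcome: lag_col})
                df = df.merge(prev, on=["pid", "day"], how="left")
            cov_cols.append(lag_col)
        elif cov not in df.columns:
            raise ValueError(f"covariate {cov!r} not in data")
        else:
            cov_cols.append(cov)

    out = df[["pid", "day", spec.outcome] + bc + wc + cov_cols].rename(
        columns={spec.outcome: "y"}
    )
    # binary coding for categorical covariates (e.g. sex)
    for c in cov_cols:
        if not pd.api.types.is_numeric_dtype(out[c]):
            levels = sorted(out[c].dropna().unique())
            if len(levels) > 2:
                raise ValueError(f"covariate {c!r} has >2 categories: {levels}")
            out[c] = out[c].map({lev: i for i, lev in enumerate(levels)}).astype(float)
    out = out.dropna().reset_index(drop=True)
    for c in cov_cols:
        vals = out[c].to_numpy(dtype=float)
        if len(np.unique(vals)) > 2:  # leave binary indicators uncentered
            out[c] = vals - vals.mean()
    if out["pid"].nunique() < 2:
        raise ValueError("need at least 2 participants with usable rows")
    out.attrs["pivot_order"] = spec.order
    out.attrs["covariate_columns"] = tuple(cov_cols)
    return out


@dataclass
class PosteriorDraws:
    """Post-warmup draws, shaped (chains, draws, ...)."""

    order: PivotOrder
    covariate_names: tuple[str, ...]
    person_ids: np.ndarray
    beta0: np.ndarray  # (c, d)
    beta_between: np.ndarray  # (c, d, D-1)
    beta_within: np.ndarray  # (c, d, D-1)
    gamma: np.ndarray  # (c, d, n_cov)
    sigma: np.ndarray  # (c, d)
    tau0: np.ndarray  # (c, d)
    tau_within: np.ndarray  # (c, d, D-1)
    corr_ranef: np.ndarray  # (c, d, q, q)
    ranef: np.ndarray  # (c, d, m, q)

    @property
    def n_draws(self) -> int:
        return self.beta0.shape[0] * self.beta0.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws with chains flattened into the leading axis."""
        arr = getattr(self, name)
        return arr.reshape((-1,) + arr.shape[2:])

    def monitored(self) -> dict[str, np.ndarray]:
        """Population-level parameters monitored for convergence."""
        out: dict[str, np.ndarray] = {"beta0": self.beta0, "sigma": self.sigma}
        for k in range(self.beta_between.shape[-1]):
            out[f"betaB[{k + 1}]"] = self.beta_between[..., k]
            out[f"betaW[{k + 1}]"] = self.beta_within[..., k]
        for j, name in enumerate(self.covariate_names):
            out[f"gamma[{name}]"] = self.gamma[..., j]
        out["tau0"] = self.tau0
        for k in range(self.tau_within.shape[-1]):
            out[f"tauW[{k + 1}]"] = self.tau_within[..., k]
        return out


@dataclass
class Diagnostics:
    """Split-chain R-hat and bulk ESS per monitored parameter."""

    table: pd.DataFrame  # columns: parameter, rhat, ess_bulk
    converged: bool

    @property
    def max_rhat(self) -> float:
        return float(self.table["rhat"].max())

    @property
    def min_ess(self) -> float:
        return float(self.table["ess_bulk"].min())


def _diagnose(monitored: dict[str, np.ndarray]) -> Diagnostics:
    import arviz as az

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, arr in monitored.items():
            rows.append(
                {
                    "parameter": name,
                    "rhat": float(az.rhat(arr.astype(float))),
                    "ess_bulk": float(az.ess(arr.astype(float), method="bulk")),
                }
            )
    table = pd.DataFrame(rows)
    converged = bool(
        (table["rhat"] < RHAT_MAX).all() and (table["ess_bulk"] > ESS_MIN).all()
    )
    return Diagnostics(table=table, converged=converged)


def fit(design: pd.DataFrame, spec: ModelSpec) -> tuple[PosteriorDraws, Diagnostics]:
    """Sample the posterior; non-convergence is flagged, never raised."""
    D = spec.order.n_parts
    bc, wc = between_columns(D), within_columns(D)
    cov_cols = list(design.attrs.get("covariate_columns", ()))
    y = design["y"].to_numpy(dtype=float)
    n = len(y)
    counts = design.groupby("pid").size()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 participants with >= 2 rows each")

    X = np.column_stack(
        [np.ones(n)]
        + [design[c].to_numpy(dtype=float) for c in bc + wc + cov_cols]
    )
    if spec.random_effects:
        Z = np.column_stack([np.ones(n)] + [design[c].to_numpy(float) for c in wc])
    else:
        Z = np.zeros((n, 1))  # degenerate: collapsed update reduces to OLS form
    pid_codes, person_ids = pd.factorize(design["pid"], sort=True)

    sd_y = float(np.std(y))
    p = X.shape[1]
    beta_mean = np.zeros(p)
    beta_mean[0] = float(np.mean(y))
    beta_sd = np.full(p, spec.priors.beta_scale * sd_y)
    priors = _gibbs.GibbsPriors(
        beta_mean=beta_mean,
        beta_sd=beta_sd,
        sigma_df=spec.priors.sigma_df,
        sigma_scale=spec.priors.sd_scale * sd_y,
        ranef_scale=spec.priors.sd_scale * sd_y,
    )

    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
             np.random.SeedSequence(spec.seed).spawn(spec.chains)]
    chains = [
        _gibbs.run_chain(y, X, Z, pid_codes, priors, spec.iterations, spec.warmup, s)
        for s in seeds
    ]

    beta = np.stack([c.beta for c in chains])  # (c, d, p)
    k = D - 1
    draws = PosteriorDraws(
        order=spec.order,
        covariate_names=tuple(cov_cols),
        person_ids=np.asarray(person_ids),
        beta0=beta[..., 0],
        beta_between=beta[..., 1 : 1 + k],
        beta_within=beta[..., 1 + k : 1 + 2 * k],
        gamma=beta[..., 1 + 2 * k :],
        sigma=np.stack([c.sigma for c in chains]),
        tau0=np.stack([c.sd_ranef[:, 0] for c in chains]),
        tau_within=np.stack([c.sd_ranef[:, 1:] for c in chains]),
        corr_ranef=np.stack([c.corr_ranef for c in chains]),
        ranef=np.stack([c.ranef for c in chains]),
    )
    diag = _diagnose(draws.monitored())
    if not diag.converged:
        warnings.warn(
            f"MCMC did not meet convergence gates (max R-hat {diag.max_rhat:.3f}, "
            f"min bulk ESS {diag.min_ess:.0f}); treat estimates with caution",
            stacklevel=2,
        )
    return draws, diag


def _interval(x: np.ndarray) -> tuple[float, float, float]:
    return float(x.mean()), float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5))


def summarize(
    draws: PosteriorDraws, report_orders: Sequence[PivotOrder] | None = None
) -> pd.DataFrame:
    """Coefficient table: posterior mean, 95% equal-tailed CI, significance.

    For every requested pivot order the compositional coefficient draws are
    rotated with the orthogonal change-of-basis matrix (betaB and betaW
    separately), so a single fit reports e.g. both the MVPA-first and the
    sedentary-first first coordinates.  Significance = 95% CI excludes zero.
    """
    if report_orders is None:
        report_orders = [draws.order]
    rows = []

    def add(parameter: str, level: str, pivot: str, x: np.ndarray) -> None:
        mean, lo, hi = _interval(x)
        rows.append(
            {
                "parameter": parameter,
                "level": level,
                "pivot": pivot,
                "mean": mean,
                "lower": lo,
                "upper": hi,
                "significant": bool(lo > 0 or hi < 0),
            }
        )

    add("intercept", "population", "", draws.stacked("beta0"))
    bB = draws.stacked("beta_between")
    bW = draws.stacked("beta_within")
    for order in report_orders:
        Q = rotation_matrix(draws.order, order)
        rB, rW = bB @ Q.T, bW @ Q.T
        for k in range(rB.shape[1]):
            contrast = (
                f"{order.labels[k]}_vs_remaining" if k == 0 else f"z{k + 1}"
            )
            add(f"ilr[{contrast}]", "between", order.pivot, rB[:, k])
            add(f"ilr[{contrast}]", "within", order.pivot, rW[:, k])
    for j, name in enumerate(draws.covariate_names):
        add(f"gamma[{name}]", "population", "", draws.stacked("gamma")[:, j])
    add("sigma", "population", "", draws.stacked("sigma"))
    add("tau0", "population", "", draws.stacked("tau0"))
    for k in range(draws.tau_within.shape[-1]):
        add(f"tauW[{k + 1}]", "population", "", draws.stacked("tau_within")[:, k])
    return pd.DataFrame(rows)
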