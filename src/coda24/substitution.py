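"""Posterior time-reallocation (isotemporal substitution) estimates.

Given a fitted multilevel compositional model, these routines estimate the
expected change in the daily outcome when a fixed number of minutes is moved
from one behavior to another, holding the remaining behaviors constant.  All
estimates are evaluated relative to a reference composition (by default the
mean composition among included participants) and are computed per posterior
draw as

    dy = beta_level' * ( ilr(reallocated) - ilr(reference) )

where ``beta_level`` selects the between- or within-person coefficients.
Covariates and random effects cancel exactly in this difference under the
linear model.  Because the ilr transform is nonlinear in minutes, adding
t minutes to a behavior is *not* the mirror image of removing t minutes, so
grids are computed over ordered (to, from) pairs, covering both directions.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import Composition, IlrVector, ilr_pivot
from .model import PosteriorDraws

__all__ = [
    "InfeasibleReallocationError",
    "ReallocationRequest",
    "SubstitutionEstimate",
    "reallocate",
    "estimate",
    "substitution_grid",
    "substitution_matrix",
]

LEVELS = ("between", "within")


class InfeasibleReallocationError(ValueError):
    """The donor behavior does not have enough minutes to give up."""


@dataclass(frozen=True)
class ReallocationRequest:
    """Move ``minutes`` from ``from_part`` to ``to_part`` at a given level."""

    to_part: str
    from_part: str
    minutes: float
    level: str = "within"

    def __post_init__(self) -> None:
        if self.to_part == self.from_part:
            raise ValueError("to_part and from_part must differ")
        if self.minutes < 0:
            raise ValueError(
                "minutes must be >= 0; model the opposite direction by swapping parts"
            )
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")


@dataclass(frozen=True)
class SubstitutionEstimate:
    request: ReallocationRequest
    mean: float
    lower: float
    upper: float

    @property
    def significant(self) -> bool:
        return self.lower > 0 or self.upper < 0


def reallocate(
    base: Composition, to_part: str, from_part: str, minutes: float
) -> Composition:
    """The composition after moving ``minutes`` from ``from_part`` to ``to_part``."""
    if to_part == from_part:
        raise ValueError("to_part and from_part must differ")
    new = dict(base.as_dict())
    for part in (to_part, from_part):
        if part not in new:
            raise KeyError(part)
    if new[from_part] - minutes <= 0:
        raise InfeasibleReallocationError(
            f"cannot move {minutes} min out of {from_part!r} "
            f"({new[from_part]:.1f} min available)"
        )
    new[to_part] += minutes
    new[from_part] -= minutes
    return Composition(base.labels, np.array([new[l] for l in base.labels]), base.total)


def _delta_ilr(base: Composition, req: ReallocationRequest, order) -> np.ndarray:
    new = reallocate(base, req.to_part, req.from_part, req.minutes)
    return ilr_pivot(new, order).coords - ilr_pivot(base, order).coords


def estimate(
    draws: PosteriorDraws, req: ReallocationRequest, base: Composition
) -> SubstitutionEstimate:
    """Posterior mean difference and 95% equal-tailed CI for one reallocation.

    Uses the population-level (fixed) coefficients of the requested level;
    the within-level contrast is evaluated at the reference composition with
    zero within-person deviation, i.e. on an average day.
    """
    dz = _delta_ilr(base, req, draws.order)
    beta = draws.stacked(
        "beta_between" if req.level == "between" else "beta_within"
    )
    dy = beta @ dz
    return SubstitutionEstimate(
        request=req,
        mean=float(dy.mean()),
        lower=float(np.percentile(dy, 2.5)),
        upper=float(np.percentile(dy, 97.5)),
    )


def substitution_grid(
    draws: PosteriorDraws,
    base: Composition,
    minutes_grid: Iterable[float] = range(1, 61),
    levels: Sequence[str] = LEVELS,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """All ordered pairwise reallocations over a minutes grid, both levels.

    Returns a long table with columns ``level, to, from, minutes, mean,
    lower, upper, significant, feasible``.  Cells where the donor behavior
    would be exhausted are flagged ``feasible=False`` with missing estimates
    rather than dropped, so the grid shape is always complete.
    """
    minutes_grid = list(minutes_grid)
    if not minutes_grid:
        raise ValueError("empty minutes grid")
    if pairs is None:
        pairs = [
            (a, b) for a in base.labels for b in base.labels if a != b
        ]
    rows = []
    for level in levels:
        beta = draws.stacked(
            "beta_between" if level == "between" else "beta_within"
        )
        for to_part, from_part in pairs:
            for t in minutes_grid:
                rec = {
                    "level": level,
                    "to": to_part,
                    "from": from_part,
                    "minutes": float(t),
                }
                try:
                    dz = _delta_ilr(
                        base, ReallocationRequest(to_part, from_part, t, level), order=draws.order
                    )
                except InfeasibleReallocationError:
                    rec.update(
                        mean=np.nan, lower=np.nan, upper=np.nan,
                        significant=False, feasible=False,
                    )
                else:
                    dy = beta @ dz
                    lo, hi = np.percentile(dy, [2.5, 97.5])
                    rec.update(
                        mean=float(dy.mean()),
                        lower=float(lo),
                        upper=float(hi),
                        significant=bool(lo > 0 or hi < 0),
                        feasible=True,
                    )
                rows.append(rec)
    return pd.DataFrame(rows)


def substitution_matrix(
    grid: pd.DataFrame, level: str, minutes: float = 30.0, value: str = "mean"
) -> pd.DataFrame:
    """Pairwise matrix view at one duration: rows = gaining behavior
    (increased), columns = donating behavior (decreased)."""
    sub = grid[(grid["level"] == level) & (grid["minutes"] == minutes)]
    if sub.empty:
        raise ValueError(f"no grid cells at level={level!r}, minutes={minutes}")
    mat = sub.pivot(index="to", columns="from", values=value)
    order = [l for l in sub["to"].unique()]
    return mat.reindex(index=order, columns=order)
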