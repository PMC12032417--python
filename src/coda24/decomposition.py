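"""Between/within-person decomposition of daily compositions.

Repeated daily compositions are split into a *between-person* component (the
person's compositional mean, i.e. the geometric center of their days) and a
*within-person* deviation (the day's departure from that mean).  Both are
expressed in ilr pivot coordinates, where the decomposition is an exact
additive identity:

    ilr(day) = between_ilr(person) + within_ilr(person, day)

and each person's within deviations average to exactly zero.  Geometric-mean
(not arithmetic) centering is what makes the identity exact in ilr space.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .composition import (
    DEFAULT_LABELS,
    DEFAULT_TOTAL,
    Composition,
    PivotOrder,
    geometric_center,
    pivot_contrast_matrix,
)

__all__ = [
    "PART_COLUMNS",
    "part_columns",
    "person_mean_composition",
    "decompose",
    "between_columns",
    "within_columns",
    "ilr_day_columns",
    "sample_reference_composition",
]

#: Canonical CSV columns holding minutes per part, aligned with DEFAULT_LABELS.
PART_COLUMNS: tuple[str, ...] = tuple(f"{lab}_min" for lab in DEFAULT_LABELS)


def part_columns(labels: Sequence[str] = DEFAULT_LABELS) -> tuple[str, ...]:
    return tuple(f"{lab}_min" for lab in labels)


def between_columns(n_parts: int = 5) -> list[str]:
    return [f"bz{k}" for k in range(1, n_parts)]


def within_columns(n_parts: int = 5) -> list[str]:
    return [f"wz{k}" for k in range(1, n_parts)]


def ilr_day_columns(n_parts: int = 5) -> list[str]:
    return [f"z{k}" for k in range(1, n_parts)]


def person_mean_composition(days: Sequence[Composition]) -> Composition:
    """A person's average 24-h composition: the geometric center of their days."""
    if len(days) == 0:
        raise ValueError("person_mean_composition of an empty day list")
    return geometric_center(days)


def decompose(
    data: pd.DataFrame,
    order: PivotOrder,
    labels: Sequence[str] = DEFAULT_LABELS,
    id_col: str = "pid",
) -> pd.DataFrame:
    """Add day, between and within ilr coordinates to a participant-day table.

    Parameters
    ----------
    data
        One row per participant-day with minutes columns ``<label>_min`` for
        every label; other columns (outcomes, covariates) pass through.
    order
        Pivot order for the ilr basis (e.g. MVPA-first).
    labels
        Part labels; columns are ``f"{label}_min"``.
    id_col
        Participant identifier column.

    Returns
    -------
    DataFrame
        Copy of ``data`` with columns ``z1..z{D-1}`` (day ilr), ``bz*``
        (between, constant within participant) and ``wz*`` (within,
        mean-zero per participant); the pivot order is stored in
        ``.attrs["pivot_order"]``.
    """
    labels = tuple(labels)
    if set(order.labels) != set(labels):
        raise ValueError(f"pivot order {order.labels} does not match labels {labels}")
    cols = part_columns(labels)
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing minutes columns: {missing}")
    minutes = data[list(cols)].to_numpy(dtype=float)
    if not np.all(minutes > 0):
        bad = data.index[(minutes <= 0).any(axis=1)][:5].tolist()
        raise ValueError(f"non-positive minutes in rows {bad}")

    # permute columns into pivot order, then z = V ln(x); the per-person mean
    # of day ilr vectors IS the ilr of the person's geometric center.
    idx = [labels.index(lab) for lab in order.labels]
    V = pivot_contrast_matrix(len(labels))
    z = np.log(minutes[:, idx]) @ V.T

    out = data.copy()
    D = len(labels)
    zc, bc, wc = ilr_day_columns(D), between_columns(D), within_columns(D)
    out[zc] = z
    grouped = out.groupby(id_col, sort=False)[zc].transform("mean")
    out[bc] = grouped.to_numpy()
    out[wc] = z - grouped.to_numpy()
    out.attrs["pivot_order"] = order
    out.attrs["labels"] = labels
    return out


def sample_reference_composition(
    data: pd.DataFrame,
    labels: Sequence[str] = DEFAULT_LABELS,
    id_col: str = "pid",
    total: float = DEFAULT_TOTAL,
    method: str = "person_mean",
) -> Composition:
    """Mean composition among included participants.

    ``method="person_mean"`` (default) takes the geometric center of the
    per-person geometric means, weighting each participant equally;
    ``"pooled"`` pools all days (weights participants by day count).
    """
    cols = list(part_columns(labels))
    logs = np.log(data[cols].to_numpy(dtype=float))
    if method == "person_mean":
        mean_log = (
            pd.DataFrame(logs, index=data[id_col].to_numpy())
            .groupby(level=0, sort=False)
            .mean()
            .to_numpy()
            .mean(axis=0)
        )
    elif method == "pooled":
        mean_log = logs.mean(axis=0)
    else:
        raise ValueError(f"unknown method {method!r}")
    g = np.exp(mean_log)
    return Composition(tuple(labels), g * (total / g.sum()), total)
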