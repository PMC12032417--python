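"""Aitchison-geometry primitives for daily time-use compositions.

A 24-hour day is described as a *composition*: strictly positive minutes in
each of a fixed set of behaviors (by default sleep period, sedentary time,
standing, light physical activity, moderate-to-vigorous physical activity)
that are closed to a fixed total (1440 min).  Compositions carry only
relative information, so all modelling happens in isometric log-ratio (ilr)
coordinates.  This module implements closure, pivot-coordinate ilr and its
inverse, rotation between pivot bases, and geometric centering.

Pivot coordinates are the ilr basis associated with the sequential binary
partition that first splits one chosen part (the *pivot*) from all remaining
parts; the first coordinate is then proportional to the log-ratio of the
pivot against the geometric mean of the rest,

    z_k = sqrt((D-k)/(D-k+1)) * ln( x_k / gmean(x_{k+1}, ..., x_D) ),

for parts taken in the order given by a :class:`PivotOrder`.  Natural
logarithms throughout.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_LABELS",
    "DEFAULT_TOTAL",
    "Composition",
    "PivotOrder",
    "IlrVector",
    "ZeroPartError",
    "LabelMismatchError",
    "close",
    "pivot_order",
    "pivot_contrast_matrix",
    "ilr_pivot",
    "ilr_inverse",
    "rotation_matrix",
    "rotate_basis",
    "geometric_center",
    "aitchison_distance",
    "ilr_array",
    "ilr_inverse_array",
]

#: Canonical part labels for the 5-part 24-h physical-behavior composition.
DEFAULT_LABELS: tuple[str, ...] = ("sleep", "sedentary", "standing", "lpa", "mvpa")

#: Minutes in a midnight-to-midnight day.
DEFAULT_TOTAL: float = 1440.0

_REL_TOL = 1e-9


class ZeroPartError(ValueError):
    """A compositional part is zero or negative where positivity is required."""


class LabelMismatchError(ValueError):
    """Two compositional objects do not share the same part labels."""


@dataclass(frozen=True)
class Composition:
    """A strictly positive D-part composition closed to a fixed total.

    Parameters
    ----------
    labels
        Ordered part labels (length D >= 2).
    minutes
        Positive minutes per part, summing to ``total`` within relative
        tolerance 1e-9.
    total
        The closure constant in minutes (default 1440).
    """

    labels: tuple[str, ...]
    minutes: np.ndarray
    total: float = DEFAULT_TOTAL

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        minutes = np.asarray(self.minutes, dtype=float)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "minutes", minutes)
        if minutes.ndim != 1 or len(labels) != minutes.size:
            raise ValueError("labels and minutes must have matching 1-d shape")
        if len(labels) < 2:
            raise ValueError("a composition needs at least 2 parts")
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate part labels: {labels}")
        if self.total <= 0:
            raise ValueError("total must be positive")
        for lab, m in zip(labels, minutes):
            if not m > 0:
                raise ZeroPartError(f"part {lab!r} is {m}; all parts must be > 0")
        if abs(minutes.sum() - self.total) > _REL_TOL * self.total:
            raise ValueError(
                f"parts sum to {minutes.sum()!r}, expected total {self.total!r}"
            )
        minutes.setflags(write=False)

    @property
    def n_parts(self) -> int:
        return len(self.labels)

    def __getitem__(self, label: str) -> float:
        try:
            return float(self.minutes[self.labels.index(label)])
        except ValueError:
            raise KeyError(label) from None

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, map(float, self.minutes)))

    def proportions(self) -> np.ndarray:
        return self.minutes / self.total

    def reorder(self, labels: Sequence[str]) -> "Composition":
        """Return the same composition with parts listed in ``labels`` order."""
        idx = _permutation(self.labels, tuple(labels))
        return Composition(tuple(labels), self.minutes[idx], self.total)

    def isclose(self, other: "Composition", atol: float = 1e-9) -> bool:
        if set(self.labels) != set(other.labels):
            return False
        o = other.reorder(self.labels)
        return bool(
            np.allclose(self.minutes, o.minutes, atol=atol)
            and abs(self.total - other.total) <= atol
        )


@dataclass(frozen=True)
class PivotOrder:
    """An ordering of part labels; the first label is the pivot part."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(set(labels)) != len(labels) or len(labels) < 2:
            raise ValueError(f"pivot order must be >= 2 distinct labels, got {labels}")

    @property
    def pivot(self) -> str:
        return self.labels[0]

    @property
    def n_parts(self) -> int:
        return len(self.labels)


def pivot_order(first: str, labels: Sequence[str] = DEFAULT_LABELS) -> PivotOrder:
    """Pivot order with ``first`` as pivot and the rest in canonical order.

    Coordinates 2..D-1 depend on the order of the remaining parts; fixing it
    to the canonical label order makes reported coordinates reproducible.
    The first coordinate does not depend on that choice.
    """
    if first not in labels:
        raise LabelMismatchError(f"{first!r} not among {tuple(labels)}")
    rest = tuple(l for l in labels if l != first)
    return PivotOrder((first,) + rest)


def _permutation(src: tuple[str, ...], dst: tuple[str, ...]) -> np.ndarray:
    if set(src) != set(dst) or len(src) != len(dst):
        raise LabelMismatchError(f"label sets differ: {src} vs {dst}")
    pos = {lab: i for i, lab in enumerate(src)}
    return np.array([pos[lab] for lab in dst], dtype=int)


def close(
    raw_parts: Mapping[str, float] | Composition,
    total: float = DEFAULT_TOTAL,
    *,
    offset: float = 0.0,
) -> Composition:
    """Rescale positive raw parts so they sum to ``total``.

    Parameters
    ----------
    raw_parts
        Mapping label -> nonnegative minutes, or an existing composition.
    total
        Closure constant (minutes).
    offset
        Optional additive offset applied to every part *before* closure,
        for degenerate inputs with structural zeros (e.g. synthetic rows).
        Default 0 (off): zero parts raise :class:`ZeroPartError` because the
        day-level inclusion filters guarantee positive parts in real data.
    """
    if isinstance(raw_parts, Composition):
        items = list(raw_parts.as_dict().items())
    else:
        items = list(raw_parts.items())
    if len(items) < 2:
        raise ValueError("a composition needs at least 2 parts")
    labels = tuple(lab for lab, _ in items)
    raw = np.array([v for _, v in items], dtype=float) + offset
    for lab, v in zip(labels, raw):
        if not v > 0:
            raise ZeroPartError(
                f"part {lab!r} is {v - offset} before closure; zero-handling is the "
                "caller's job (see the `offset` option)"
            )
    return Composition(labels, raw * (total / raw.sum()), total)


def pivot_contrast_matrix(n_parts: int) -> np.ndarray:
    """Orthonormal (D-1, D) contrast matrix V with z = V @ ln(x).

    Row k (0-based) contrasts part k against the geometric mean of parts
    k+1..D-1.  Rows are orthonormal and sum to zero, so V @ V.T = I and the
    map is invariant to rescaling x.
    """
    D = n_parts
    V = np.zeros((D - 1, D))
    for k in range(D - 1):
        r = D - k - 1  # parts remaining after the pivot at position k
        c = np.sqrt(r / (r + 1.0))
        V[k, k] = c
        V[k, k + 1 :] = -c / r
    return V


@dataclass(frozen=True)
class IlrVector:
    """Ilr pivot coordinates (length D-1) together with their pivot order."""

    coords: np.ndarray
    order: PivotOrder

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 1 or coords.size != self.order.n_parts - 1:
            raise ValueError(
                f"need {self.order.n_parts - 1} coordinates, got shape {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("ilr coordinates must be finite")


def ilr_pivot(x: Composition, order: PivotOrder) -> IlrVector:
    """Ilr pivot coordinates of ``x`` with parts taken in ``order``."""
    idx = _permutation(x.labels, order.labels)
    V = pivot_contrast_matrix(x.n_parts)
    return IlrVector(V @ np.log(x.minutes[idx]), order)


def ilr_inverse(
    z: IlrVector, total: float = DEFAULT_TOTAL, labels: Sequence[str] | None = None
) -> Composition:
    """Composition whose pivot coordinates are ``z``, closed to ``total``.

    ``labels`` optionally fixes the part order of the result (defaults to the
    pivot order's own sequence).
    """
    coords = np.asarray(z.coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("ilr coordinates must be finite")
    V = pivot_contrast_matrix(z.order.n_parts)
    x = np.exp(V.T @ coords)
    comp = Composition(z.order.labels, x * (total / x.sum()), total)
    return comp.reorder(labels) if labels is not None else comp


def rotation_matrix(old: PivotOrder, new: PivotOrder) -> np.ndarray:
    """Orthogonal Q mapping coordinates in ``old`` basis to ``new``: z' = Q z."""
    P = np.zeros((old.n_parts, old.n_parts))
    idx = _permutation(old.labels, new.labels)
    P[np.arange(old.n_parts), idx] = 1.0
    V = pivot_contrast_matrix(old.n_parts)
    return V @ P @ V.T


def rotate_basis(z: IlrVector, new_order: PivotOrder) -> IlrVector:
    """Re-express ilr coordinates in another pivot order (a linear isometry)."""
    Q = rotation_matrix(z.order, new_order)
    return IlrVector(Q @ z.coords, new_order)


def geometric_center(xs: Sequence[Composition] | Iterable[Composition]) -> Composition:
    """Closed per-part geometric mean; the Aitchison mean of the set.

    Equals ilr_inverse(arithmetic mean of the ilr vectors) for any basis.
    """
    xs = list(xs)
    if not xs:
        raise ValueError("geometric_center of an empty set")
    ref = xs[0]
    logs = np.stack([x.reorder(ref.labels).minutes for x in xs])
    g = np.exp(np.log(logs).mean(axis=0))
    return Composition(ref.labels, g * (ref.total / g.sum()), ref.total)


def aitchison_distance(x: Composition, y: Composition) -> float:
    """Aitchison distance, computed as the clr-difference Euclidean norm."""
    ly = np.log(y.reorder(x.labels).minutes)
    lx = np.log(x.minutes)
    dx = lx - lx.mean()
    dy = ly - ly.mean()
    return float(np.linalg.norm(dx - dy))


# -- array fast paths (rows = observations, columns in a fixed label order) --

def ilr_array(minutes: np.ndarray, V: np.ndarray | None = None) -> np.ndarray:
    """Pivot ilr of each row of a positive (n, D) array."""
    minutes = np.asarray(minutes, dtype=float)
    if V is None:
        V = pivot_contrast_matrix(minutes.shape[-1])
    return np.log(minutes) @ V.T


def ilr_inverse_array(
    coords: np.ndarray, total: float = DEFAULT_TOTAL, V: np.ndarray | None = None
) -> np.ndarray:
    """Rows of compositions (closed to ``total``) from (n, D-1) coordinates."""
    coords = np.asarray(coords, dtype=float)
    if V is None:
        V = pivot_contrast_matrix(coords.shape[-1] + 1)
    x = np.exp(coords @ V)
    return x * (total / x.sum(axis=-1, keepdims=True))
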