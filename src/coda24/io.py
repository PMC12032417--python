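"""Data ingestion, day-level validity filters, and the end-to-end pipeline.

CSV dialect: long format, one row per participant-day, UTF-8 with header:

    pid, day, sleep_min, sedentary_min, standing_min, lpa_min, mvpa_min,
    wear_h, walk_detected, valence, energetic_arousal, calmness,
    working_memory, age, sex, bmi[, n_ratings]

Day-level inclusion filters mirror the accelerometer validity rules: a valid
day needs >= 20 h of wear, > 0 min of sleep and at least one detected walking
period; participants keep their data only with >= 3 valid days.  An optional
minimum number of affect ratings per day supports the sensitivity analysis.
Every excluded day is logged with a reason code, never dropped silently.
"""

from __future__ import annotations

import json
import logging
import time
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .composition import DEFAULT_LABELS, PivotOrder, pivot_order
from .decomposition import (
    decompose,
    part_columns,
    sample_reference_composition,
)
from .model import ModelSpec, build_design, fit, summarize
from .substitution import substitution_grid, substitution_matrix

__all__ = [
    "RunConfig",
    "ReadError",
    "read_and_filter",
    "shift_outcome_next_day",
    "run_analysis",
]

logger = logging.getLogger("coda24")

DEFAULT_OUTCOMES = ("valence", "energetic_arousal", "calmness", "working_memory")

REQUIRED_COLUMNS = (
    ("pid", "day")
    + part_columns(DEFAULT_LABELS)
    + ("wear_h", "walk_detected", "age", "sex", "bmi")
)


class ReadError(ValueError):
    """Malformed input table."""


@dataclass(frozen=True)
class RunConfig:
    """Everything one analysis run needs; loadable from YAML."""

    input_path: str | None = None
    outcomes: tuple[str, ...] = DEFAULT_OUTCOMES
    report_pivots: tuple[str, ...] = ("mvpa", "sedentary")
    min_wear_h: float = 20.0
    min_valid_days: int = 3
    require_sleep: bool = True
    require_walk: bool = True
    min_ratings: int | None = None
    timing: tuple[str, ...] = ("concurrent",)  # and/or "prospective"
    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    grid_max_minutes: int = 60
    matrix_minutes: float = 30.0
    seed: int = 0
    outdir: str = "coda24_out"

    def __post_init__(self) -> None:
        if not self.outcomes:
            raise ValueError("outcome list must be non-empty")
        if self.min_wear_h <= 0 or self.min_valid_days <= 0:
            raise ValueError("filter thresholds must be positive")
        bad = set(self.timing) - {"concurrent", "prospective"}
        if bad:
            raise ValueError(f"unknown timing mode(s): {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("outcomes", "report_pivots", "timing"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def read_and_filter(
    path: str | Path | pd.DataFrame, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load a participant-day CSV and apply the day-level validity filters.

    Returns ``(retained, exclusions)``; the exclusion log has one row per
    removed day with columns ``pid, day, reason``.  Retained day count plus
    exclusion count always equals the input day count.
    """
    df = path.copy() if isinstance(path, pd.DataFrame) else pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ReadError(f"missing required columns: {missing}")
    if df.duplicated(["pid", "day"]).any():
        dup = df[df.duplicated(["pid", "day"])][["pid", "day"]].iloc[0]
        raise ReadError(f"duplicate participant-day: {tuple(dup)}")
    parts = df[list(part_columns(DEFAULT_LABELS))].to_numpy(float)
    if np.any(parts < 0):
        raise ReadError("negative minutes in composition columns")

    reasons = pd.Series("", index=df.index, dtype=object)
    wear_bad = df["wear_h"] < config.min_wear_h
    reasons[wear_bad] = f"wear_below_{config.min_wear_h:g}h"
    if config.require_sleep:
        sleep_bad = (df["sleep_min"] <= 0) & (reasons == "")
        reasons[sleep_bad] = "no_sleep"
    if config.require_walk:
        walk_bad = (~df["walk_detected"].astype(bool)) & (reasons == "")
        reasons[walk_bad] = "no_walking_detected"
    if config.min_ratings is not None:
        if "n_ratings" not in df.columns:
            raise ReadError("min_ratings filter requires an n_ratings column")
        nr_bad = (df["n_ratings"] < config.min_ratings) & (reasons == "")
        reasons[nr_bad] = f"fewer_than_{config.min_ratings}_ratings"

    valid = reasons == ""
    counts = df.loc[valid, "pid"].value_counts()
    short = counts[counts < config.min_valid_days].index
    too_few = valid & df["pid"].isin(short)
    reasons[too_few] = f"participant_below_{config.min_valid_days}_valid_days"
    valid = reasons == ""

    exclusions = (
        df.loc[~valid, ["pid", "day"]]
        .assign(reason=reasons[~valid])
        .reset_index(drop=True)
    )
    retained = df.loc[valid].reset_index(drop=True)
    logger.info(
        "read_and_filter: %d days in, %d retained, %d excluded (%d participants kept)",
        len(df), len(retained), len(exclusions), retained["pid"].nunique(),
    )
    return retained, exclusions


def shift_outcome_next_day(
    data: pd.DataFrame, outcomes: Sequence[str] | str
) -> pd.DataFrame:
    """Pair each day's composition with the *next* day's outcome(s).

    The same-day outcome value is kept as ``{outcome}_lag`` (it is the
    previous-day outcome relative to the shifted outcome), so the lag
    adjustment stays coherent in prospective models.  Days without an
    adjacent next day (end of participation, or an index gap such as a
    weekend break) are dropped.
    """
    if isinstance(outcomes, str):
        outcomes = [outcomes]
    for o in outcomes:
        if o not in data.columns:
            raise ValueError(f"outcome {o!r} not in data")
    nxt = data[["pid", "day"] + list(outcomes)].copy()
    nxt["day"] = nxt["day"] - 1  # align next-day outcome onto today's row
    out = data.copy()
    out = out.rename(columns={o: f"{o}_lag" for o in outcomes})
    out = out.merge(nxt, on=["pid", "day"], how="inner")
    return out.reset_index(drop=True)


def run_analysis(config: RunConfig, data: pd.DataFrame | None = None) -> dict:
    """Full pipeline: filter, decompose, fit, summarize, substitution grids.

    Writes per outcome x timing: a coefficient table (both report pivots), a
    1..60-min substitution grid, 30-min matrix views per level, and a
    diagnostics summary; plus an exclusion log and a JSON run manifest.
    Returns a result bundle dict with the same objects in memory; the
    ``converged`` entry is False if any fit failed the convergence gates.
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if data is None:
        if config.input_path is None:
            raise ValueError("run_analysis needs input_path or an in-memory table")
        data = pd.read_csv(config.input_path)
    retained, exclusions = read_and_filter(data, config)
    exclusions.to_csv(outdir / "exclusions.csv", index=False)

    fit_order = pivot_order("mvpa", DEFAULT_LABELS)
    report_orders = [pivot_order(p, DEFAULT_LABELS) for p in config.report_pivots]
    reference = sample_reference_composition(retained)
    bundle: dict = {
        "reference_composition": reference,
        "exclusions": exclusions,
        "fits": {},
        "converged": True,
    }
    for timing in config.timing:
        table = (
            retained
            if timing == "concurrent"
            else shift_outcome_next_day(retained, [o for o in config.outcomes])
        )
        dec = decompose(table, fit_order)
        for outcome in config.outcomes:
            tag = f"{outcome}_{timing}"
            spec = ModelSpec(
                outcome=outcome,
                order=fit_order,
                chains=config.chains,
                iterations=config.iterations,
                warmup=config.warmup,
                seed=config.seed,
            )
            design = build_design(dec, spec)
            draws, diag = fit(design, spec)
            coef = summarize(draws, report_orders)
            grid_minutes = sorted(
                set(range(1, config.grid_max_minutes + 1)) | {config.matrix_minutes}
            )
            grid = substitution_grid(draws, reference, minutes_grid=grid_minutes)
            coef.to_csv(outdir / f"coefficients_{tag}.csv", index=False)
            grid.to_csv(outdir / f"substitution_grid_{tag}.csv", index=False)
            for level in ("between", "within"):
                substitution_matrix(grid, level, config.matrix_minutes).to_csv(
                    outdir / f"substitution_matrix_{config.matrix_minutes:g}min_{level}_{tag}.csv"
                )
            diag.table.to_csv(outdir / f"diagnostics_{tag}.csv", index=False)
            bundle["fits"][tag] = {
                "draws": draws,
                "diagnostics": diag,
                "coefficients": coef,
                "substitution_grid": grid,
                "design_rows": len(design),
            }
            bundle["converged"] &= diag.converged
            logger.info(
                "fit %s: n=%d rows, converged=%s (max Rhat %.3f, min ESS %.0f)",
                tag, len(design), diag.converged, diag.max_rhat, diag.min_ess,
            )

    manifest = {
        "seed": config.seed,
        "n_days_in": int(len(data)),
        "n_days_retained": int(len(retained)),
        "n_participants": int(retained["pid"].nunique()),
        "outcomes": list(config.outcomes),
        "timing": list(config.timing),
        "reference_composition_min": reference.as_dict(),
        "converged": bool(bundle["converged"]),
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    bundle["manifest"] = manifest
    return bundle
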