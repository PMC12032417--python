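"""Design construction, Gibbs fitting, summaries, and model invariants."""

import warnings

import numpy as np
import pandas as pd
import pytest

from coda24.composition import DEFAULT_LABELS, pivot_order, rotation_matrix
from coda24.decomposition import decompose
from coda24.model import (
    ModelSpec,
    PriorConfig,
    build_design,
    fit,
    summarize,
)
from coda24.synthetic import GeneratorConfig, generate

ORDER = pivot_order("mvpa")


def _complete_data(n_participants, days, seed):
    cfg = GeneratorConfig(
        n_participants=n_participants,
        days_fixed=days,
        seed=seed,
        missing_outcome_rate=0.0,
    )
    return generate(cfg)


class TestBuildDesign:
    def test_row_count_and_columns(self):
        data, _ = _complete_data(3, 4, 0)
        dec = decompose(data, ORDER)
        spec = ModelSpec(outcome="valence")
        design = build_design(dec, spec)
        # first day per participant has no lag -> 3 x (4 - 1) rows
        assert len(design) == 9
        assert design.groupby("pid")["day"].min().eq(2).all()
        # design matrix: intercept + 2(D-1) coords + covariates
        n_cols = 1 + 2 * (len(DEFAULT_LABELS) - 1) + len(spec.covariates)
        assert len(design.columns) - 3 + 1 == n_cols  # pid, day, y replaced by 1

    def test_missing_outcome_day_still_feeds_person_mean(self):
        data, _ = _complete_data(3, 4, 1)
        data.loc[data.index[1], "valence"] = np.nan
        dec = decompose(data, ORDER)
        design = build_design(dec, ModelSpec(outcome="valence"))
        # between coordinates still reflect all 4 compositions
        full_dec = decompose(data, ORDER)
        pid = data.loc[data.index[1], "pid"]
        expected = full_dec[full_dec.pid == pid][["bz1"]].iloc[0, 0]
        got = design[design.pid == pid]["bz1"].iloc[0]
        assert got == pytest.approx(expected, rel=1e-12)
        # the NaN day and its successor (missing lag) drop from model rows
        assert len(design[design.pid == pid]) == 1

    def test_unknown_outcome_rejected(self):
        data, _ = _complete_data(3, 4, 0)
        dec = decompose(data, ORDER)
        with pytest.raises(ValueError, match="outcome"):
            build_design(dec, ModelSpec(outcome="mood"))

    def test_sex_coded_binary_and_continuous_centered(self):
        data, _ = _complete_data(6, 5, 2)
        dec = decompose(data, ORDER)
        design = build_design(dec, ModelSpec(outcome="calmness"))
        assert set(np.unique(design["sex"])) <= {0.0, 1.0}
        assert design["age"].mean() == pytest.approx(0.0, abs=1e-9)


class TestFit:
    def test_seed_determinism(self, small_decomposed):
        spec = ModelSpec(outcome="valence", chains=2, iterations=300, warmup=150, seed=9)
        design = build_design(small_decomposed, spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d1, _ = fit(design, spec)
            d2, _ = fit(design, spec)
        np.testing.assert_array_equal(d1.beta0, d2.beta0)
        np.testing.assert_array_equal(d1.sigma, d2.sigma)
        np.testing.assert_array_equal(d1.ranef, d2.ranef)

    def test_draw_count_contract(self, small_fit):
        _, draws, _ = small_fit
        assert draws.beta0.shape == (2, 400)
        assert draws.n_draws == 800
        assert (draws.stacked("sigma") > 0).all()
        assert (draws.stacked("tau_within") >= 0).all()

    def test_ols_limit_with_flat_priors(self, small_decomposed):
        """Without random effects and with flat priors the posterior mean
        must agree with ordinary least squares on the same design."""
        spec = ModelSpec(
            outcome="valence", chains=2, iterations=2000, warmup=500, seed=3,
            random_effects=False, priors=PriorConfig(beta_scale=1e5),
        )
        design = build_design(small_decomposed, spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws, _ = fit(design, spec)
        cols = (
            [f"bz{k}" for k in range(1, 5)]
            + [f"wz{k}" for k in range(1, 5)]
            + list(design.attrs["covariate_columns"])
        )
        X = np.column_stack([np.ones(len(design))] + [design[c] for c in cols])
        ols = np.linalg.lstsq(X, design["y"].to_numpy(), rcond=None)[0]
        post = np.concatenate(
            [
                [draws.stacked("beta0").mean()],
                draws.stacked("beta_between").mean(0),
                draws.stacked("beta_within").mean(0),
                draws.stacked("gamma").mean(0),
            ]
        )
        mcse = (
            np.concatenate(
                [
                    [draws.stacked("beta0").std()],
                    draws.stacked("beta_between").std(0),
                    draws.stacked("beta_within").std(0),
                    draws.stacked("gamma").std(0),
                ]
            )
            / np.sqrt(draws.n_draws)
        )
        assert np.all(np.abs(post - ols) < 3 * mcse * np.sqrt(draws.n_draws / 400))

    def test_prediction_invariant_to_fit_basis(self, small_data):
        """Fitting in MVPA-first vs sedentary-first bases gives the same
        fitted values up to Monte-Carlo error (orthogonal reparameterisation)."""
        data, _ = small_data
        results = {}
        for first in ("mvpa", "sedentary"):
            order = pivot_order(first)
            dec = decompose(data, order)
            spec = ModelSpec(
                outcome="valence", order=order, chains=2,
                iterations=700, warmup=300, seed=5,
            )
            design = build_design(dec, spec)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                draws, _ = fit(design, spec)
            cols = [f"bz{k}" for k in range(1, 5)] + [f"wz{k}" for k in range(1, 5)]
            M = design[cols].to_numpy()
            coef = np.concatenate(
                [
                    draws.stacked("beta_between").mean(0),
                    draws.stacked("beta_within").mean(0),
                ]
            )
            results[first] = (
                draws.stacked("beta0").mean() + M @ coef,
                draws.stacked("sigma").mean(),
            )
        yhat_m, sig = results["mvpa"]
        yhat_s, _ = results["sedentary"]
        assert np.abs(yhat_m - yhat_s).max() < 0.15 * sig


class TestSummarize:
    def test_scalar_interval_from_known_draws(self):
        x = np.array([1.0, 2.0, 3.0])
        assert x.mean() == 2.0
        np.testing.assert_allclose(
            np.percentile(x, [2.5, 97.5]), [1.05, 2.95]
        )

    def test_identity_report_matches_raw_draws(self, small_fit):
        _, draws, _ = small_fit
        table = summarize(draws, [draws.order])
        b1 = draws.stacked("beta_within")[:, 0]
        row = table[
            (table.parameter == "ilr[mvpa_vs_remaining]") & (table.level == "within")
        ].iloc[0]
        assert row["mean"] == pytest.approx(b1.mean(), rel=1e-12)
        assert row["lower"] == pytest.approx(np.percentile(b1, 2.5), rel=1e-9)
        assert bool(row["significant"]) == (row["lower"] > 0 or row["upper"] < 0)

    def test_rotated_first_coordinate_uses_orthogonal_map(self, small_fit):
        _, draws, _ = small_fit
        sed = pivot_order("sedentary")
        table = summarize(draws, [sed])
        Q = rotation_matrix(draws.order, sed)
        expected = (draws.stacked("beta_between") @ Q.T)[:, 0].mean()
        row = table[
            (table.parameter == "ilr[sedentary_vs_remaining]")
            & (table.level == "between")
        ].iloc[0]
        assert row["mean"] == pytest.approx(expected, rel=1e-12)

    def test_interval_brackets_mean(self, small_fit):
        _, draws, _ = small_fit
        table = summarize(draws, [draws.order, pivot_order("sedentary")])
        assert (table["lower"] <= table["mean"]).all()
        assert (table["mean"] <= table["upper"]).all()
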