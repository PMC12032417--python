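"""Aitchison-geometry primitives: closure, pivot ilr, rotation, centering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coda24.composition import (
    DEFAULT_LABELS,
    Composition,
    ZeroPartError,
    aitchison_distance,
    close,
    geometric_center,
    ilr_inverse,
    ilr_pivot,
    pivot_order,
    rotate_basis,
    rotation_matrix,
)
from conftest import random_compositions

SAMPLE_MEAN_HOURS = dict(
    zip(DEFAULT_LABELS, (7.95, 10.5, 2.79, 1.15, 1.35))
)
SAMPLE_MEAN_MIN = {k: v * 60.0 for k, v in SAMPLE_MEAN_HOURS.items()}

# pivot ilr of the closed sample mean composition (MVPA-first order),
# frozen from a 40-digit mpmath evaluation of the pivot formula
SAMPLE_MEAN_ILR_MVPA_FIRST = np.array(
    [-0.98161871606991692, 0.78009749448973625, 1.4439525564617165, 0.62669435298789689]
)


def mp_pivot_ilr(minutes_in_order):
    """Independent arbitrary-precision pivot-coordinate oracle (mpmath)."""
    from mpmath import mp, mpf, log, sqrt

    mp.dps = 30
    x = [mpf(str(v)) for v in minutes_in_order]
    D = len(x)
    out = []
    for k in range(D - 1):
        r = D - k - 1
        gm = mp.exp(sum(log(xi) for xi in x[k + 1 :]) / r)
        out.append(float(sqrt(mpf(r) / (r + 1)) * log(x[k] / gm)))
    return np.array(out)


class TestClose:
    def test_scales_sample_mean_to_full_day(self):
        c = close(SAMPLE_MEAN_MIN)
        raw_sum = sum(SAMPLE_MEAN_MIN.values())  # 1424.4
        for lab, v in SAMPLE_MEAN_MIN.items():
            assert c[lab] == pytest.approx(v * 1440.0 / raw_sum, rel=1e-12)
        assert c.minutes.sum() == pytest.approx(1440.0)

    def test_identity_when_already_closed(self):
        raw = {"a": 700.0, "b": 740.0}
        c = close(raw)
        assert c.as_dict() == pytest.approx(raw)

    def test_uniform_symmetry(self):
        c = close({lab: 1.0 for lab in DEFAULT_LABELS})
        assert np.allclose(c.minutes, 288.0)

    def test_idempotent(self):
        c = close(SAMPLE_MEAN_MIN)
        assert close(c).isclose(c, atol=1e-12)

    def test_zero_part_rejected_with_name(self):
        with pytest.raises(ZeroPartError, match="mvpa"):
            close({**SAMPLE_MEAN_MIN, "mvpa": 0.0})

    def test_offset_rescues_zero_parts(self):
        c = close({**SAMPLE_MEAN_MIN, "mvpa": 0.0}, offset=0.5)
        assert c["mvpa"] > 0


class TestIlrPivot:
    def test_uniform_composition_maps_to_zero(self):
        c = close({lab: 288.0 for lab in DEFAULT_LABELS})
        for first in DEFAULT_LABELS:
            z = ilr_pivot(c, pivot_order(first))
            assert np.allclose(z.coords, 0.0, atol=1e-12)

    def test_two_part_closed_form(self):
        t = 500.0
        c = Composition(("a", "b"), np.array([t, 1440.0 - t]))
        z = ilr_pivot(c, pivot_order("a", ("a", "b")))
        assert z.coords[0] == pytest.approx(
            np.sqrt(0.5) * np.log(t / (1440.0 - t)), rel=1e-14
        )

    def test_sample_mean_matches_frozen_high_precision_values(self):
        c = close(SAMPLE_MEAN_MIN)
        z = ilr_pivot(c, pivot_order("mvpa"))
        np.testing.assert_allclose(z.coords, SAMPLE_MEAN_ILR_MVPA_FIRST, atol=1e-12)

    def test_matches_arbitrary_precision_oracle_on_random_compositions(self):
        rng = np.random.default_rng(1)
        order = pivot_order("mvpa")
        idx = [DEFAULT_LABELS.index(l) for l in order.labels]
        for row in random_compositions(50, rng):
            c = Composition(DEFAULT_LABELS, row)
            expected = mp_pivot_ilr(row[idx])
            np.testing.assert_allclose(
                ilr_pivot(c, order).coords, expected, atol=1e-10
            )

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        row = random_compositions(1, rng)[0]
        big = Composition(DEFAULT_LABELS, row * 3.0, total=3 * 1440.0)
        small = Composition(DEFAULT_LABELS, row)
        order = pivot_order("sedentary")
        np.testing.assert_allclose(
            ilr_pivot(big, order).coords, ilr_pivot(small, order).coords, atol=1e-12
        )

    def test_first_coordinate_invariant_to_remaining_order(self):
        import itertools

        rng = np.random.default_rng(3)
        row = random_compositions(1, rng)[0]
        c = Composition(DEFAULT_LABELS, row)
        rest = [l for l in DEFAULT_LABELS if l != "mvpa"]
        z1s = {
            round(
                float(
                    ilr_pivot(
                        c, type(pivot_order("mvpa"))(("mvpa",) + perm)
                    ).coords[0]
                ),
                12,
            )
            for perm in itertools.permutations(rest)
        }
        assert len(z1s) == 1

    def test_isometry_with_aitchison_distance(self):
        rng = np.random.default_rng(4)
        X = random_compositions(20, rng)
        order = pivot_order("lpa")
        for a, b in zip(X[:10], X[10:]):
            ca, cb = Composition(DEFAULT_LABELS, a), Composition(DEFAULT_LABELS, b)
            d_ilr = np.linalg.norm(
                ilr_pivot(ca, order).coords - ilr_pivot(cb, order).coords
            )
            assert d_ilr == pytest.approx(aitchison_distance(ca, cb), abs=1e-9)


class TestIlrInverse:
    def test_zero_vector_gives_uniform(self):
        from coda24.composition import IlrVector

        c = ilr_inverse(IlrVector(np.zeros(4), pivot_order("mvpa")))
        assert np.allclose(c.minutes, 288.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-4, 4), min_size=4, max_size=4))
    def test_round_trip_from_coordinates(self, coords):
        from coda24.composition import IlrVector

        z = IlrVector(np.array(coords), pivot_order("sedentary"))
        back = ilr_pivot(ilr_inverse(z), z.order)
        np.testing.assert_allclose(back.coords, z.coords, atol=1e-10)

    def test_round_trip_from_random_compositions(self):
        rng = np.random.default_rng(5)
        order = pivot_order("mvpa")
        for row in random_compositions(1000, rng):
            c = Composition(DEFAULT_LABELS, row)
            back = ilr_inverse(ilr_pivot(c, order), labels=DEFAULT_LABELS)
            np.testing.assert_allclose(back.minutes, c.minutes, atol=1e-9)

    def test_first_coordinate_monotone_in_pivot_part(self):
        from coda24.composition import IlrVector

        order = pivot_order("mvpa")
        grid = np.linspace(-2, 2, 41)
        mvpa = [
            ilr_inverse(IlrVector(np.array([z1, 0.3, -0.2, 0.1]), order))["mvpa"]
            for z1 in grid
        ]
        assert np.all(np.diff(mvpa) > 0)


class TestRotateBasis:
    def test_identity_rotation(self):
        from coda24.composition import IlrVector

        z = IlrVector(np.array([0.5, -1.0, 0.2, 0.9]), pivot_order("mvpa"))
        np.testing.assert_allclose(
            rotate_basis(z, z.order).coords, z.coords, atol=1e-14
        )

    def test_rotation_matrix_is_orthogonal_and_invertible(self):
        o1, o2 = pivot_order("mvpa"), pivot_order("sedentary")
        Q = rotation_matrix(o1, o2)
        np.testing.assert_allclose(Q @ Q.T, np.eye(4), atol=1e-12)
        from coda24.composition import IlrVector

        z = IlrVector(np.array([1.2, 0.1, -0.7, 0.4]), o1)
        back = rotate_basis(rotate_basis(z, o2), o1)
        np.testing.assert_allclose(back.coords, z.coords, atol=1e-10)

    def test_agrees_with_inverse_then_forward_route(self):
        rng = np.random.default_rng(6)
        o1, o2 = pivot_order("mvpa"), pivot_order("standing")
        from coda24.composition import IlrVector

        for _ in range(100):
            z = IlrVector(rng.normal(0, 1.5, 4), o1)
            via_simplex = ilr_pivot(ilr_inverse(z), o2)
            np.testing.assert_allclose(
                rotate_basis(z, o2).coords, via_simplex.coords, atol=1e-10
            )


class TestGeometricCenter:
    def test_single_and_duplicate(self):
        c = close(SAMPLE_MEAN_MIN)
        assert geometric_center([c]).isclose(c, atol=1e-9)
        assert geometric_center([c, c]).isclose(c, atol=1e-9)

    def test_agrees_with_ilr_mean_route(self):
        rng = np.random.default_rng(7)
        order = pivot_order("mvpa")
        comps = [Composition(DEFAULT_LABELS, r) for r in random_compositions(30, rng)]
        center = geometric_center(comps)
        z_mean = np.mean([ilr_pivot(c, order).coords for c in comps], axis=0)
        from coda24.composition import IlrVector

        via_ilr = ilr_inverse(IlrVector(z_mean, order), labels=DEFAULT_LABELS)
        np.testing.assert_allclose(center.minutes, via_ilr.minutes, atol=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            geometric_center([])
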