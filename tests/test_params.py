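"""Tests for the composite-parameter algebra and regime builders."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfqnet.network import NetworkSpec
from hfqnet.params import (REGIMES, association_from_y, build_scheme,
                           compute_y_metrics, dissociation_from_y)

log_y = st.floats(min_value=-6.0, max_value=6.0)


def _pair_spec(k1, kn1, k2, kn2, k3, kn3, k4, kn4, k5=1.0):
    return NetworkSpec(1, 1, 1.0, 1.0, 1.0, 1.0, k1, kn1, k2, kn2,
                       k3, kn3, k4, kn4, k5)


class TestComputeY:
    def test_all_ones(self):
        y = compute_y_metrics(_pair_spec(*[1.0] * 8))
        for name in ("y1", "y2", "y3", "y4", "y5", "y6", "y7"):
            assert getattr(y, name) == pytest.approx(1.0)

    def test_relative_affinity_regime(self):
        # k1 = k4 = 10^0.5, k2 = k3 = 10^4.5: strong mRNA affinity bias
        y = compute_y_metrics(_pair_spec(10**0.5, 0, 10**4.5, 0,
                                         10**4.5, 0, 10**0.5, 0))
        assert y.y1 == pytest.approx(1e4, rel=1e-10)
        assert y.y2 == pytest.approx(10**2.5, rel=1e-10)
        assert y.y3 == pytest.approx(1.0, rel=1e-10)
        assert y.y4 == pytest.approx(1.0, rel=1e-10)

    def test_cooperative_dissociation_values(self):
        y = compute_y_metrics(_pair_spec(1, 1e6, 1, 1e6, 1, 1e2, 1, 1e2))
        assert y.y5 == pytest.approx(1e4, rel=1e-10)
        assert y.y6 == pytest.approx(1e4, rel=1e-10)

    def test_zero_denominators_reported_as_nan(self):
        y = compute_y_metrics(_pair_spec(1, 0, 1, 0, 1, 0, 1, 0))
        assert math.isnan(y.y6) and math.isnan(y.y7)
        assert y.y5 == 0.0

    def test_single_pair_has_no_starred_constants(self):
        y = compute_y_metrics(_pair_spec(*[1.0] * 8))
        assert math.isnan(y.y8) and math.isnan(y.y9)


class TestAssociationInversion:
    @pytest.mark.parametrize("ys,expected", [
        ((1.0, 7.0, 1.0, 1.0), (7.0, 7.0, 7.0, 7.0)),
        ((1e4, 10**2.5, 1.0, 1.0), (10**0.5, 10**4.5, 10**4.5, 10**0.5)),
        ((1.0, 1.0, 1e4, 1e4), (1e-4, 1.0, 1.0, 1e4)),
    ])
    def test_known_solutions(self, ys, expected):
        np.testing.assert_allclose(association_from_y(*ys), expected, rtol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_log_linear_solve(self, seed):
        """Independent oracle: the four definitions are linear in log-space;
        solve the 4x4 system numerically and compare."""
        r = np.random.default_rng(seed)
        ys = 10 ** r.uniform(-4, 4, 4)
        # rows: y1, y2, y3, y4 definitions acting on (log k1..k4)
        A = np.array([[-0.5, 0.5, 0.5, -0.5],
                      [0.25, 0.25, 0.25, 0.25],
                      [-0.5, 0.5, -0.5, 0.5],
                      [-0.5, -0.5, 0.5, 0.5]])
        logk = np.linalg.solve(A, np.log10(ys))
        np.testing.assert_allclose(association_from_y(*ys), 10 ** logk, rtol=1e-8)

    def test_round_trip(self):
        ks = association_from_y(1e-3, 10**1.5, 1e2, 1e-2)
        y = compute_y_metrics(_pair_spec(ks[0], 0, ks[1], 0, ks[2], 0, ks[3], 0))
        np.testing.assert_allclose([y.y1, y.y2, y.y3, y.y4],
                                   [1e-3, 10**1.5, 1e2, 1e-2], rtol=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            association_from_y(0.0, 1.0, 1.0, 1.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(l1=log_y, l2=log_y, l3=log_y, l4=log_y)
    def test_round_trip_property(self, l1, l2, l3, l4):
        """Any positive (y1..y4) is realized exactly by the closed-form
        inversion: reading the y's back off the constants recovers them."""
        ys = (10.0 ** l1, 10.0 ** l2, 10.0 ** l3, 10.0 ** l4)
        k1, k2, k3, k4 = association_from_y(*ys)
        y = compute_y_metrics(_pair_spec(k1, 0, k2, 0, k3, 0, k4, 0))
        np.testing.assert_allclose([y.y1, y.y2, y.y3, y.y4], ys, rtol=1e-9)


class TestDissociationSplit:
    def test_no_cooperativity(self):
        assert dissociation_from_y(3.0, 1.0) == (3.0, 3.0, 3.0, 3.0)

    def test_no_dissociation(self):
        assert dissociation_from_y(0.0, 1.0) == (0.0, 0.0, 0.0, 0.0)

    def test_cooperative_split(self):
        np.testing.assert_allclose(dissociation_from_y(1e4, 1e4),
                                   (1e6, 1e6, 1e2, 1e2), rtol=1e-10)

    def test_inconsistent_combination_rejected(self):
        with pytest.raises(ValueError):
            dissociation_from_y(0.0, 10.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(l5=log_y, l6=log_y)
    def test_split_recovers_y5_y6(self, l5, l6):
        y5, y6 = 10.0 ** l5, 10.0 ** l6
        kn = dissociation_from_y(y5, y6)
        y = compute_y_metrics(_pair_spec(1, kn[0], 1, kn[1], 1, kn[2], 1, kn[3]))
        assert y.y5 == pytest.approx(y5, rel=1e-9)
        assert y.y6 == pytest.approx(y6, rel=1e-9)


class TestBuildScheme:
    def test_unknown_regime(self):
        with pytest.raises(ValueError, match="unknown regime"):
            build_scheme("nope")

    def test_unused_parameters_rejected(self):
        with pytest.raises(ValueError, match="unused"):
            build_scheme("independent_no_dissociation", y5=3.0)

    @pytest.mark.parametrize("regime,kw,requested", [
        ("independent_no_dissociation", dict(y1=1e4, y2=10**2.5),
         dict(y1=1e4, y2=10**2.5, y3=1.0, y4=1.0, y5=0.0)),
        ("cooperative_association", dict(y3=1e-4, y4=1e4, y5=1e4),
         dict(y1=1.0, y3=1e-4, y4=1e4, y5=1e4)),
        ("independent_with_dissociation", dict(y2=10**2.5, y5=1e4),
         dict(y2=10**2.5, y5=1e4, y6=1.0)),
        ("cooperative_dissociation", dict(y5=1e4, y6=1e4),
         dict(y5=1e4, y6=1e4)),
        ("network_uniform", dict(n=5, y9=1e4), dict(y9=1e4, y7=1.0, y8=1.0)),
        ("cognate_selection", dict(n=5, y7=1e-1, y9=1.0), dict(y7=1e-1, y9=1.0)),
        ("noncognate_exclusion", dict(n=5, y8=1e1, y9=1.0), dict(y8=1e1, y9=1.0)),
        ("unpartnered_pool", dict(y9=1e1, y8=1e1), dict(y8=1e1, y9=1e1)),
    ])
    def test_round_trip_recovers_requested_y(self, regime, kw, requested):
        spec = build_scheme(regime, **kw)
        y = compute_y_metrics(spec)
        for name, want in requested.items():
            got = getattr(y, name)
            assert got == pytest.approx(want, rel=1e-12), (regime, name)

    def test_independent_means_equal_branch_constants(self):
        spec = build_scheme("independent_no_dissociation", y1=1e4, y2=10**2.5)
        np.testing.assert_allclose(spec.k1, np.diag(spec.k4))
        np.testing.assert_allclose(spec.k2, np.diag(spec.k3))

    def test_positive_cooperative_association_raises_second_binding(self):
        spec = build_scheme("cooperative_association", y4=1e4)
        assert spec.k3[0, 0] > spec.k2[0] or spec.k4[0, 0] > spec.k1[0]

    def test_indiscriminate_k5_is_full(self):
        spec = build_scheme("indiscriminate", n=3, k5=1e3)
        np.testing.assert_allclose(spec.k5, np.full((3, 3), 1e3))

    def test_specific_pairing_k5_is_diagonal(self):
        spec = build_scheme("network_uniform", n=3, k5=1e3)
        np.testing.assert_allclose(spec.k5, np.diag([1e3] * 3))

    def test_unpartnered_pool_production(self):
        spec = build_scheme("unpartnered_pool", pool_factor=100.0)
        assert spec.n_srna == 1 and spec.m_mrna == 2
        assert spec.alpha_T[1] == pytest.approx(100.0 * spec.alpha_T[0])
        assert spec.k5[0, 1] == 0.0  # the pool species never forms duplexes

    def test_pool_affinity_tilt(self):
        spec = build_scheme("unpartnered_pool", affinity_ratio=1e-2)
        num = spec.k2[0] * spec.k3[0, 0] * spec.k3[0, 1]
        den = spec.k1[0] * spec.k4[0, 0] * spec.k4[0, 1]
        assert (num / den) ** (1 / 3) == pytest.approx(1e-2, rel=1e-10)

    def test_stable_unstable_mix(self):
        spec = build_scheme("stable_pairs", n_stable=2, n_unstable=3,
                            y9_stable=1.0, y9_unstable=1e4)
        assert spec.n_srna == 5
        np.testing.assert_allclose(spec.kneg1[:2], 1.0)
        np.testing.assert_allclose(spec.kneg1[2:], 1e4)
        # dissociation of a ternary follows the species that leaves
        assert spec.kneg4[4, 0] == pytest.approx(1e4)  # unstable sRNA leaving
        assert spec.kneg3[4, 0] == pytest.approx(1.0)  # stable mRNA leaving

    def test_two_pair_overproduction(self):
        spec = build_scheme("two_pair_overproduction", srna1_factor=10.0)
        assert spec.alpha_S[0] == pytest.approx(10.0 * spec.alpha_S[1])

    def test_imbalanced_pair_conserves_total_production(self):
        for ratio in (5.0, 1.0, 0.2):
            spec = build_scheme("imbalanced_pair", ratio=ratio)
            assert spec.alpha_S[0] + spec.alpha_T[0] == pytest.approx(2.0)
            assert spec.alpha_S[0] / spec.alpha_T[0] == pytest.approx(ratio)

    def test_s1_degradation_override(self):
        spec = build_scheme("s1_degradation", base="independent_with_dissociation",
                            y5=1.0)
        assert spec.beta_overrides == {"S": 10.0}

    def test_every_regime_is_buildable(self):
        for regime in REGIMES:
            assert build_scheme(regime).n_srna >= 1
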