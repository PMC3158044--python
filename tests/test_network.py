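"""Unit and property tests for the reaction-network data model."""

import numpy as np
import pytest

from hfqnet.network import (NetworkSpec, StateVector, count_complex_types,
                            derivatives, derivatives_flat, jacobian_flat,
                            state_dimension)

from conftest import make_random_spec


@pytest.mark.parametrize("n,m,expected", [(1, 1, 7), (5, 5, 71), (2, 3, 23)])
def test_state_dimension(n, m, expected):
    spec = make_random_spec(np.random.default_rng(0), n, m)
    assert state_dimension(spec) == expected


class TestComplexTypeCounts:
    @pytest.mark.parametrize("n,shared,expected", [
        (5, False, {"singly_bound": 10, "cognate_ternary": 5, "noncognate_ternary": 20}),
        (1, False, {"singly_bound": 2, "cognate_ternary": 1, "noncognate_ternary": 0}),
        (3, True, {"singly_bound": 6, "cognate_ternary": 3, "noncognate_ternary": 15}),
    ])
    def test_examples(self, n, shared, expected):
        assert count_complex_types(n, n, shared_sites=shared) == expected

    def test_rejects_rectangular(self):
        with pytest.raises(ValueError):
            count_complex_types(2, 3)

    @pytest.mark.parametrize("n", range(1, 7))
    def test_matches_enumeration(self, n):
        """Counts agree with explicit enumeration of two-slot Hfq occupancies.

        Separate sites: the sRNA slot holds one of n species, the mRNA slot
        one of n; mixed pairs with i != j are non-cognate.  Shared sites:
        both slots accept either RNA class, so same-class occupancies become
        possible; enumerating ordered slot assignments and halving for the
        slot orientation reproduces the 2n^2 - n arithmetic.
        """
        got = count_complex_types(n, n, shared_sites=False)
        mixed = [(i, j) for i in range(n) for j in range(n)]
        assert got["cognate_ternary"] == sum(1 for i, j in mixed if i == j)
        assert got["noncognate_ternary"] == sum(1 for i, j in mixed if i != j)
        assert got["singly_bound"] == len([("S", i) for i in range(n)]
                                          + [("T", j) for j in range(n)])

        got_shared = count_complex_types(n, n, shared_sites=True)
        rnas = [("S", i) for i in range(n)] + [("T", j) for j in range(n)]
        ordered = [(a, b) for a in rnas for b in rnas]
        cognate = [(a, b) for a, b in ordered
                   if {a[0], b[0]} == {"S", "T"} and a[1] == b[1]]
        assert got_shared["noncognate_ternary"] == (len(ordered) - len(cognate)) // 2
        assert got_shared["cognate_ternary"] == len(cognate) // 2

    def test_combinatorial_threshold(self):
        """Non-cognate ternary types first outnumber singly-bound plus
        cognate types at n = 5."""
        def excess(n):
            c = count_complex_types(n, n)
            return c["noncognate_ternary"] - (c["singly_bound"] + c["cognate_ternary"])
        crossing = next(n for n in range(1, 50) if excess(n) > 0)
        assert crossing == 5


class TestDerivatives:
    def test_zero_state_gives_production_vector(self):
        spec = make_random_spec(np.random.default_rng(1), 2, 3)
        d = derivatives(spec, StateVector.zeros(spec))
        assert d.H == pytest.approx(spec.alpha_H)
        np.testing.assert_allclose(d.S, spec.alpha_S)
        np.testing.assert_allclose(d.T, spec.alpha_T)
        assert np.all(d.HS == 0) and np.all(d.HT == 0)
        assert np.all(d.HST == 0) and np.all(d.D == 0)

    def test_hfq_only_closed_form(self):
        spec = NetworkSpec(1, 1, alpha_H=3.0, alpha_S=0.0, alpha_T=0.0, beta=1.5,
                           k1=1, kneg1=0, k2=1, kneg2=0, k3=1, kneg3=0,
                           k4=1, kneg4=0, k5=1)
        st = StateVector.zeros(spec)
        st.H = spec.alpha_H / spec.beta
        assert derivatives(spec, st).H == pytest.approx(0.0, abs=1e-14)

    def test_dimension_mismatch_rejected(self):
        spec = make_random_spec(np.random.default_rng(2), 2, 2)
        with pytest.raises(ValueError):
            derivatives_flat(spec, np.zeros(5))

    @pytest.mark.parametrize("seed", range(4))
    def test_hfq_lineage_cancellation(self, seed):
        """Summed over H, HS, HT and HST, every binding/unbinding/annealing
        term cancels: the net rate is alpha_H minus degradation."""
        r = np.random.default_rng(seed)
        spec = make_random_spec(r, 3, 2)
        st = StateVector.from_flat(r.uniform(0, 3, state_dimension(spec)), spec)
        d = derivatives(spec, st)
        got = d.H + d.HS.sum() + d.HT.sum() + d.HST.sum()
        want = spec.alpha_H - spec.beta * (st.H + st.HS.sum() + st.HT.sum()
                                           + st.HST.sum())
        assert got == pytest.approx(want, rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_rna_lineage_cancellation(self, seed):
        r = np.random.default_rng(100 + seed)
        spec = make_random_spec(r, 2, 3)
        st = StateVector.from_flat(r.uniform(0, 3, state_dimension(spec)), spec)
        d = derivatives(spec, st)
        for i in range(spec.n_srna):
            got = d.S[i] + d.HS[i] + d.HST[i, :].sum() + d.D[i, :].sum()
            want = spec.alpha_S[i] - spec.beta * (st.S[i] + st.HS[i]
                                                  + st.HST[i, :].sum()
                                                  + st.D[i, :].sum())
            assert got == pytest.approx(want, rel=1e-12, abs=1e-12)
        for j in range(spec.m_mrna):
            got = d.T[j] + d.HT[j] + d.HST[:, j].sum() + d.D[:, j].sum()
            want = spec.alpha_T[j] - spec.beta * (st.T[j] + st.HT[j]
                                                  + st.HST[:, j].sum()
                                                  + st.D[:, j].sum())
            assert got == pytest.approx(want, rel=1e-12, abs=1e-12)

    def test_linear_in_production_at_fixed_state(self, rng):
        from dataclasses import replace
        spec = make_random_spec(rng, 2, 2)
        y = rng.uniform(0, 2, state_dimension(spec))
        spec2 = replace(spec, alpha_H=spec.alpha_H * 3, alpha_S=spec.alpha_S * 3,
                        alpha_T=spec.alpha_T * 3)
        d1 = derivatives_flat(spec, y)
        d2 = derivatives_flat(spec2, y)
        # difference is exactly the extra production, zero elsewhere
        diff = d2 - d1
        n, m = spec.n_srna, spec.m_mrna
        np.testing.assert_allclose(diff[0], 2 * spec.alpha_H, rtol=1e-12)
        np.testing.assert_allclose(diff[1:1 + n], 2 * spec.alpha_S, rtol=1e-12)
        np.testing.assert_allclose(diff[1 + n:1 + n + m], 2 * spec.alpha_T, rtol=1e-12)
        np.testing.assert_allclose(diff[1 + n + m:], 0, atol=1e-14)

    def test_role_symmetry_under_transposition(self, rng):
        """Swapping the sRNA and mRNA roles (with transposed rate tensors)
        transposes the derivative."""
        spec = make_random_spec(rng, 2, 3)
        tspec = NetworkSpec(
            n_srna=spec.m_mrna, m_mrna=spec.n_srna, alpha_H=spec.alpha_H,
            alpha_S=spec.alpha_T, alpha_T=spec.alpha_S, beta=spec.beta,
            k1=spec.k2, kneg1=spec.kneg2, k2=spec.k1, kneg2=spec.kneg1,
            k3=spec.k4.T, kneg3=spec.kneg4.T, k4=spec.k3.T, kneg4=spec.kneg3.T,
            k5=spec.k5.T)
        st = StateVector.from_flat(rng.uniform(0, 2, state_dimension(spec)), spec)
        tst = StateVector(st.H, st.T, st.S, st.HT, st.HS, st.HST.T, st.D.T)
        d = derivatives(spec, st)
        td = derivatives(tspec, tst)
        assert td.H == pytest.approx(d.H, rel=1e-12)
        np.testing.assert_allclose(td.S, d.T, rtol=1e-12)
        np.testing.assert_allclose(td.HS, d.HT, rtol=1e-12)
        np.testing.assert_allclose(td.HST, d.HST.T, rtol=1e-12)
        np.testing.assert_allclose(td.D, d.D.T, rtol=1e-12)

    @pytest.mark.parametrize("n,m", [(1, 1), (2, 3), (3, 3)])
    def test_jacobian_matches_finite_differences(self, n, m):
        r = np.random.default_rng(7)
        spec = make_random_spec(r, n, m, beta_overrides={"S": 2.0})
        y = r.uniform(0.1, 2.0, state_dimension(spec))
        J = jacobian_flat(spec, y)
        f0 = derivatives_flat(spec, y)
        eps = 1e-7
        Jfd = np.empty_like(J)
        for k in range(len(y)):
            yp = y.copy()
            yp[k] += eps
            Jfd[:, k] = (derivatives_flat(spec, yp) - f0) / eps
        np.testing.assert_allclose(J, Jfd, rtol=2e-5, atol=1e-4 * np.abs(J).max())


class TestSpecValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="k1"):
            NetworkSpec(1, 1, 1.0, 1.0, 1.0, 1.0, k1=-1, kneg1=0, k2=1, kneg2=0,
                        k3=1, kneg3=0, k4=1, kneg4=0, k5=1)

    def test_nonpositive_beta_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            NetworkSpec(1, 1, 1.0, 1.0, 1.0, 0.0, k1=1, kneg1=0, k2=1, kneg2=0,
                        k3=1, kneg3=0, k4=1, kneg4=0, k5=1)

    def test_wrong_matrix_shape_rejected(self):
        with pytest.raises(ValueError, match="k3"):
            NetworkSpec(2, 3, 1.0, 1.0, 1.0, 1.0, k1=1, kneg1=0, k2=1, kneg2=0,
                        k3=np.ones((3, 2)), kneg3=0, k4=1, kneg4=0, k5=1)

    def test_unknown_beta_role_rejected(self):
        with pytest.raises(ValueError, match="beta_overrides"):
            NetworkSpec(1, 1, 1.0, 1.0, 1.0, 1.0, k1=1, kneg1=0, k2=1, kneg2=0,
                        k3=1, kneg3=0, k4=1, kneg4=0, k5=1,
                        beta_overrides={"X": 2.0})

    def test_flat_round_trip(self, rng):
        spec = make_random_spec(rng, 2, 2)
        y = rng.uniform(0, 2, state_dimension(spec))
        st = StateVector.from_flat(y, spec)
        np.testing.assert_array_equal(st.to_flat(), y)
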