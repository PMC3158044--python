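"""Composite kinetic parameters (y1-y9) and named kinetic regimes.

The eight elementary rate constants of a cognate pair (k1..k4 associations,
k-1..k-4 dissociations) are awkward to reason about directly, so the model
is usually discussed in terms of composite, mostly unitless combinations:

* ``y1 = sqrt((k2*k3)/(k1*k4))`` -- relative affinity of mRNAs vs sRNAs for Hfq
* ``y2 = (k1*k2*k3*k4)**(1/4)`` -- overall association magnitude (conc^-1 time^-1)
* ``y3 = sqrt((k2*k4)/(k1*k3))`` -- branch bias (sRNA-first vs mRNA-first path)
* ``y4 = sqrt((k3*k4)/(k1*k2))`` -- cooperative association (>1 positive)
* ``y5 = (k-1*k-2*k-3*k-4)**(1/4)`` -- overall dissociation magnitude (time^-1)
* ``y6 = sqrt((k-1*k-2)/(k-3*k-4))`` -- cooperative dissociation (>1 positive)
* ``y7 = ((k1*k2*k-3*k-4)/(k-1*k-2*k3*k4))**(1/4)`` -- cognate selection (<1 selects)
* ``y8`` -- same form as y7 but over the starred (non-cognate) ternary
  constants; >1 means non-cognate exclusion
* ``y9 = (k-1*k-2*k-3*k*-3*k-4*k*-4)**(1/6)`` -- total RNA dissociation
  including the non-cognate routes (time^-1)

plus the duplex annealing-and-release rate ``k5`` (cognate / non-cognate).
:func:`build_scheme` constructs complete :class:`~hfqnet.network.NetworkSpec`
objects for the named regimes explored by the model, from a single pair with
independent binding up to networks with cooperativity, unstable pairs,
indiscriminate pairing, production imbalances and unpartnered mRNA pools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import NetworkSpec

__all__ = [
    "YParameters",
    "compute_y_metrics",
    "association_from_y",
    "dissociation_from_y",
    "build_scheme",
    "REGIMES",
]

#: Default production rate for every RNA species (concentration * time^-1).
#: With beta = 1 this puts the total of each RNA at 1, so "relative Hfq"
#: equals the Hfq production rate directly.
DEFAULT_ALPHA_RNA = 1.0
#: Default overall association magnitude (the center of the explored range).
DEFAULT_Y2 = 10**2.5
#: Default duplex annealing-and-release rate for cognate pairs.
DEFAULT_K5 = 1e3
#: Default global degradation/dilution rate.
DEFAULT_BETA = 1.0


def _geomean(*vals: float) -> float:
    logs = [math.log(v) for v in vals]
    return math.exp(sum(logs) / len(logs))


def _ratio(num: float, den: float) -> float:
    """num/den, or NaN when the denominator vanishes (undefined, not an error)."""
    if den == 0.0:
        return math.nan
    return num / den


@dataclass(frozen=True)
class YParameters:
    """The nine composite parameters plus the two k5 classes of a regime.

    Undefined ratios (a zero denominator, e.g. y6 in a no-dissociation
    scheme) are reported as NaN rather than raising.
    """

    y1: float
    y2: float
    y3: float
    y4: float
    y5: float
    y6: float
    y7: float
    y8: float
    y9: float
    k5_cognate: float
    k5_noncognate: float


def compute_y_metrics(spec: NetworkSpec,
                      focal_pair: tuple[int, int] = (0, 0),
                      noncognate_partner: int | None = None) -> YParameters:
    """Evaluate y1..y9 on the rate constants of one cognate pair.

    ``focal_pair = (i, j)`` selects the cognate constants; the starred
    (non-cognate) constants entering y8 and y9 are taken from the ternary
    complex of sRNA i with a designated non-cognate mRNA (by default the
    first index different from j).  For a single-pair network y8 and y9's
    starred factors are undefined and reported as NaN.
    """
    i, j = focal_pair
    k1, kn1 = float(spec.k1[i]), float(spec.kneg1[i])
    k2, kn2 = float(spec.k2[j]), float(spec.kneg2[j])
    k3, kn3 = float(spec.k3[i, j]), float(spec.kneg3[i, j])
    k4, kn4 = float(spec.k4[i, j]), float(spec.kneg4[i, j])

    y1 = math.sqrt(_ratio(k2 * k3, k1 * k4))
    y2 = _geomean(k1, k2, k3, k4) if min(k1, k2, k3, k4) > 0 else (k1 * k2 * k3 * k4) ** 0.25
    y3 = math.sqrt(_ratio(k2 * k4, k1 * k3))
    y4 = math.sqrt(_ratio(k3 * k4, k1 * k2))
    y5 = (kn1 * kn2 * kn3 * kn4) ** 0.25
    y6 = math.sqrt(_ratio(kn1 * kn2, kn3 * kn4))
    y7 = _ratio(k1 * k2 * kn3 * kn4, kn1 * kn2 * k3 * k4) ** 0.25 \
        if kn1 * kn2 * k3 * k4 != 0 else math.nan

    if noncognate_partner is None:
        noncognate_partner = next((jj for jj in range(spec.m_mrna) if jj != j), None)
    if noncognate_partner is None:
        y8 = math.nan
        y9 = math.nan
        k5_noncog = 0.0
    else:
        # starred constants: those of the designated non-cognate ternary
        # complex HS_i T_jnc (identical to HS_inc T_j in uniform networks)
        jnc = noncognate_partner
        k3s, kn3s = float(spec.k3[i, jnc]), float(spec.kneg3[i, jnc])
        k4s, kn4s = float(spec.k4[i, jnc]), float(spec.kneg4[i, jnc])
        y8 = _ratio(k1 * k2 * kn3s * kn4s, kn1 * kn2 * k3s * k4s) ** 0.25 \
            if kn1 * kn2 * k3s * k4s != 0 else math.nan
        y9 = (kn1 * kn2 * kn3 * kn3s * kn4 * kn4s) ** (1.0 / 6.0)
        k5_noncog = float(spec.k5[i, jnc])

    return YParameters(y1=y1, y2=y2, y3=y3, y4=y4, y5=y5, y6=y6,
                       y7=y7, y8=y8, y9=y9,
                       k5_cognate=float(spec.k5[i, j]),
                       k5_noncognate=k5_noncog)


def association_from_y(y1: float, y2: float, y3: float, y4: float
                       ) -> tuple[float, float, float, float]:
    """Unique elementary association constants realizing (y1, y2, y3, y4).

    The four definitions are log-linear in (k1..k4) with an invertible
    coefficient matrix, so the solution is closed-form::

        k1 = y2 / sqrt(y1*y3*y4)    k2 = y2 * sqrt(y1*y3/y4)
        k3 = y2 * sqrt(y1*y4/y3)    k4 = y2 * sqrt(y3*y4/y1)
    """
    for name, v in (("y1", y1), ("y2", y2), ("y3", y3), ("y4", y4)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    k1 = y2 / math.sqrt(y1 * y3 * y4)
    k2 = y2 * math.sqrt(y1 * y3 / y4)
    k3 = y2 * math.sqrt(y1 * y4 / y3)
    k4 = y2 * math.sqrt(y3 * y4 / y1)
    return k1, k2, k3, k4


def dissociation_from_y(y5: float, y6: float = 1.0
                        ) -> tuple[float, float, float, float]:
    """Dissociation constants from (y5, y6) under the symmetric convention.

    Two constraints cannot pin four constants; the convention used
    throughout is the symmetric split ``k-1 = k-2 = y5*sqrt(y6)`` and
    ``k-3 = k-4 = y5/sqrt(y6)``, which reproduces every case where the
    model pins all four equal (y6 = 1).  ``y5 = 0`` gives the
    no-dissociation scheme (all four zero) and then requires y6 = 1.
    """
    if y5 < 0:
        raise ValueError("y5 must be >= 0")
    if y6 <= 0:
        raise ValueError("y6 must be positive")
    if y5 == 0.0:
        if y6 != 1.0:
            raise ValueError("y5 = 0 (no dissociation) is inconsistent with y6 != 1")
        return 0.0, 0.0, 0.0, 0.0
    s = math.sqrt(y6)
    return y5 * s, y5 * s, y5 / s, y5 / s


# ---------------------------------------------------------------------------
# Named regimes
# ---------------------------------------------------------------------------

REGIMES = (
    "independent_no_dissociation",
    "cooperative_association",
    "independent_with_dissociation",
    "cooperative_dissociation",
    "cognate_selection",
    "noncognate_exclusion",
    "network_uniform",
    "stable_pairs",
    "unstable_pairs",
    "indiscriminate",
    "imbalanced_pair",
    "two_pair_overproduction",
    "unpartnered_pool",
    "s1_degradation",
)


def _uniform_network(n: int, *, k_assoc: float, k_dissoc: float, k5: float,
                     k5_matrix: str = "diagonal",
                     alpha_H: float = 1.0,
                     alpha_S=None, alpha_T=None,
                     beta: float = DEFAULT_BETA,
                     beta_overrides: dict | None = None) -> NetworkSpec:
    """n identical single-partner pairs, every elementary constant uniform."""
    if k5_matrix == "diagonal":
        k5m = np.diag(np.full(n, k5))
    elif k5_matrix == "full":
        k5m = np.full((n, n), k5)
    else:
        raise ValueError(f"unknown k5_matrix {k5_matrix!r}")
    return NetworkSpec(
        n_srna=n, m_mrna=n, alpha_H=alpha_H,
        alpha_S=DEFAULT_ALPHA_RNA if alpha_S is None else alpha_S,
        alpha_T=DEFAULT_ALPHA_RNA if alpha_T is None else alpha_T,
        beta=beta,
        k1=k_assoc, kneg1=k_dissoc, k2=k_assoc, kneg2=k_dissoc,
        k3=k_assoc, kneg3=k_dissoc, k4=k_assoc, kneg4=k_dissoc,
        k5=k5m, beta_overrides=beta_overrides or {},
    )


def _scale_diag(mat: np.ndarray, factor: float) -> np.ndarray:
    out = mat.copy()
    np.fill_diagonal(out, np.diag(out) * factor)
    return out


def _scale_offdiag(mat: np.ndarray, factor: float) -> np.ndarray:
    out = mat * factor
    np.fill_diagonal(out, np.diag(mat))
    return out


def build_scheme(regime: str, **params) -> NetworkSpec:
    """Build a fully populated :class:`NetworkSpec` for a named kinetic regime.

    Common keyword parameters (regime-dependent, all overridable):

    ``n``         network size (cognate pairs; default 1 or 5 for network regimes)
    ``y1..y9``    composite-parameter targets as defined in this module
    ``k5``        cognate duplex annealing-and-release rate (default 1e3)
    ``alpha_H``   Hfq production (default 1; usually swept afterwards)
    ``beta``      degradation/dilution rate (default 1)

    Raises ``ValueError`` for unknown regimes or inconsistent parameter
    combinations (e.g. y5 = 0 with y6 != 1).
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    p = dict(params)
    n = int(p.pop("n", 1))
    beta = float(p.pop("beta", DEFAULT_BETA))
    alpha_H = float(p.pop("alpha_H", 1.0))
    k5 = float(p.pop("k5", DEFAULT_K5))

    def finish(spec: NetworkSpec) -> NetworkSpec:
        if p:
            raise ValueError(f"unused parameters for regime {regime!r}: {sorted(p)}")
        return spec

    if regime == "independent_no_dissociation":
        # independent binding (k1 = k4, k2 = k3) forces y3 = y4 = 1
        y1 = float(p.pop("y1", 1.0))
        y2 = float(p.pop("y2", DEFAULT_Y2))
        alpha_rna = float(p.pop("alpha_rna", DEFAULT_ALPHA_RNA))
        k1, k2, k3, k4 = association_from_y(y1, y2, 1.0, 1.0)
        return finish(NetworkSpec(n, n, alpha_H, alpha_rna, alpha_rna,
                                  beta, k1, 0.0, k2, 0.0, k3, 0.0, k4, 0.0,
                                  np.diag(np.full(n, k5))))

    if regime == "cooperative_association":
        y1 = float(p.pop("y1", 1.0))
        y2 = float(p.pop("y2", DEFAULT_Y2))
        y3 = float(p.pop("y3", 1.0))
        y4 = float(p.pop("y4", 1.0))
        y5 = float(p.pop("y5", 0.0))
        y6 = float(p.pop("y6", 1.0))
        alpha_rna = float(p.pop("alpha_rna", DEFAULT_ALPHA_RNA))
        k1, k2, k3, k4 = association_from_y(y1, y2, y3, y4)
        kn1, kn2, kn3, kn4 = dissociation_from_y(y5, y6)
        return finish(NetworkSpec(n, n, alpha_H, alpha_rna, alpha_rna,
                                  beta, k1, kn1, k2, kn2, k3, kn3, k4, kn4,
                                  np.diag(np.full(n, k5))))

    if regime == "independent_with_dissociation":
        # balanced affinity and independence: k1 = k2 = k3 = k4 = y2,
        # all four dissociation constants equal to y5
        y2 = float(p.pop("y2", DEFAULT_Y2))
        y5 = float(p.pop("y5", 1.0))
        alpha_rna = float(p.pop("alpha_rna", DEFAULT_ALPHA_RNA))
        return finish(_uniform_network(n, k_assoc=y2, k_dissoc=y5, k5=k5,
                                       alpha_H=alpha_H, beta=beta,
                                       alpha_S=alpha_rna, alpha_T=alpha_rna))

    if regime == "cooperative_dissociation":
        y1 = float(p.pop("y1", 1.0))
        y2 = float(p.pop("y2", DEFAULT_Y2))
        y3 = float(p.pop("y3", 1.0))
        y4 = float(p.pop("y4", 1.0))
        y5 = float(p.pop("y5", 1e4))
        y6 = float(p.pop("y6", 1e4))
        alpha_rna = float(p.pop("alpha_rna", DEFAULT_ALPHA_RNA))
        k1, k2, k3, k4 = association_from_y(y1, y2, y3, y4)
        kn1, kn2, kn3, kn4 = dissociation_from_y(y5, y6)
        return finish(NetworkSpec(n, n, alpha_H, alpha_rna, alpha_rna,
                                  beta, k1, kn1, k2, kn2, k3, kn3, k4, kn4,
                                  np.diag(np.full(n, k5))))

    if regime in ("network_uniform", "cognate_selection", "noncognate_exclusion"):
        n = int(params.get("n", 5)) if "n" not in p else n
        y2 = float(p.pop("y2", DEFAULT_Y2))
        y9 = float(p.pop("y9", 1.0))
        y7 = float(p.pop("y7", 1.0))
        y8 = float(p.pop("y8", 1.0))
        route = p.pop("route", None)
        # cognate selection defaults to the association route (faster cognate
        # partner binding): with k5 >> k-3, k-4 the dissociation route has no
        # leverage on an already committed cognate ternary complex.  Exclusion
        # defaults to the dissociation route (faster non-cognate unbinding).
        y7_route = p.pop("y7_route", route or "association")
        y8_route = p.pop("y8_route", route or "dissociation")
        if regime == "network_uniform" and (y7 != 1.0 or y8 != 1.0):
            raise ValueError("network_uniform is the independent baseline; "
                             "use cognate_selection / noncognate_exclusion for y7/y8 != 1")
        if regime == "cognate_selection" and "y7" not in params:
            y7 = 1e-1
        if regime == "noncognate_exclusion" and "y8" not in params:
            y8 = 1e1
        # y9 is the composite six-constant target: when exclusion raises the
        # two starred dissociation constants by y8**2, lower the uniform base
        # so the geometric mean still equals the requested y9
        kd_base = y9
        if y8 != 1.0 and y8_route == "dissociation":
            kd_base /= y8 ** (2.0 / 3.0)
        if y7 != 1.0 and y7_route == "dissociation":
            kd_base /= y7 ** (2.0 / 3.0)  # diagonal k-3,k-4 scale by y7**2
        spec = _uniform_network(n, k_assoc=y2, k_dissoc=kd_base, k5=k5,
                                alpha_H=alpha_H, beta=beta)
        kn3, kn4, k3a, k4a = spec.kneg3, spec.kneg4, spec.k3, spec.k4
        if y7 != 1.0:
            if y7 <= 0:
                raise ValueError("y7 must be positive")
            if y7_route == "dissociation":
                # y7 scales as sqrt(f) when diagonal k-3, k-4 are scaled by f
                kn3 = _scale_diag(kn3, y7 ** 2)
                kn4 = _scale_diag(kn4, y7 ** 2)
            elif y7_route == "association":
                k3a = _scale_diag(k3a, y7 ** -2)
                k4a = _scale_diag(k4a, y7 ** -2)
            else:
                raise ValueError(f"unknown cooperativity route {y7_route!r}")
        if y8 != 1.0:
            if y8 <= 0:
                raise ValueError("y8 must be positive")
            if y8_route == "dissociation":
                kn3 = _scale_offdiag(kn3, y8 ** 2)
                kn4 = _scale_offdiag(kn4, y8 ** 2)
            elif y8_route == "association":
                k3a = _scale_offdiag(k3a, y8 ** -2)
                k4a = _scale_offdiag(k4a, y8 ** -2)
            else:
                raise ValueError(f"unknown cooperativity route {y8_route!r}")
        from dataclasses import replace
        return finish(replace(spec, kneg3=kn3, kneg4=kn4, k3=k3a, k4=k4a))

    if regime in ("stable_pairs", "unstable_pairs"):
        # a mixed network: the first n_stable pairs dissociate slowly
        # (y9_stable), the remaining n_unstable rapidly (y9_unstable).
        n_stable = int(p.pop("n_stable", n if regime == "stable_pairs" else 0))
        n_unstable = int(p.pop("n_unstable", 0 if regime == "stable_pairs" else n))
        y2 = float(p.pop("y2", DEFAULT_Y2))
        y9_stable = float(p.pop("y9_stable", 1e0))
        y9_unstable = float(p.pop("y9_unstable", 1e4))
        ntot = n_stable + n_unstable
        if ntot < 1:
            raise ValueError("need at least one pair")
        kd = np.concatenate([np.full(n_stable, y9_stable),
                             np.full(n_unstable, y9_unstable)])
        # dissociation follows the RNA doing the leaving: sRNA i sets
        # k-1(i) and k-4(i, .); mRNA j sets k-2(j) and k-3(., j)
        return finish(NetworkSpec(
            ntot, ntot, alpha_H, DEFAULT_ALPHA_RNA, DEFAULT_ALPHA_RNA, beta,
            k1=np.full(ntot, y2), kneg1=kd,
            k2=np.full(ntot, y2), kneg2=kd,
            k3=np.full((ntot, ntot), y2), kneg3=np.tile(kd, (ntot, 1)),
            k4=np.full((ntot, ntot), y2), kneg4=np.tile(kd[:, None], (1, ntot)),
            k5=np.diag(np.full(ntot, k5))))

    if regime == "indiscriminate":
        n = int(params.get("n", 3)) if "n" not in p else n
        y2 = float(p.pop("y2", DEFAULT_Y2))
        y9 = float(p.pop("y9", 1.0))
        return finish(_uniform_network(n, k_assoc=y2, k_dissoc=y9, k5=k5,
                                       k5_matrix="full", alpha_H=alpha_H, beta=beta))

    if regime == "imbalanced_pair":
        # one cognate pair; sRNA:mRNA production ratio varied at constant sum
        ratio = float(p.pop("ratio", 1.0))           # alpha_S / alpha_T
        total = float(p.pop("total_alpha", 2.0 * DEFAULT_ALPHA_RNA))
        y1 = float(p.pop("y1", 1.0))
        y2 = float(p.pop("y2", DEFAULT_Y2))
        y3 = float(p.pop("y3", 1.0))
        y4 = float(p.pop("y4", 1.0))
        y5 = float(p.pop("y5", 1.0))
        y6 = float(p.pop("y6", 1.0))
        k1, k2, k3, k4 = association_from_y(y1, y2, y3, y4)
        kn1, kn2, kn3, kn4 = dissociation_from_y(y5, y6)
        a_s = total * ratio / (1.0 + ratio)
        a_t = total / (1.0 + ratio)
        return finish(NetworkSpec(1, 1, alpha_H, a_s, a_t, beta,
                                  k1, kn1, k2, kn2, k3, kn3, k4, kn4, k5))

    if regime == "two_pair_overproduction":
        # two single-partner pairs; sRNA_1 production scaled up
        factor = float(p.pop("srna1_factor", 1.0))
        y2 = float(p.pop("y2", DEFAULT_Y2))
        y9 = float(p.pop("y9", 1.0))
        alpha_S = np.array([DEFAULT_ALPHA_RNA * factor, DEFAULT_ALPHA_RNA])
        spec = _uniform_network(2, k_assoc=y2, k_dissoc=y9, k5=k5,
                                alpha_H=alpha_H, alpha_S=alpha_S, beta=beta)
        return finish(spec)

    if regime == "unpartnered_pool":
        # one sRNA, its cognate mRNA, plus an aggregate unpartnered-mRNA
        # species produced at pool_factor times the cognate mRNA's rate
        pool_factor = float(p.pop("pool_factor", 100.0))
        y2 = float(p.pop("y2", DEFAULT_Y2))
        y9 = float(p.pop("y9", 1.0))
        y8 = float(p.pop("y8", 1.0))
        affinity_ratio = float(p.pop("affinity_ratio", 1.0))
        include_pool = bool(p.pop("include_pool", True))
        m = 2 if include_pool else 1
        alpha_T = np.array([DEFAULT_ALPHA_RNA] + ([DEFAULT_ALPHA_RNA * pool_factor]
                                                  if include_pool else []))
        # y9 is the composite target; with exclusion scaling the pool-side
        # dissociation by y8**2, a uniform base of y9 / y8**(2/3) makes the
        # six-constant geometric mean land exactly on the requested y9
        kd = y9 / y8 ** (2.0 / 3.0) if include_pool else y9
        k3 = np.full((1, m), y2)
        kn3 = np.full((1, m), kd)
        k4 = np.full((1, m), y2)
        kn4 = np.full((1, m), kd)
        k5m = np.zeros((1, m)); k5m[0, 0] = k5
        if include_pool and y8 != 1.0:
            # exclusion realized by faster dissociation from the
            # non-cognate (pool) ternary complex
            kn3[0, 1] *= y8 ** 2
            kn4[0, 1] *= y8 ** 2
        # affinity tilt: ((k2*k3*k3*)/(k1*k4*k4*))^(1/3); scale the mRNA-side
        # group by sqrt(tilt) and the sRNA-side group by 1/sqrt(tilt) so the
        # overall association magnitude is unchanged
        s = math.sqrt(affinity_ratio)
        k1 = y2 / s
        k2 = y2 * s
        k3 *= s
        k4 /= s
        return finish(NetworkSpec(1, m, alpha_H, DEFAULT_ALPHA_RNA, alpha_T, beta,
                                  k1, kd, np.full(m, k2), kd,
                                  k3, kn3, k4, kn4, k5m))

    if regime == "s1_degradation":
        # 10-fold faster turnover of the free sRNA, everything else as the base
        base = p.pop("base", "independent_with_dissociation")
        factor = float(p.pop("degradation_factor", 10.0))
        spec = build_scheme(base, n=n, beta=beta, alpha_H=alpha_H, k5=k5, **p)
        p.clear()
        from dataclasses import replace
        return finish(replace(spec, beta_overrides={"S": spec.beta * factor}))

    raise AssertionError("unreachable")
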