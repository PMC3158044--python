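"""Reaction-network data model for Hfq-mediated sRNA-target mRNA duplex formation.

The model tracks seven groups of molecular species for a network of ``n``
sRNA species and ``m`` target-mRNA species competing for the Hfq hexamer:

* ``H``   -- free Hfq hexamer
* ``S_i`` -- free sRNA i
* ``T_j`` -- free target mRNA j
* ``HS_i`` -- singly-bound sRNA-Hfq complex
* ``HT_j`` -- singly-bound mRNA-Hfq complex
* ``HS_iT_j`` -- ternary complex (Hfq bound by sRNA i and mRNA j)
* ``D_ij`` -- released sRNA-mRNA duplex

Every species is produced (Hfq and free RNAs only), degraded/diluted at a
first-order rate ``beta``, and interconverted by elementary mass-action
reactions.  There are two paths to the ternary complex: sRNA binds free Hfq
first (rate ``k1``) then the mRNA joins (``k3``), or the mRNA binds first
(``k2``) then the sRNA joins (``k4``).  Duplex annealing and release from
the ternary complex is lumped into a single step with rate ``k5``, which
simultaneously regenerates free Hfq.  Duplexes never rebind Hfq.

An Hfq hexamer binds at most one sRNA and one mRNA, so the full state has
``1 + 2n + 2m + 2 n m`` concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NetworkSpec",
    "StateVector",
    "state_dimension",
    "count_complex_types",
    "derivatives",
    "derivatives_flat",
    "jacobian_flat",
]

#: Species roles accepted by :attr:`NetworkSpec.beta_overrides`.
BETA_ROLES = ("H", "S", "T", "HS", "HT", "HST", "D")


def _as_vector(x, length: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = np.full(length, float(arr))
    if arr.shape != (length,):
        raise ValueError(f"{name} must be a scalar or length-{length} vector, got shape {arr.shape}")
    return arr


def _as_matrix(x, shape: tuple[int, int], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = np.full(shape, float(arr))
    if arr.shape != shape:
        raise ValueError(f"{name} must be a scalar or {shape} matrix, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class NetworkSpec:
    """Full kinetic specification of an n x m Hfq network.

    Rate-constant conventions (units: arbitrary concentration / time):

    ``k1[i]`` / ``kneg1[i]``
        sRNA i association with / dissociation from free Hfq.
    ``k2[j]`` / ``kneg2[j]``
        mRNA j association with / dissociation from free Hfq.
    ``k3[i, j]`` / ``kneg3[i, j]``
        mRNA j binding to / unbinding from the HS_i complex.  Off-diagonal
        entries describe non-cognate ternary complexes.
    ``k4[i, j]`` / ``kneg4[i, j]``
        sRNA i binding to / unbinding from the HT_j complex.
    ``k5[i, j]``
        lumped duplex annealing-and-release rate; zero for non-cognate
        pairs unless duplex formation is indiscriminate.

    ``beta`` is the global degradation/dilution rate applied to every
    species; ``beta_overrides`` maps a species role (one of ``"H"``,
    ``"S"``, ``"T"``, ``"HS"``, ``"HT"``, ``"HST"``, ``"D"``) to a
    replacement rate (scalar or per-species array), e.g. a 10-fold faster
    turnover of free sRNA.
    """

    n_srna: int
    m_mrna: int
    alpha_H: float
    alpha_S: np.ndarray
    alpha_T: np.ndarray
    beta: float
    k1: np.ndarray
    kneg1: np.ndarray
    k2: np.ndarray
    kneg2: np.ndarray
    k3: np.ndarray
    kneg3: np.ndarray
    k4: np.ndarray
    kneg4: np.ndarray
    k5: np.ndarray
    beta_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        n, m = int(self.n_srna), int(self.m_mrna)
        if n < 1 or m < 1:
            raise ValueError("n_srna and m_mrna must be positive")
        object.__setattr__(self, "n_srna", n)
        object.__setattr__(self, "m_mrna", m)
        object.__setattr__(self, "alpha_H", float(self.alpha_H))
        object.__setattr__(self, "beta", float(self.beta))
        object.__setattr__(self, "alpha_S", _as_vector(self.alpha_S, n, "alpha_S"))
        object.__setattr__(self, "alpha_T", _as_vector(self.alpha_T, m, "alpha_T"))
        for name in ("k1", "kneg1"):
            object.__setattr__(self, name, _as_vector(getattr(self, name), n, name))
        for name in ("k2", "kneg2"):
            object.__setattr__(self, name, _as_vector(getattr(self, name), m, name))
        for name in ("k3", "kneg3", "k4", "kneg4", "k5"):
            object.__setattr__(self, name, _as_matrix(getattr(self, name), (n, m), name))
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.alpha_H < 0:
            raise ValueError("alpha_H must be non-negative")
        for name in ("alpha_S", "alpha_T", "k1", "kneg1", "k2", "kneg2",
                     "k3", "kneg3", "k4", "kneg4", "k5"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")
        for role in self.beta_overrides:
            if role not in BETA_ROLES:
                raise ValueError(f"unknown beta_overrides role {role!r}; expected one of {BETA_ROLES}")

    # -- degradation rates per role, honoring overrides -------------------

    def beta_for(self, role: str) -> np.ndarray | float:
        """Degradation rate for a species role (scalar or broadcastable array)."""
        val = self.beta_overrides.get(role, self.beta)
        return np.asarray(val, dtype=float) if np.ndim(val) else float(val)

    def with_alpha_H(self, alpha_H: float) -> "NetworkSpec":
        """Copy of this spec with a different Hfq production rate."""
        return replace(self, alpha_H=float(alpha_H))

    @property
    def dimension(self) -> int:
        return state_dimension(self)


def state_dimension(spec: NetworkSpec) -> int:
    """Number of coupled ODEs: 1 + 2n + 2m + 2nm.

    One equation for free Hfq, n + m for free RNAs, n + m for singly-bound
    complexes, n*m for ternary complexes and n*m for duplexes.
    """
    n, m = spec.n_srna, spec.m_mrna
    return 1 + 2 * n + 2 * m + 2 * n * m


def count_complex_types(n: int, m: int, shared_sites: bool = False) -> dict:
    """Count the distinct Hfq-complex types in a single-partner network.

    Assumes each sRNA has exactly one cognate mRNA (cognate iff i == j),
    which requires ``n == m``.  With separate sRNA and mRNA binding sites
    on the hexamer there are ``n**2 - n`` non-cognate ternary types; if
    both RNA classes compete for shared sites, same-class pairings such as
    (sRNA)2-Hfq become possible and the count grows to ``2*n**2 - n``.

    Returns a dict with keys ``singly_bound``, ``cognate_ternary`` and
    ``noncognate_ternary``.
    """
    if n != m:
        raise ValueError("complex-type counting assumes single-partner pairing (n == m)")
    if n < 1:
        raise ValueError("n must be >= 1")
    noncognate = 2 * n * n - n if shared_sites else n * n - n
    return {
        "singly_bound": 2 * n,
        "cognate_ternary": n,
        "noncognate_ternary": noncognate,
    }


@dataclass
class StateVector:
    """Concentrations of every molecular species in a network."""

    H: float
    S: np.ndarray   # (n,)
    T: np.ndarray   # (m,)
    HS: np.ndarray  # (n,)
    HT: np.ndarray  # (m,)
    HST: np.ndarray  # (n, m)
    D: np.ndarray   # (n, m)

    @classmethod
    def zeros(cls, spec: NetworkSpec) -> "StateVector":
        n, m = spec.n_srna, spec.m_mrna
        return cls(0.0, np.zeros(n), np.zeros(m), np.zeros(n), np.zeros(m),
                   np.zeros((n, m)), np.zeros((n, m)))

    @classmethod
    def from_flat(cls, y: np.ndarray, spec: NetworkSpec) -> "StateVector":
        n, m = spec.n_srna, spec.m_mrna
        y = np.asarray(y, dtype=float)
        if y.shape != (state_dimension(spec),):
            raise ValueError(
                f"flat state has shape {y.shape}, expected ({state_dimension(spec)},)")
        o = 1
        S = y[o:o + n]; o += n
        T = y[o:o + m]; o += m
        HS = y[o:o + n]; o += n
        HT = y[o:o + m]; o += m
        HST = y[o:o + n * m].reshape(n, m); o += n * m
        D = y[o:o + n * m].reshape(n, m)
        return cls(float(y[0]), S.copy(), T.copy(), HS.copy(), HT.copy(),
                   HST.copy(), D.copy())

    def to_flat(self) -> np.ndarray:
        """Flatten in the fixed layout H, S, T, HS, HT, HST (row-major), D (row-major)."""
        return np.concatenate([
            [self.H], self.S, self.T, self.HS, self.HT,
            self.HST.ravel(), self.D.ravel(),
        ])

    # Totals used by the conservation identities and the output metrics.

    def total_hfq(self) -> float:
        """Hfq in all forms: free, singly bound and ternary (duplexes carry no Hfq)."""
        return float(self.H + self.HS.sum() + self.HT.sum() + self.HST.sum())

    def total_srna(self, i: int) -> float:
        return float(self.S[i] + self.HS[i] + self.HST[i, :].sum() + self.D[i, :].sum())

    def total_mrna(self, j: int) -> float:
        return float(self.T[j] + self.HT[j] + self.HST[:, j].sum() + self.D[:, j].sum())


def _offsets(n: int, m: int):
    oS = 1
    oT = oS + n
    oHS = oT + m
    oHT = oHS + n
    oHST = oHT + m
    oD = oHST + n * m
    return oS, oT, oHS, oHT, oHST, oD


def derivatives_flat(spec: NetworkSpec, y: np.ndarray) -> np.ndarray:
    """Mass-action time derivative of the flattened state vector."""
    n, m = spec.n_srna, spec.m_mrna
    dim = state_dimension(spec)
    y = np.asarray(y, dtype=float)
    if y.shape != (dim,):
        raise ValueError(f"state has shape {y.shape}, expected ({dim},)")
    oS, oT, oHS, oHT, oHST, oD = _offsets(n, m)
    H = y[0]
    S = y[oS:oT]
    T = y[oT:oHS]
    HS = y[oHS:oHT]
    HT = y[oHT:oHST]
    HST = y[oHST:oD].reshape(n, m)
    D = y[oD:].reshape(n, m)

    assoc1 = spec.k1 * S * H                      # S_i + H -> HS_i
    assoc2 = spec.k2 * T * H                      # T_j + H -> HT_j
    bind3 = spec.k3 * HS[:, None] * T[None, :]    # HS_i + T_j -> HS_iT_j
    bind4 = spec.k4 * S[:, None] * HT[None, :]    # HT_j + S_i -> HS_iT_j
    rel3 = spec.kneg3 * HST                       # HS_iT_j -> HS_i + T_j
    rel4 = spec.kneg4 * HST                       # HS_iT_j -> HT_j + S_i
    rel5 = spec.k5 * HST                          # HS_iT_j -> D_ij + H

    out = np.empty(dim)
    out[0] = (spec.alpha_H + spec.kneg1 @ HS + spec.kneg2 @ HT + rel5.sum()
              - assoc1.sum() - assoc2.sum() - spec.beta_for("H") * H)
    out[oS:oT] = (spec.alpha_S + spec.kneg1 * HS + rel4.sum(axis=1)
                  - assoc1 - bind4.sum(axis=1) - spec.beta_for("S") * S)
    out[oT:oHS] = (spec.alpha_T + spec.kneg2 * HT + rel3.sum(axis=0)
                   - assoc2 - bind3.sum(axis=0) - spec.beta_for("T") * T)
    out[oHS:oHT] = (assoc1 + rel3.sum(axis=1)
                    - spec.kneg1 * HS - bind3.sum(axis=1) - spec.beta_for("HS") * HS)
    out[oHT:oHST] = (assoc2 + rel4.sum(axis=0)
                     - spec.kneg2 * HT - bind4.sum(axis=0) - spec.beta_for("HT") * HT)
    out[oHST:oD] = (bind3 + bind4
                    - (spec.kneg3 + spec.kneg4 + spec.k5 + spec.beta_for("HST")) * HST).ravel()
    out[oD:] = (rel5 - spec.beta_for("D") * D).ravel()
    return out


def derivatives(spec: NetworkSpec, state: StateVector) -> StateVector:
    """Mass-action derivative, structured like the state itself."""
    return StateVector.from_flat(derivatives_flat(spec, state.to_flat()), spec)


def jacobian_flat(spec: NetworkSpec, y: np.ndarray) -> np.ndarray:
    """Dense analytic Jacobian of :func:`derivatives_flat` at ``y``.

    Supplying this to the stiff integrator avoids finite-difference
    Jacobians, which dominate the cost for larger networks.
    """
    n, m = spec.n_srna, spec.m_mrna
    dim = state_dimension(spec)
    y = np.asarray(y, dtype=float)
    oS, oT, oHS, oHT, oHST, oD = _offsets(n, m)
    H = y[0]
    S = y[oS:oT]
    T = y[oT:oHS]
    HS = y[oHS:oHT]
    HT = y[oHT:oHST]

    J = np.zeros((dim, dim))
    ii = np.arange(n)
    jj = np.arange(m)
    hst = (oHST + (ii[:, None] * m + jj[None, :])).ravel()
    hst_i = np.repeat(ii, m)   # sRNA index of each HST entry
    hst_j = np.tile(jj, n)     # mRNA index of each HST entry
    k3f = spec.k3.ravel()
    k4f = spec.k4.ravel()
    kn3f = spec.kneg3.ravel()
    kn4f = spec.kneg4.ravel()
    k5f = spec.k5.ravel()

    # free Hfq row
    J[0, 0] = -(spec.k1 @ S) - (spec.k2 @ T) - spec.beta_for("H")
    J[0, oS:oT] = -spec.k1 * H
    J[0, oT:oHS] = -spec.k2 * H
    J[0, oHS:oHT] = spec.kneg1
    J[0, oHT:oHST] = spec.kneg2
    J[0, hst] = k5f

    # free sRNA rows
    rS = oS + ii
    J[rS, 0] = -spec.k1 * S
    J[rS, rS] = -spec.k1 * H - spec.k4 @ HT - np.broadcast_to(spec.beta_for("S"), (n,))
    J[rS, oHS + ii] = spec.kneg1
    J[np.repeat(rS, m), np.tile(oHT + jj, n)] = -(spec.k4 * S[:, None]).ravel()
    J[oS + hst_i, hst] = kn4f

    # free mRNA rows
    rT = oT + jj
    J[rT, 0] = -spec.k2 * T
    J[rT, rT] = -spec.k2 * H - HS @ spec.k3 - np.broadcast_to(spec.beta_for("T"), (m,))
    J[rT, oHT + jj] = spec.kneg2
    J[np.repeat(rT, n), np.tile(oHS + ii, m)] = -(spec.k3 * T[None, :]).T.ravel()
    J[oT + hst_j, hst] = kn3f

    # HS rows
    rHS = oHS + ii
    J[rHS, 0] = spec.k1 * S
    J[rHS, rS] = spec.k1 * H
    J[rHS, rHS] = (-spec.kneg1 - spec.k3 @ T
                   - np.broadcast_to(spec.beta_for("HS"), (n,)))
    J[np.repeat(rHS, m), np.tile(oT + jj, n)] = -(spec.k3 * HS[:, None]).ravel()
    J[oHS + hst_i, hst] = kn3f

    # HT rows
    rHT = oHT + jj
    J[rHT, 0] = spec.k2 * T
    J[rHT, rT] = spec.k2 * H
    J[rHT, rHT] = (-spec.kneg2 - S @ spec.k4
                   - np.broadcast_to(spec.beta_for("HT"), (m,)))
    J[np.repeat(rHT, n), np.tile(oS + ii, m)] = -(spec.k4 * HT[None, :]).T.ravel()
    J[oHT + hst_j, hst] = kn4f

    # HST rows
    J[hst, oHS + hst_i] = (spec.k3 * T[None, :]).ravel()
    J[hst, oT + hst_j] = (spec.k3 * HS[:, None]).ravel()
    J[hst, oS + hst_i] = (spec.k4 * HT[None, :]).ravel()
    J[hst, oHT + hst_j] = (spec.k4 * S[:, None]).ravel()
    J[hst, hst] = -(kn3f + kn4f + k5f
                    + np.broadcast_to(spec.beta_for("HST"), (n, m)).ravel())

    # duplex rows
    dd = oD + np.arange(n * m)
    J[dd, hst] = k5f
    J[dd, dd] = -np.broadcast_to(spec.beta_for("D"), (n, m)).ravel()
    return J
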