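"""Output metrics, Hfq-production sweeps, and robustness extraction.

The measured output of the pathway is the fraction of a target mRNA's
total pool converted to a specific cognate duplex at steady state.  Hfq
availability is expressed as "relative Hfq": total Hfq in all forms
divided by the focal pair's total target mRNA.  Sweeping the Hfq
production rate over many decades produces the characteristic
single-peaked duplex-formation curve; the minimum and maximum relative
Hfq giving at least 10% duplex conversion are the lower and upper bounds,
and their log10 fold-difference is the "Hfq robustness" of the pathway.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import NetworkSpec, StateVector
from .steady import ConvergenceConfig, SteadyState, integrate_to_steady_state

__all__ = [
    "percent_duplex",
    "relative_hfq",
    "hfq_allocation",
    "percent_hfq_sequestered",
    "default_alpha_grid",
    "hfq_sweep",
    "bounds_and_robustness",
    "SweepResult",
    "RobustnessSummary",
]

log = logging.getLogger(__name__)

#: Duplex-conversion threshold (percent) defining the bounds.
DEFAULT_THRESHOLD = 10.0


def _cognate_mask(spec: NetworkSpec) -> np.ndarray:
    return spec.k5 > 0.0


def percent_duplex(state: StateVector, spec: NetworkSpec,
                   pair: tuple[int, int] = (0, 0)) -> float:
    """Percent of target mRNA j present as the specific duplex D_ij.

    The denominator is the total pool of mRNA j in every form: free,
    singly bound, in any ternary complex and in any duplex.  At steady
    state with uniform degradation this equals ``alpha_T[j] / beta``.
    Returns NaN if the total pool is zero.
    """
    i, j = pair
    total = state.total_mrna(j)
    if total == 0.0:
        return math.nan
    return 100.0 * float(state.D[i, j]) / total


def relative_hfq(state: StateVector, spec: NetworkSpec, focal_j: int = 0) -> float:
    """Total Hfq (all forms) over the total mRNA pool of the focal target."""
    total_t = state.total_mrna(focal_j)
    if total_t == 0.0:
        return math.nan
    return state.total_hfq() / total_t


def hfq_allocation(state: StateVector, spec: NetworkSpec) -> dict:
    """Fractions of total Hfq held as free, HS, HT, cognate and non-cognate ternary.

    Ternary complexes are cognate where ``k5 > 0``.  Fractions sum to 1;
    every key is NaN when no Hfq is present.
    """
    total = state.total_hfq()
    keys = ("free", "srna_bound", "mrna_bound", "cognate_ternary", "noncognate_ternary")
    if total == 0.0:
        return dict.fromkeys(keys, math.nan)
    cog = _cognate_mask(spec)
    return {
        "free": state.H / total,
        "srna_bound": state.HS.sum() / total,
        "mrna_bound": state.HT.sum() / total,
        "cognate_ternary": state.HST[cog].sum() / total,
        "noncognate_ternary": state.HST[~cog].sum() / total,
    }


def percent_hfq_sequestered(state: StateVector, spec: NetworkSpec) -> float:
    """Percent of total Hfq trapped in non-productive complexes.

    Counts Hfq in singly-bound complexes plus non-cognate ternary
    complexes - i.e. bound Hfq that is not on the path to releasing a
    duplex.  (The complement of the free and cognate-ternary fractions.)
    """
    total = state.total_hfq()
    if total == 0.0:
        return math.nan
    cog = _cognate_mask(spec)
    seq = state.HS.sum() + state.HT.sum() + state.HST[~cog].sum()
    return 100.0 * float(seq) / total


def default_alpha_grid(lo: float = 1e-5, hi: float = 1e7,
                       points_per_decade: int = 10) -> np.ndarray:
    """Log-spaced Hfq-production grid covering the explored range."""
    decades = math.log10(hi) - math.log10(lo)
    npts = int(round(decades * points_per_decade)) + 1
    return np.logspace(math.log10(lo), math.log10(hi), npts)


@dataclass
class SweepResult:
    """Per-grid-point metrics over an Hfq-production titration.

    ``percent_duplex[pair]`` and ``relative_hfq[pair]`` are arrays over
    the grid, one entry per focal pair.  Non-converged grid points are
    recorded in ``failed`` and carry NaN metrics.
    """

    alpha_H: np.ndarray
    pairs: list
    relative_hfq: dict = field(default_factory=dict)   # pair -> array
    percent_duplex: dict = field(default_factory=dict)  # pair -> array
    allocation: pd.DataFrame | None = None             # one row per grid point
    percent_sequestered: np.ndarray | None = None
    failed: list = field(default_factory=list)          # indices of failed points
    states: list | None = None                          # optional SteadyState cache

    def __len__(self) -> int:
        return len(self.alpha_H)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (grid point, focal pair)."""
        rows = []
        for pair in self.pairs:
            for k, a in enumerate(self.alpha_H):
                rows.append({
                    "alpha_H": a,
                    "pair_i": pair[0],
                    "pair_j": pair[1],
                    "relative_hfq": self.relative_hfq[pair][k],
                    "percent_duplex": self.percent_duplex[pair][k],
                    "percent_hfq_sequestered": (self.percent_sequestered[k]
                                                if self.percent_sequestered is not None
                                                else math.nan),
                    "converged": k not in self.failed,
                })
        return pd.DataFrame(rows)


@dataclass
class RobustnessSummary:
    """Lower/upper relative-Hfq bounds and log-range robustness for one pair.

    ``robustness = log10(upper/lower)``; when the duplex curve never
    reaches the threshold both bounds are undefined and robustness is
    reported as 0 with ``defined = False``.
    """

    lower_bound: float
    upper_bound: float
    robustness: float
    max_percent_duplex: float
    threshold: float = DEFAULT_THRESHOLD
    defined: bool = True
    edge_warning: str = ""

    def to_dict(self) -> dict:
        return {
            "lower_bound": self.lower_bound,
            "upper_bound": self.upper_bound,
            "robustness": self.robustness,
            "max_percent_duplex": self.max_percent_duplex,
            "threshold": self.threshold,
            "defined": self.defined,
            "edge_warning": self.edge_warning,
        }


def hfq_sweep(template: NetworkSpec,
              alpha_H_grid: np.ndarray | None = None,
              pairs: list | None = None,
              cfg: ConvergenceConfig | None = None,
              keep_states: bool = False) -> SweepResult:
    """Solve the network to steady state at each Hfq production rate.

    ``template`` provides every parameter except ``alpha_H``, which is
    replaced grid point by grid point.  Convergence failures are recorded
    per point (NaN metrics) and never abort the sweep.
    """
    if alpha_H_grid is None:
        alpha_H_grid = default_alpha_grid()
    grid = np.asarray(alpha_H_grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0:
        raise ValueError("alpha_H_grid must be a non-empty 1-D array")
    if len(grid) > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("alpha_H_grid must be strictly increasing")
    if pairs is None:
        pairs = [(i, i) for i in range(min(template.n_srna, template.m_mrna))][:1]
    pairs = [tuple(p) for p in pairs]
    cfg = cfg or ConvergenceConfig()

    res = SweepResult(alpha_H=grid, pairs=pairs)
    for pair in pairs:
        res.relative_hfq[pair] = np.full(len(grid), np.nan)
        res.percent_duplex[pair] = np.full(len(grid), np.nan)
    res.percent_sequestered = np.full(len(grid), np.nan)
    alloc_rows = []
    states: list[SteadyState | None] = []

    for k, a in enumerate(grid):
        spec = template.with_alpha_H(float(a))
        ss = integrate_to_steady_state(spec, cfg)
        states.append(ss if keep_states else None)
        if not ss.converged:
            res.failed.append(k)
            alloc_rows.append(dict.fromkeys(
                ("free", "srna_bound", "mrna_bound",
                 "cognate_ternary", "noncognate_ternary"), math.nan))
            log.warning("sweep point alpha_H=%g failed: %s", a, ss.message)
            continue
        st = ss.state
        for pair in pairs:
            res.relative_hfq[pair][k] = relative_hfq(st, spec, focal_j=pair[1])
            res.percent_duplex[pair][k] = percent_duplex(st, spec, pair)
        res.percent_sequestered[k] = percent_hfq_sequestered(st, spec)
        alloc_rows.append(hfq_allocation(st, spec))

    res.allocation = pd.DataFrame(alloc_rows)
    if keep_states:
        res.states = states
    return res


def _interp_crossing(x0: float, y0: float, x1: float, y1: float,
                     threshold: float) -> float:
    """Log-linear interpolation of the relative-Hfq value where the curve
    crosses the threshold between two grid points (log x, linear percent)."""
    if y1 == y0:
        return x0
    t = (threshold - y0) / (y1 - y0)
    return 10 ** (math.log10(x0) + t * (math.log10(x1) - math.log10(x0)))


def bounds_and_robustness(sweep: SweepResult,
                          pair: tuple[int, int] | None = None,
                          threshold: float = DEFAULT_THRESHOLD) -> RobustnessSummary:
    """Extract the lower/upper bounds and robustness from a sweep.

    The lower bound is the smallest relative Hfq at which the duplex
    curve reaches the threshold (first upward crossing, log-linearly
    interpolated); the upper bound is the largest (last downward
    crossing).  A curve that never reaches the threshold yields undefined
    bounds, reported as NaN with ``robustness = 0`` and ``defined =
    False``.  If the curve is still at or above threshold at a grid edge
    an ``edge_warning`` is set.
    """
    if pair is None:
        pair = sweep.pairs[0]
    pair = tuple(pair)
    x = np.asarray(sweep.relative_hfq[pair], dtype=float)
    y = np.asarray(sweep.percent_duplex[pair], dtype=float)
    good = np.isfinite(x) & np.isfinite(y)
    x, y = x[good], y[good]
    if len(x) == 0:
        return RobustnessSummary(math.nan, math.nan, 0.0, math.nan,
                                 threshold, defined=False,
                                 edge_warning="no converged grid points")
    ymax = float(np.max(y))
    if ymax < threshold:
        return RobustnessSummary(math.nan, math.nan, 0.0, ymax, threshold,
                                 defined=False)

    above = y >= threshold
    first = int(np.argmax(above))
    last = len(y) - 1 - int(np.argmax(above[::-1]))
    warning = ""
    if first == 0 and above[0]:
        lower = float(x[0])
        warning += "curve at/above threshold at lower grid edge; "
    else:
        lower = _interp_crossing(x[first - 1], y[first - 1], x[first], y[first], threshold)
    if last == len(y) - 1 and above[-1]:
        upper = float(x[-1])
        warning += "curve at/above threshold at upper grid edge; "
    else:
        upper = _interp_crossing(x[last], y[last], x[last + 1], y[last + 1], threshold)
    robustness = math.log10(upper / lower) if lower > 0 else math.inf
    return RobustnessSummary(lower, upper, robustness, ymax, threshold,
                             defined=True, edge_warning=warning.strip("; "))
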