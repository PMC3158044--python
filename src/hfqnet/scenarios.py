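"""Named simulation scenarios: each figure-style study as a declarative object.

A :class:`Scenario` expands deterministically into a list of
``(label, NetworkSpec, SweepConfig)`` triples; :func:`run_scenario`
orchestrates the Hfq-production sweep and robustness extraction for each
entry.  Panel labels follow the top-left..bottom-right convention
(TL, TC, TR, ML, MC, MR, BL, BC, BR) where a 3x3 grid of parameter values
is scanned; other scenarios use descriptive labels.

Every constant a scenario encodes can be overridden through its
``overrides`` mapping, since several per-panel values are design choices
of the preset library rather than uniquely pinned by the published
ranges.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .metrics import (RobustnessSummary, SweepResult, bounds_and_robustness,
                      default_alpha_grid, hfq_sweep)
from .network import NetworkSpec
from .params import build_scheme
from .steady import ConvergenceConfig

__all__ = ["Scenario", "SweepConfig", "SCENARIO_IDS", "expand", "run_scenario"]

log = logging.getLogger(__name__)

SCENARIO_IDS = ("fig2", "fig3_assoc", "fig3_dissoc", "fig4a", "fig4b",
                "fig6", "fig7", "fig8", "fig9", "fig10", "fig11", "fig12",
                "fig13", "s1")

_PANEL33 = ("TL", "TC", "TR", "ML", "MC", "MR", "BL", "BC", "BR")

#: RNA production rate shared by the single-pair (isolated cognate pair)
#: scenarios.  The published behavior of those schemes requires even the
#: slowest association step (y2 = 10^0.5 with a strong affinity bias) to
#: outpace RNA turnover, which pins the RNA pool well above one model unit;
#: 100 concentration units per RNA achieves that across the whole explored
#: rate-constant range.  Network scenarios use 1 unit per RNA so "relative
#: Hfq" equals the Hfq production rate directly.
PART1_ALPHA_RNA = 100.0

#: Network baseline shared by the network-scaling scenarios (y2 at the
#: center of the explored association range; slow uniform dissociation;
#: fast cognate annealing as pinned for the comparison baseline).
NETWORK_BASE = {"y2": 10 ** 2.5, "y9": 1e0, "k5": 1e3}
#: Baseline for the isolated-pair/network contrast: the low ends of the
#: explored association and annealing ranges, with independent binding
#: and unbinding.
FIG6_BASE = {"y2": 10 ** 0.5, "y9": 1e0, "k5": 1e0}


@dataclass(frozen=True)
class SweepConfig:
    """Grid plus solver settings for one sweep."""

    grid: np.ndarray = field(default_factory=default_alpha_grid)
    pairs: tuple = ((0, 0),)
    convergence: ConvergenceConfig = field(default_factory=ConvergenceConfig)


@dataclass(frozen=True)
class Scenario:
    """A named simulation design.

    ``overrides`` tweaks the scenario's constants (e.g. ``{"n_list":
    [1, 5], "points_per_decade": 4}``); unknown override keys raise at
    expansion time.
    """

    id: str
    overrides: dict = field(default_factory=dict)

    def expand(self):
        return expand(self)

    def run(self, **kw):
        return run_scenario(self, **kw)


def _sweepcfg(o: dict, pairs=((0, 0),)) -> SweepConfig:
    ppd = o.pop("points_per_decade", 10)
    lo = o.pop("grid_lo", 1e-5)
    hi = o.pop("grid_hi", 1e7)
    conv = o.pop("convergence", ConvergenceConfig())
    return SweepConfig(grid=default_alpha_grid(lo, hi, ppd), pairs=tuple(pairs),
                       convergence=conv)


def expand(scenario: Scenario) -> list[tuple[str, NetworkSpec, SweepConfig]]:
    """Deterministic expansion of a scenario into labelled sweep jobs."""
    sid = scenario.id
    if sid not in SCENARIO_IDS:
        raise ValueError(f"unknown scenario id {sid!r}; expected one of {SCENARIO_IDS}")
    o = dict(scenario.overrides)
    out: list[tuple[str, NetworkSpec, SweepConfig]] = []

    if sid == "fig2":
        # independent binding, no dissociation; rows scan y1, columns y2
        y1_vals = o.pop("y1_vals", (1e-4, 1e0, 1e4))
        y2_vals = o.pop("y2_vals", (10 ** 0.5, 10 ** 2.5, 10 ** 4.5))
        k5 = o.pop("k5", 1e3)
        alpha = o.pop("alpha_rna", PART1_ALPHA_RNA)
        cfg = _sweepcfg(o)
        for lbl, (y1, y2) in zip(_PANEL33, itertools.product(y1_vals, y2_vals)):
            spec = build_scheme("independent_no_dissociation", y1=y1, y2=y2,
                                k5=k5, alpha_rna=alpha)
            out.append((lbl, spec, cfg))

    elif sid == "fig3_assoc":
        # cooperative association, no dissociation; rows scan y4, columns y3
        y3_vals = o.pop("y3_vals", (1e-4, 1e0, 1e4))
        y4_vals = o.pop("y4_vals", (1e-4, 1e0, 1e4))
        k5 = o.pop("k5", 1e3)
        alpha = o.pop("alpha_rna", PART1_ALPHA_RNA)
        cfg = _sweepcfg(o)
        for lbl, (y4, y3) in zip(_PANEL33, itertools.product(y4_vals, y3_vals)):
            spec = build_scheme("cooperative_association", y3=y3, y4=y4, k5=k5,
                                alpha_rna=alpha)
            out.append((lbl, spec, cfg))

    elif sid == "fig3_dissoc":
        # independent association and dissociation; rows scan y5, columns k5
        y5_vals = o.pop("y5_vals", (1e0, 1e4, 1e8))
        k5_vals = o.pop("k5_vals", (1e0, 1e3, 1e6))
        alpha = o.pop("alpha_rna", PART1_ALPHA_RNA)
        cfg = _sweepcfg(o)
        for lbl, (y5, k5) in zip(_PANEL33, itertools.product(reversed(y5_vals), k5_vals)):
            spec = build_scheme("independent_with_dissociation", y5=y5, k5=k5,
                                alpha_rna=alpha)
            out.append((lbl, spec, cfg))

    elif sid == "fig4a":
        # cooperative association crossed with independent dissociation
        k5 = o.pop("k5", 1e3)
        y5_on = o.pop("y5", 1e4)
        y4_on = o.pop("y4", 1e4)
        alpha = o.pop("alpha_rna", PART1_ALPHA_RNA)
        cfg = _sweepcfg(o)
        for lbl, (y5, y4) in (("TL", (0.0, 1.0)), ("TR", (0.0, y4_on)),
                              ("BL", (y5_on, 1.0)), ("BR", (y5_on, y4_on))):
            spec = build_scheme("cooperative_association", y4=y4, y5=y5, k5=k5,
                                alpha_rna=alpha)
            out.append((lbl, spec, cfg))

    elif sid == "fig4b":
        # cooperative association crossed with cooperative dissociation
        k5 = o.pop("k5", 1e3)
        y5 = o.pop("y5", 1e4)
        y4_on = o.pop("y4", 1e4)
        y6_on = o.pop("y6", 1e4)
        alpha = o.pop("alpha_rna", PART1_ALPHA_RNA)
        cfg = _sweepcfg(o)
        for lbl, (y6, y4) in (("TL", (1.0, 1.0)), ("TR", (1.0, y4_on)),
                              ("BL", (y6_on, 1.0)), ("BR", (y6_on, y4_on))):
            spec = build_scheme("cooperative_dissociation", y4=y4, y5=y5, y6=y6,
                                k5=k5, alpha_rna=alpha)
            out.append((lbl, spec, cfg))

    elif sid == "fig6":
        # one pair in isolation vs the same kinetics in a 5-pair network
        base = {**FIG6_BASE, **{k: o.pop(k) for k in ("y2", "y9", "k5") if k in o}}
        n_list = o.pop("n_list", (1, 5))
        cfg = _sweepcfg(o)
        for n in n_list:
            spec = build_scheme("network_uniform", n=n, **base)
            out.append((f"n={n}", spec, cfg))

    elif sid == "fig7":
        # cognate selection / non-cognate exclusion across network sizes
        base = {**NETWORK_BASE, **{k: o.pop(k) for k in ("y2", "y9", "k5") if k in o}}
        n_list = o.pop("n_list", (1, 2, 5, 10, 20))
        y7 = o.pop("y7", 1e-1)
        y8 = o.pop("y8", 1e1)
        routes = {k: o.pop(k) for k in ("y7_route", "y8_route") if k in o}
        variants = (("independent", "network_uniform", {}),
                    ("selection", "cognate_selection", {"y7": y7}),
                    ("exclusion", "noncognate_exclusion", {"y8": y8}),
                    ("both", "cognate_selection", {"y7": y7, "y8": y8}))
        cfg = _sweepcfg(o)
        for n in n_list:
            for vlabel, regime, kw in variants:
                spec = build_scheme(regime, n=n, **base, **kw, **routes)
                out.append((f"{vlabel},n={n}", spec, cfg))

    elif sid == "fig8":
        # duplex annealing (k5) crossed with uniform RNA dissociation (y9)
        y2 = o.pop("y2", NETWORK_BASE["y2"])
        n_list = o.pop("n_list", (1, 2, 5, 10, 20))
        k5_vals = o.pop("k5_vals", (1e3, 1e6))
        y9_vals = o.pop("y9_vals", (1e0, 1e4))
        cfg = _sweepcfg(o)
        for n in n_list:
            for k5, y9 in itertools.product(k5_vals, y9_vals):
                spec = build_scheme("network_uniform", n=n, y2=y2, y9=y9, k5=k5)
                out.append((f"k5={k5:g},y9={y9:g},n={n}", spec, cfg))

    elif sid == "fig9":
        # stable/unstable pair mixes; focal pair 0 is stable when present
        y2 = o.pop("y2", NETWORK_BASE["y2"])
        k5 = o.pop("k5", NETWORK_BASE["k5"])
        y9_stable = o.pop("y9_stable", 1e0)
        y9_unstable = o.pop("y9_unstable", 1e4)
        stable_range = o.pop("stable_range", tuple(range(0, 9)))
        unstable_range = o.pop("unstable_range", tuple(range(0, 9)))
        cfg0 = _sweepcfg(o)
        for ns, nu in itertools.product(stable_range, unstable_range):
            if ns + nu == 0:
                continue
            spec = build_scheme("stable_pairs", n_stable=ns, n_unstable=nu,
                                y2=y2, k5=k5, y9_stable=y9_stable,
                                y9_unstable=y9_unstable)
            pairs = []
            if ns > 0:
                pairs.append((0, 0))            # focal stable pair
            if nu > 0:
                pairs.append((ns, ns))          # focal unstable pair
            cfg = SweepConfig(grid=cfg0.grid, pairs=tuple(pairs),
                              convergence=cfg0.convergence)
            out.append((f"stable={ns},unstable={nu}", spec, cfg))

    elif sid == "fig10":
        # specific vs indiscriminate pairing, slow vs fast dissociation
        y2 = o.pop("y2", NETWORK_BASE["y2"])
        k5 = o.pop("k5", 1e3)
        n_list = o.pop("n_list", (5,))
        y9_vals = o.pop("y9_vals", (1e0, 1e4))
        cfg = _sweepcfg(o)
        for n in n_list:
            for pairing, regime in (("specific", "network_uniform"),
                                    ("indiscriminate", "indiscriminate")):
                for y9 in y9_vals:
                    spec = build_scheme(regime, n=n, y2=y2, y9=y9, k5=k5)
                    out.append((f"{pairing},y9={y9:g},n={n}", spec, cfg))

    elif sid == "fig11":
        # sRNA:mRNA production ratio series at three branch biases
        y3_vals = o.pop("y3_vals", (1e-8, 1e8, 1e0))
        ratios = o.pop("ratios", tuple(np.geomspace(5.0, 0.2, 9)))
        y5 = o.pop("y5", 1e0)
        k5 = o.pop("k5", 1e3)
        total = o.pop("total_alpha", 2 * PART1_ALPHA_RNA)
        cfg = _sweepcfg(o)
        for y3 in y3_vals:
            for r in ratios:
                spec = build_scheme("imbalanced_pair", ratio=float(r), y3=y3,
                                    y5=y5, k5=k5, total_alpha=total)
                out.append((f"y3={y3:g},ratio={r:.3g}", spec, cfg))

    elif sid == "fig12":
        # two identical pairs; sRNA_1 production raised 1x..100x
        factors = o.pop("factors", tuple(np.geomspace(1.0, 100.0, 5)))
        y2 = o.pop("y2", NETWORK_BASE["y2"])
        y9 = o.pop("y9", 1e0)
        k5 = o.pop("k5", NETWORK_BASE["k5"])
        cfg0 = _sweepcfg(o)
        cfg = SweepConfig(grid=cfg0.grid, pairs=((0, 0), (1, 1)),
                          convergence=cfg0.convergence)
        for f in factors:
            spec = build_scheme("two_pair_overproduction", srna1_factor=float(f),
                                y2=y2, y9=y9, k5=k5)
            out.append((f"srna1={f:.3g}x", spec, cfg))

    elif sid == "fig13":
        # cognate pair +/- a 100x unpartnered mRNA pool, three kinetic
        # topologies (control / fast dissociation / exclusion) at three
        # affinity tilts
        pool_factor = o.pop("pool_factor", 100.0)
        topologies = o.pop("topologies", (("control", 1e0, 1e0),
                                          ("dissociation", 1e4, 1e0),
                                          ("exclusion", 1e1, 1e1)))
        tilts = o.pop("affinity_ratios", (1e0, 1e-2, 1e2))
        k5 = o.pop("k5", 1e3)
        cfg = _sweepcfg(o)
        for tilt in tilts:
            for tname, y9, y8 in topologies:
                for pool in (False, True):
                    spec = build_scheme("unpartnered_pool", include_pool=pool,
                                        pool_factor=pool_factor, y9=y9, y8=y8,
                                        affinity_ratio=tilt, k5=k5)
                    out.append((f"{tname},tilt={tilt:g},pool={'on' if pool else 'off'}",
                                spec, cfg))

    elif sid == "s1":
        # paired runs: uniform beta vs 10-fold free-sRNA degradation,
        # for three base kinetic regimes
        # the rapid-dissociation base pairs fast dissociation with fast
        # association: cycling among Hfq complexes only beats degradation if
        # rebinding is fast, and the published claim of a minimal degradation
        # effect requires the free-sRNA pool to stay small
        bases = o.pop("bases", (
            ("independent", "independent_with_dissociation",
             {"y5": 1e0, "alpha_rna": PART1_ALPHA_RNA}),
            ("cooperative_association", "cooperative_association",
             {"y4": 1e4, "y5": 1e0, "y6": 1e0, "alpha_rna": PART1_ALPHA_RNA}),
            ("rapid_dissociation", "independent_with_dissociation",
             {"y5": 1e4, "y2": 10 ** 4.5, "alpha_rna": PART1_ALPHA_RNA}),
        ))
        factor = o.pop("degradation_factor", 10.0)
        k5 = o.pop("k5", 1e3)
        cfg = _sweepcfg(o)
        for bname, regime, kw in bases:
            out.append((f"{bname},beta=uniform",
                        build_scheme(regime, k5=k5, **kw), cfg))
            out.append((f"{bname},beta=srna10x",
                        build_scheme("s1_degradation", base=regime, k5=k5,
                                     degradation_factor=factor, **kw), cfg))

    if o:
        raise ValueError(f"unknown overrides for scenario {sid!r}: {sorted(o)}")
    return out


def run_scenario(scenario: Scenario, cache: dict | None = None,
                 progress: bool = False) -> dict:
    """Run every sweep of a scenario.

    Returns ``{label: {"sweep": SweepResult, "robustness": {pair:
    RobustnessSummary}}}``.  Per-label results already present in
    ``cache`` are reused, making long scenario runs resumable;
    convergence failures are logged and recorded per point, never fatal.
    """
    results: dict = {}
    cache = cache if cache is not None else {}
    jobs = expand(scenario)
    for idx, (label, spec, cfg) in enumerate(jobs):
        if label in cache:
            results[label] = cache[label]
            continue
        if progress:
            log.info("[%s] %d/%d %s", scenario.id, idx + 1, len(jobs), label)
        sweep = hfq_sweep(spec, cfg.grid, pairs=list(cfg.pairs),
                          cfg=cfg.convergence)
        summaries = {pair: bounds_and_robustness(sweep, pair)
                     for pair in sweep.pairs}
        entry = {"sweep": sweep, "robustness": summaries, "spec": spec}
        results[label] = entry
        cache[label] = entry
    return results
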