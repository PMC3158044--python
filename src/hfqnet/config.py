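"""Declarative configuration and result serialization.

Network specifications, sweep settings and scenario references are
expressed in a flat YAML/JSON mapping.  Matrices accept either dense
lists-of-lists or, for single-partner networks, the shorthand
``{diagonal: x, off_diagonal: y}``; an explicit matrix wins if both are
somehow given.  Unknown keys are rejected with their location so typos
never silently fall back to defaults.

Result objects export to tidy CSV (one observation per row) and to a
versioned JSON bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .metrics import RobustnessSummary, SweepResult, default_alpha_grid
from .network import BETA_ROLES, NetworkSpec
from .scenarios import SCENARIO_IDS, Scenario
from .steady import ConvergenceConfig

__all__ = ["RunConfig", "load_config", "spec_to_dict", "spec_from_dict",
           "write_results", "load_sweep_csv"]

RESULT_SCHEMA_VERSION = 1

_SPEC_KEYS = {"n_srna", "m_mrna", "alpha_H", "alpha_S", "alpha_T", "beta",
              "beta_overrides", "k1", "kneg1", "k2", "kneg2",
              "k3", "kneg3", "k4", "kneg4", "k5"}
_VECTOR_KEYS = {"alpha_S", "alpha_T", "k1", "kneg1", "k2", "kneg2"}
_MATRIX_KEYS = {"k3", "kneg3", "k4", "kneg4", "k5"}
_CONV_KEYS = {"horizon_multiplier", "rel_check_fraction", "tolerance",
              "rel_tolerance", "max_doublings", "rtol", "atol"}
_GRID_KEYS = {"lo", "hi", "points_per_decade"}
_TOP_KEYS = {"network", "regime", "scenario", "grid", "convergence",
             "pairs", "output", "verbosity"}


class ConfigError(ValueError):
    """A configuration problem, reported with the offending key path."""


def _require_number(val, path: str, minimum=None) -> float:
    if isinstance(val, bool) or not isinstance(val, (int, float)):
        raise ConfigError(f"{path}: expected a number, got {type(val).__name__}")
    if minimum is not None and val < minimum:
        raise ConfigError(f"{path}: must be >= {minimum}, got {val}")
    return float(val)


def _parse_matrix(val, n: int, m: int, path: str) -> np.ndarray:
    if isinstance(val, dict):
        extra = set(val) - {"diagonal", "off_diagonal"}
        if extra:
            raise ConfigError(f"{path}: unknown matrix keys {sorted(extra)}")
        if n != m:
            raise ConfigError(f"{path}: (diagonal, off_diagonal) shorthand "
                              f"requires a square network, got {n}x{m}")
        diag = _require_number(val.get("diagonal", 0.0), f"{path}.diagonal", 0.0)
        off = _require_number(val.get("off_diagonal", 0.0), f"{path}.off_diagonal", 0.0)
        out = np.full((n, m), off)
        np.fill_diagonal(out, diag)
        return out
    arr = np.asarray(val, dtype=float)
    if arr.ndim == 0:
        return np.full((n, m), _require_number(val, path, 0.0))
    if arr.shape != (n, m):
        raise ConfigError(f"{path}: expected a {n}x{m} matrix, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ConfigError(f"{path}: rate constants must be non-negative")
    return arr


def spec_from_dict(d: dict, path: str = "network") -> NetworkSpec:
    """Build a NetworkSpec from its flat mapping form, validating keys."""
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: expected a mapping")
    extra = set(d) - _SPEC_KEYS
    if extra:
        raise ConfigError(f"{path}: unknown keys {sorted(extra)}")
    missing = {"n_srna", "m_mrna", "alpha_H", "beta"} - set(d)
    if missing:
        raise ConfigError(f"{path}: missing required keys {sorted(missing)}")
    n = int(_require_number(d["n_srna"], f"{path}.n_srna", 1))
    m = int(_require_number(d["m_mrna"], f"{path}.m_mrna", 1))
    kw: dict = {"n_srna": n, "m_mrna": m,
                "alpha_H": _require_number(d["alpha_H"], f"{path}.alpha_H", 0.0),
                "beta": _require_number(d["beta"], f"{path}.beta")}
    if kw["beta"] <= 0:
        raise ConfigError(f"{path}.beta: must be positive")
    for key in _VECTOR_KEYS:
        val = d.get(key, 0.0)
        arr = np.asarray(val, dtype=float)
        if np.any(arr < 0):
            raise ConfigError(f"{path}.{key}: must be non-negative")
        kw[key] = arr if arr.ndim else float(arr)
    for key in _MATRIX_KEYS:
        kw[key] = _parse_matrix(d.get(key, 0.0), n, m, f"{path}.{key}")
    bo = d.get("beta_overrides", {})
    if not isinstance(bo, dict):
        raise ConfigError(f"{path}.beta_overrides: expected a mapping")
    for role, val in bo.items():
        if role not in BETA_ROLES:
            raise ConfigError(f"{path}.beta_overrides.{role}: unknown species role; "
                              f"expected one of {BETA_ROLES}")
        arr = np.asarray(val, dtype=float)
        if np.any(arr < 0):
            raise ConfigError(f"{path}.beta_overrides.{role}: must be non-negative")
    kw["beta_overrides"] = {k: (np.asarray(v, dtype=float) if np.ndim(v) else float(v))
                            for k, v in bo.items()}
    try:
        return NetworkSpec(**kw)
    except ValueError as e:
        raise ConfigError(f"{path}: {e}") from e


def spec_to_dict(spec: NetworkSpec) -> dict:
    """Flat mapping form of a NetworkSpec (lossless at double precision)."""
    d = {
        "n_srna": spec.n_srna, "m_mrna": spec.m_mrna,
        "alpha_H": spec.alpha_H, "beta": spec.beta,
        "alpha_S": spec.alpha_S.tolist(), "alpha_T": spec.alpha_T.tolist(),
        "k1": spec.k1.tolist(), "kneg1": spec.kneg1.tolist(),
        "k2": spec.k2.tolist(), "kneg2": spec.kneg2.tolist(),
        "k3": spec.k3.tolist(), "kneg3": spec.kneg3.tolist(),
        "k4": spec.k4.tolist(), "kneg4": spec.kneg4.tolist(),
        "k5": spec.k5.tolist(),
    }
    if spec.beta_overrides:
        d["beta_overrides"] = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                               for k, v in spec.beta_overrides.items()}
    return d


@dataclass
class RunConfig:
    """Validated top-level run configuration."""

    network: NetworkSpec | None = None
    regime: dict | None = None         # {"name": ..., **params}, expanded lazily
    scenario: Scenario | None = None
    grid: np.ndarray = field(default_factory=default_alpha_grid)
    convergence: ConvergenceConfig = field(default_factory=ConvergenceConfig)
    pairs: tuple = ((0, 0),)
    output: str | None = None
    verbosity: int = 0

    def resolve_network(self) -> NetworkSpec:
        if self.network is not None:
            return self.network
        if self.regime is not None:
            from .params import build_scheme
            kw = dict(self.regime)
            return build_scheme(kw.pop("name"), **kw)
        raise ConfigError("config defines neither a network nor a regime")


def _parse_config_dict(data: dict, path: str = "config") -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    extra = set(data) - _TOP_KEYS
    if extra:
        raise ConfigError(f"{path}: unknown keys {sorted(extra)}")
    cfg = RunConfig()
    n_sources = sum(k in data for k in ("network", "regime", "scenario"))
    if n_sources != 1:
        raise ConfigError(f"{path}: exactly one of network/regime/scenario required")
    if "network" in data:
        cfg.network = spec_from_dict(data["network"], f"{path}.network")
    if "regime" in data:
        reg = data["regime"]
        if not isinstance(reg, dict) or "name" not in reg:
            raise ConfigError(f"{path}.regime: expected a mapping with a 'name' key")
        cfg.regime = dict(reg)
    if "scenario" in data:
        sc = data["scenario"]
        if isinstance(sc, str):
            sc = {"id": sc}
        if not isinstance(sc, dict) or "id" not in sc:
            raise ConfigError(f"{path}.scenario: expected an id string or mapping with 'id'")
        if sc["id"] not in SCENARIO_IDS:
            raise ConfigError(f"{path}.scenario.id: unknown id {sc['id']!r}")
        cfg.scenario = Scenario(id=sc["id"], overrides=sc.get("overrides", {}))
        unknown = set(sc) - {"id", "overrides"}
        if unknown:
            raise ConfigError(f"{path}.scenario: unknown keys {sorted(unknown)}")
    if "grid" in data:
        g = data["grid"]
        if isinstance(g, dict):
            extra = set(g) - _GRID_KEYS
            if extra:
                raise ConfigError(f"{path}.grid: unknown keys {sorted(extra)}")
            cfg.grid = default_alpha_grid(
                _require_number(g.get("lo", 1e-5), f"{path}.grid.lo"),
                _require_number(g.get("hi", 1e7), f"{path}.grid.hi"),
                int(g.get("points_per_decade", 10)))
        else:
            cfg.grid = np.asarray(g, dtype=float)
            if cfg.grid.ndim != 1:
                raise ConfigError(f"{path}.grid: expected a 1-D list of values")
    if "convergence" in data:
        c = data["convergence"]
        if not isinstance(c, dict):
            raise ConfigError(f"{path}.convergence: expected a mapping")
        extra = set(c) - _CONV_KEYS
        if extra:
            raise ConfigError(f"{path}.convergence: unknown keys {sorted(extra)}")
        cfg.convergence = ConvergenceConfig(**c)
    if "pairs" in data:
        cfg.pairs = tuple(tuple(int(x) for x in p) for p in data["pairs"])
    cfg.output = data.get("output")
    cfg.verbosity = int(data.get("verbosity", 0))
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    p = Path(path)
    with open(p) as fh:
        data = yaml.safe_load(fh)
    return _parse_config_dict(data, path=str(p))


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------

def write_results(results, path: str | Path, fmt: str | None = None) -> Path:
    """Write a SweepResult, RobustnessSummary or scenario-result mapping.

    CSV gives the tidy per-observation table; JSON wraps the same data in
    a schema-versioned bundle.  The format is inferred from the file
    suffix unless given explicitly.
    """
    p = Path(path)
    fmt = fmt or (p.suffix.lstrip(".") or "csv")
    p.parent.mkdir(parents=True, exist_ok=True)

    if isinstance(results, SweepResult):
        if fmt == "csv":
            results.to_frame().to_csv(p, index=False)
        elif fmt == "json":
            payload = {"schema_version": RESULT_SCHEMA_VERSION,
                       "kind": "sweep",
                       "records": results.to_frame().to_dict(orient="records")}
            p.write_text(json.dumps(payload, indent=1))
        else:
            raise ConfigError(f"unknown output format {fmt!r}")
        return p

    if isinstance(results, RobustnessSummary):
        payload = {"schema_version": RESULT_SCHEMA_VERSION,
                   "kind": "robustness", **results.to_dict()}
        p.write_text(json.dumps(payload, indent=1))
        return p

    if isinstance(results, dict):  # scenario results keyed by label
        if fmt == "csv":
            import pandas as pd
            frames = []
            for label, entry in results.items():
                df = entry["sweep"].to_frame()
                df.insert(0, "label", label)
                frames.append(df)
            pd.concat(frames, ignore_index=True).to_csv(p, index=False)
        elif fmt == "json":
            payload = {"schema_version": RESULT_SCHEMA_VERSION,
                       "kind": "scenario",
                       "labels": {
                           label: {
                               "robustness": {f"{i},{j}": s.to_dict()
                                              for (i, j), s in entry["robustness"].items()},
                               "records": entry["sweep"].to_frame().to_dict(orient="records"),
                           } for label, entry in results.items()}}
            p.write_text(json.dumps(payload, indent=1))
        else:
            raise ConfigError(f"unknown output format {fmt!r}")
        return p

    raise ConfigError(f"cannot serialize object of type {type(results).__name__}")


def load_sweep_csv(path: str | Path) -> "pd.DataFrame":
    """Read back a tidy sweep CSV (column names are part of the contract)."""
    import pandas as pd
    df = pd.read_csv(path)
    required = {"alpha_H", "pair_i", "pair_j", "relative_hfq", "percent_duplex"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: sweep CSV missing columns {sorted(missing)}")
    return df
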