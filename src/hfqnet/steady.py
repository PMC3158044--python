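"""Steady-state solution of the Hfq network ODEs.

The primary route integrates the stiff ODE system from an all-zero initial
condition (the state of a cell before any of the species is induced) until
the trajectory stops changing.  Convergence follows the classic two-point
check: the solution at 90% and 100% of the horizon must agree per species,
with the horizon defaulting to 100 RNA lifetimes (lifetime = 1/beta) and
doubling on failure up to a cap.  Rate constants in this model span more
than ten orders of magnitude within a single network, so a stiff-capable
integrator (LSODA with an analytic Jacobian) is a hard requirement.

A damped Newton root-finder (:func:`algebraic_oracle`) provides an
independent algebraic solution for small systems, used to cross-check the
integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .network import NetworkSpec, StateVector, derivatives_flat, jacobian_flat, state_dimension

__all__ = ["ConvergenceConfig", "SteadyState", "integrate_to_steady_state", "algebraic_oracle"]


@dataclass(frozen=True)
class ConvergenceConfig:
    """Controls for the steady-state integration.

    horizon_multiplier
        Integration horizon in RNA lifetimes (1/beta); default 100.
    rel_check_fraction
        The earlier of the two convergence checkpoints, as a fraction of
        the horizon; default 0.9.
    tolerance
        Maximum allowed per-species absolute difference between the two
        checkpoints (1e-10 by default).
    rel_tolerance
        Relative-difference guard for species whose concentrations are so
        large that the absolute criterion is below double precision.
    max_doublings
        How many times the horizon may be doubled before reporting failure.
    rtol, atol
        Integrator tolerances.
    """

    horizon_multiplier: float = 100.0
    rel_check_fraction: float = 0.9
    tolerance: float = 1e-10
    rel_tolerance: float = 1e-9
    max_doublings: int = 6
    rtol: float = 1e-10
    atol: float = 1e-12

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if not 0.0 < self.rel_check_fraction < 1.0:
            raise ValueError("rel_check_fraction must lie in (0, 1)")


@dataclass
class SteadyState:
    """A converged (or failed) steady-state solution."""

    state: StateVector
    converged: bool
    horizon: float
    residual: float            # max |dy/dt| at the reported state
    max_delta: float           # worst per-species change between the checkpoints
    message: str = ""
    method: str = "integration"
    spec: NetworkSpec = field(repr=False, default=None)

    def __bool__(self) -> bool:  # truthiness == convergence
        return self.converged


def _integrate(spec: NetworkSpec, y0: np.ndarray, horizon: float,
               cfg: ConvergenceConfig):
    t_check = cfg.rel_check_fraction * horizon
    sol = solve_ivp(
        lambda t, y: derivatives_flat(spec, y),
        (0.0, horizon),
        y0,
        method="LSODA",
        jac=lambda t, y: jacobian_flat(spec, y),
        t_eval=(t_check, horizon),
        rtol=cfg.rtol,
        atol=cfg.atol,
    )
    return sol


def integrate_to_steady_state(spec: NetworkSpec,
                              cfg: ConvergenceConfig | None = None,
                              y0: np.ndarray | None = None) -> SteadyState:
    """Run the network to steady state from the all-zero initial condition.

    Returns a :class:`SteadyState`; ``converged`` is False (never an
    exception) if the two-checkpoint criterion still fails after the
    horizon has been doubled ``max_doublings`` times or the integrator
    itself fails.
    """
    cfg = cfg or ConvergenceConfig()
    dim = state_dimension(spec)
    if y0 is None:
        y0 = np.zeros(dim)
    else:
        y0 = np.asarray(y0, dtype=float)
    horizon = cfg.horizon_multiplier / spec.beta

    for _ in range(cfg.max_doublings + 1):
        sol = _integrate(spec, y0, horizon, cfg)
        if not sol.success:
            return SteadyState(
                state=StateVector.from_flat(np.clip(y0, 0.0, None), spec),
                converged=False, horizon=horizon, residual=np.inf,
                max_delta=np.inf, message=f"integrator failure: {sol.message}",
                spec=spec)
        y_early, y_final = sol.y[:, 0], sol.y[:, 1]
        delta = np.abs(y_final - y_early)
        scale = np.maximum(np.abs(y_final), np.abs(y_early))
        ok = (delta <= cfg.tolerance) | (delta <= cfg.rel_tolerance * scale)
        max_delta = float(delta.max()) if delta.size else 0.0
        if np.all(ok):
            y = np.clip(y_final, 0.0, None)  # clip solver-level negative round-off
            resid = float(np.max(np.abs(derivatives_flat(spec, y))))
            return SteadyState(StateVector.from_flat(y, spec), True, horizon,
                               resid, max_delta, spec=spec)
        horizon *= 2.0

    y = np.clip(y_final, 0.0, None)
    resid = float(np.max(np.abs(derivatives_flat(spec, y))))
    return SteadyState(StateVector.from_flat(y, spec), False, horizon, resid,
                       max_delta,
                       message=f"no convergence after horizon {horizon:g} "
                               f"(max per-species delta {max_delta:.3g})",
                       spec=spec)


def algebraic_oracle(spec: NetworkSpec,
                     cfg: ConvergenceConfig | None = None,
                     warm_start: np.ndarray | None = None) -> SteadyState:
    """Steady state via a multivariate root-finder, independent of the horizon.

    Solves ``f(y) = 0`` with a damped Newton method (scipy ``hybr``),
    started from the integrator's answer (or a supplied warm start) and,
    if that fails, from a sequence of cold starts.  Intended for small
    systems (n*m up to ~9) as a cross-check of the integration route; on
    divergence the integration result is returned with
    ``method="integration-fallback"``.
    """
    cfg = cfg or ConvergenceConfig()
    dim = state_dimension(spec)

    starts = []
    integ = None
    if warm_start is not None:
        starts.append(np.asarray(warm_start, dtype=float))
    else:
        integ = integrate_to_steady_state(spec, cfg)
        starts.append(integ.state.to_flat())
    # cold starts: production/degradation balance placed in the free pools
    cold = np.zeros(dim)
    cold[0] = spec.alpha_H / spec.beta
    cold[1:1 + spec.n_srna] = spec.alpha_S / spec.beta
    cold[1 + spec.n_srna:1 + spec.n_srna + spec.m_mrna] = spec.alpha_T / spec.beta
    starts.append(cold)
    starts.append(np.full(dim, 1e-3))

    scale = max(1.0, spec.alpha_H / spec.beta,
                float(np.max(spec.alpha_S) / spec.beta),
                float(np.max(spec.alpha_T) / spec.beta))
    for y0 in starts:
        res = root(lambda y: derivatives_flat(spec, y), y0,
                   jac=lambda y: jacobian_flat(spec, y), method="hybr")
        y = res.x
        resid = float(np.max(np.abs(derivatives_flat(spec, y))))
        # accept only non-negative (to round-off) roots with a tiny residual
        if resid <= 1e-9 * scale and np.all(y >= -1e-9 * scale):
            y = np.clip(y, 0.0, None)
            return SteadyState(StateVector.from_flat(y, spec), True,
                               np.inf, resid, 0.0, method="algebraic", spec=spec)

    if integ is None:
        integ = integrate_to_steady_state(spec, cfg)
    integ.method = "integration-fallback"
    integ.message = (integ.message + " | root-finder divergence").strip(" |")
    return integ
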