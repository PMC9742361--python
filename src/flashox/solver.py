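"""Time integration of the oxygen reaction-diffusion equation.

The governing equation for the tissue oxygen concentration O(x, t) (μM) is

    dO/dt = -K1 Ddot O/(O + l) - K2 O/(O + λ) + K3 lap(O)

solved on a :class:`~flashox.geometry.DiscreteDomain` with vessel-wall
Dirichlet values and zero-flux outer faces, over three protocol stages:

1. *pre*: no radiation; marched to the metabolism-diffusion equilibrium;
2. *irradiation*: dose rate applied as a step function over [0, T];
3. *recovery*: dose rate off, oxygen replenishes from the vessels.

The scheme is IMEX: diffusion is integrated implicitly (backward Euler,
unconditionally stable, so the time step is set by the stage duration and
not by the grid), and the reaction terms explicitly at the current state.
Both reaction terms are non-stiff at the rates of interest, and the IMEX
fixed point is exactly the discrete steady state of the equation, so
equilibria do not depend on the internal time step.  After every step the
field is floored at zero and vessel nodes are overwritten with their
supply values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import DiscreteDomain, GridSpec, default_probe_point
from .parameters import BoundarySupply, IrradiationProtocol, TissueParameters

logger = logging.getLogger(__name__)

STAGE_PRE = "pre"
STAGE_IRRADIATION = "irradiation"
STAGE_RECOVERY = "recovery"


class SolverError(RuntimeError):
    """The time integrator could not proceed."""


class ConvergenceError(SolverError):
    """Equilibration did not reach the stopping criterion in time."""


def reaction_rate(o: np.ndarray | float, dose_rate: float,
                  params: TissueParameters) -> np.ndarray | float:
    """Local reaction rate dO/dt (μM/s), excluding diffusion.

    Radiolytic depletion ``-K1 Ddot O/(O+l)`` plus Michaelis-Menten
    metabolic consumption ``-K2 O/(O+λ)``.  Always <= 0 and -> 0 as O -> 0.
    """
    o_arr = np.asarray(o, dtype=float)
    if np.any(o_arr < 0):
        raise ValueError("oxygen concentration must be >= 0")
    if dose_rate < 0:
        raise ValueError("dose rate must be >= 0")
    out = (-params.k1_depletion * dose_rate * o_arr / (o_arr + params.l_depletion)
           - params.k2_metabolism * o_arr / (o_arr + params.lambda_metabolism))
    return out if isinstance(o, np.ndarray) else float(out)


@dataclass(frozen=True)
class OxygenState:
    """The oxygen field at one instant: per-node concentrations in μM."""

    time: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("oxygen state contains negative concentrations")


@dataclass(frozen=True)
class StageResult:
    """Snapshots of one protocol stage.

    ``times``/``values`` hold the stored snapshots (possibly strided);
    ``n_steps`` is the number of time steps actually taken.
    """

    stage: str
    times: np.ndarray          # (n_snapshots,)
    values: np.ndarray         # (n_snapshots, n_nodes)
    n_steps: int
    dt: float

    @property
    def final(self) -> OxygenState:
        return OxygenState(float(self.times[-1]), self.values[-1])


@dataclass
class OxygenHistory:
    """Ordered stage results of a full pre/irradiation/recovery protocol."""

    stages: list[StageResult] = field(default_factory=list)

    def stage(self, name: str) -> StageResult:
        for s in self.stages:
            if s.stage == name:
                return s
        raise KeyError(f"history has no stage {name!r}")

    @property
    def final(self) -> OxygenState:
        return self.stages[-1].final

    def midpoint_trace(self, domain: DiscreteDomain,
                       point: Optional[Sequence[float]] = None
                       ) -> tuple[np.ndarray, np.ndarray]:
        """(times, O) at the inter-vessel midpoint (or an explicit probe)."""
        idx = domain.nearest_node(
            default_probe_point(domain) if point is None else point)
        times = np.concatenate([s.times for s in self.stages])
        vals = np.concatenate([s.values[:, idx] for s in self.stages])
        return times, vals


class Stepper:
    """Pre-factorized IMEX step operator for one fixed time step."""

    def __init__(self, domain: DiscreteDomain, params: TissueParameters,
                 dt: float):
        if not dt > 0:
            raise SolverError(f"dt must be > 0, got {dt!r}")
        self.domain = domain
        self.params = params
        self.dt = dt
        n = domain.n_nodes
        A = sp.eye(n, format="csr") - dt * params.k3_diffusion * domain.laplacian()
        try:
            self._solve = spla.factorized(A.tocsc())
        except RuntimeError as exc:  # pragma: no cover - defensive
            raise SolverError(f"singular linear system: {exc}") from exc
        self._tissue = domain.tissue_mask

    def check_reaction_stability(self, dose_rate: float) -> None:
        """Warn when dt may under-resolve the explicit reaction part.

        The worst-case reaction slope is K1 Ddot / l + K2 / λ (attained at
        O = 0, where both saturating terms are steepest).  This is a
        conservative bound — away from anoxia the terms are nearly
        constant-rate — so exceeding it is logged, not fatal.
        """
        p = self.params
        slope = (p.k1_depletion * dose_rate / p.l_depletion
                 + (p.k2_metabolism / p.lambda_metabolism
                    if p.lambda_metabolism > 0 else 0.0))
        if self.dt * slope > 1.0:
            logger.warning(
                "dt = %g s may under-resolve the explicit reaction terms "
                "near anoxia at dose rate %g Gy/s (dt * max|dR/dO| = %.2f)",
                self.dt, dose_rate, self.dt * slope)

    def advance(self, values: np.ndarray, t_new: float,
                dose_rate: float) -> np.ndarray:
        """One IMEX step from ``values`` to time ``t_new``."""
        rhs = values + self.dt * np.where(
            self._tissue, reaction_rate(values, dose_rate, self.params), 0.0)
        rhs[self.domain.dirichlet_mask] = self.domain.supply_values(t_new)
        out = self._solve(rhs)
        np.clip(out, 0.0, None, out=out)
        return out


def step(state: OxygenState, dt: float, dose_rate: float,
         supplies: np.ndarray, domain: DiscreteDomain,
         params: TissueParameters) -> OxygenState:
    """Advance one IMEX step with explicitly given per-vessel-node values.

    Convenience wrapper over :class:`Stepper` for single-step use; loops
    should construct a :class:`Stepper` once per stage instead.
    """
    stepper = Stepper(domain, params, dt)
    stepper.check_reaction_stability(dose_rate)
    rhs = state.values + dt * np.where(
        domain.tissue_mask, reaction_rate(state.values, dose_rate, params), 0.0)
    rhs[domain.dirichlet_mask] = supplies
    out = stepper._solve(rhs)
    np.clip(out, 0.0, None, out=out)
    return OxygenState(state.time + dt, out)


def steady_state_residual(values: np.ndarray, domain: DiscreteDomain,
                          params: TissueParameters) -> np.ndarray:
    """|K3 lap(O) - K2 O/(O+λ)| at tissue nodes, μM/s (0 at equilibrium)."""
    r = (params.k3_diffusion * (domain.laplacian() @ values)
         + reaction_rate(values, 0.0, params))
    return np.abs(r[domain.tissue_mask])


def equilibrate(domain: DiscreteDomain, params: TissueParameters,
                grid_spec: GridSpec, at_time: float = 0.0) -> OxygenState:
    """March to the pre-irradiation metabolism-diffusion equilibrium.

    Starts from a uniform field at the largest supply level and marches
    with a fixed internal step ``recovery_duration / steps_per_stage``
    until (a) the max-norm per-step relative change drops below
    ``equilibration_tolerance`` (local O floored at 0.1 μM so the
    criterion stays meaningful in anoxic cores) and (b) the steady-state
    residual drops below ``equilibration_residual_tol``.  Supplies are
    evaluated at ``at_time`` (the pre-irradiation stage has t < 0, where
    transient supplies are still at their base level).

    Raises :class:`ConvergenceError` if ``equilibration_max_time`` of
    simulated time passes first.
    """
    dt = grid_spec.recovery_duration / grid_spec.steps_per_stage
    stepper = Stepper(domain, params, dt)
    stepper.check_reaction_stability(0.0)
    o = np.full(domain.n_nodes,
                max(s.value_at(at_time) for s in domain.supplies))
    o[domain.dirichlet_mask] = domain.supply_values(at_time)
    max_steps = int(np.ceil(grid_spec.equilibration_max_time / dt))
    res = np.inf
    for k in range(max_steps):
        o_new = stepper.advance(o, at_time, 0.0)
        change = np.max(np.abs(o_new - o) / np.maximum(o_new, 0.1))
        o = o_new
        if change < grid_spec.equilibration_tolerance:
            res = float(np.max(steady_state_residual(o, domain, params)))
            if res <= grid_spec.equilibration_residual_tol:
                logger.info(
                    "equilibrated in %d steps (dt=%.3g s, residual %.3g μM/s)",
                    k + 1, dt, res)
                return OxygenState(0.0, o)
    raise ConvergenceError(
        f"no equilibrium within {grid_spec.equilibration_max_time} s of "
        f"simulated time (final residual {res:.3g} μM/s)")


def run_stage(initial: OxygenState, duration: float, n_steps: int,
              dose_rate_fn: Callable[[float], float],
              domain: DiscreteDomain, params: TissueParameters,
              stage: str, snapshot_stride: int = 1,
              step_observer: Optional[
                  Callable[[float, np.ndarray, np.ndarray], None]] = None,
              ) -> StageResult:
    """Integrate one stage with ``n_steps`` uniform steps of
    ``duration / n_steps``.

    The dose rate is evaluated at each step midpoint.  ``step_observer``
    (if given) is called after every step as
    ``observer(dt, values_before, values_after)`` — this is how dose
    integrals are accumulated at full resolution even when snapshots are
    strided.
    """
    if not duration > 0:
        raise SolverError(f"stage duration must be > 0, got {duration!r}")
    if n_steps < 1:
        raise SolverError("n_steps must be >= 1")
    dt = duration / n_steps
    stepper = Stepper(domain, params, dt)
    stepper.check_reaction_stability(max(dose_rate_fn(0.5 * dt), 0.0))
    t0 = initial.time
    o = initial.values.copy()
    times = [t0]
    snaps = [o.copy()]
    for k in range(n_steps):
        t_new = t0 + (k + 1) * dt
        rate = dose_rate_fn(t0 + (k + 0.5) * dt)
        o_new = stepper.advance(o, t_new, rate)
        if step_observer is not None:
            step_observer(dt, o, o_new)
        o = o_new
        if (k + 1) % snapshot_stride == 0 or k == n_steps - 1:
            times.append(t_new)
            snaps.append(o.copy())
    logger.info("stage %-11s: %d steps, dt=%.3g s, O in [%.4g, %.4g] μM",
                stage, n_steps, dt, o.min(), o.max())
    return StageResult(stage, np.array(times), np.array(snaps), n_steps, dt)


def run_protocol(domain: DiscreteDomain, params: TissueParameters,
                 protocol: IrradiationProtocol, grid_spec: GridSpec,
                 initial: Optional[OxygenState] = None,
                 irradiation_observer: Optional[
                     Callable[[float, np.ndarray, np.ndarray], None]] = None,
                 include_recovery: bool = True) -> OxygenHistory:
    """Equilibrate, irradiate, recover.

    The irradiation stage spans [0, T] with T = dose / dose_rate and the
    configured number of steps; recovery spans ``recovery_duration`` with
    the same step count and zero dose rate.  A pre-computed equilibrium
    may be passed as ``initial`` (paired deliveries must start from the
    identical state).  Transient supplies switch on at t = 0 and persist
    through recovery.
    """
    if initial is None:
        initial = equilibrate(domain, params, grid_spec, at_time=-1.0)
    history = OxygenHistory()
    history.stages.append(StageResult(
        STAGE_PRE, np.array([initial.time - 0.0]),
        initial.values[None, :].copy(), 0, 0.0))
    if protocol.dose == 0.0:
        # degenerate delivery: nothing happens; all stages sit at equilibrium
        history.stages.append(StageResult(
            STAGE_IRRADIATION, np.array([0.0]),
            initial.values[None, :].copy(), 0, 0.0))
        if include_recovery:
            history.stages.append(StageResult(
                STAGE_RECOVERY, np.array([grid_spec.recovery_duration]),
                initial.values[None, :].copy(), 0, 0.0))
        return history
    T = protocol.duration
    irr = run_stage(
        OxygenState(0.0, initial.values), T, grid_spec.steps_per_stage,
        lambda t: protocol.dose_rate, domain, params, STAGE_IRRADIATION,
        snapshot_stride=grid_spec.irradiation_snapshot_stride,
        step_observer=irradiation_observer)
    history.stages.append(irr)
    if include_recovery:
        rec = run_stage(
            irr.final, grid_spec.recovery_duration, grid_spec.steps_per_stage,
            lambda t: 0.0, domain, params, STAGE_RECOVERY,
            snapshot_stride=grid_spec.other_snapshot_stride)
        history.stages.append(rec)
    return history
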