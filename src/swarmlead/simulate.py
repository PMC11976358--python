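"""Time integration of the hyperbolic follower-leader systems.

The four density fields advect at their own constant speeds (followers at
±γ, leaders at +β₊/−β₋) and exchange mass between the two orientations at
the turning rates from :mod:`swarmlead.turning`. The scheme is a
conservative first-order upwind discretization of the transport terms with
explicit Euler treatment of the turning exchange; under the CFL condition
and the rate bound ``dt·(λ₁+λ₂) ≤ 1`` every update coefficient is
non-negative, so densities stay non-negative and each species' mass is
conserved to roundoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import KernelSet, build_kernels
from .params import Grid, InitialConditionSpec, ModelParams, build_follower_ic, \
    build_leader_ic, prescribed_leader_field
from .turning import assemble_turning

__all__ = [
    "PopulationState",
    "RunSpec",
    "SimulationResult",
    "default_dt",
    "step",
    "run_m1",
    "run_m2m3",
]

NEGATIVITY_TOL = -1e-10


@dataclass
class PopulationState:
    """The four density fields on the grid at one instant."""

    u_plus: np.ndarray
    u_minus: np.ndarray
    v_plus: np.ndarray
    v_minus: np.ndarray
    time: float = 0.0

    @property
    def u(self) -> np.ndarray:
        return self.u_plus + self.u_minus

    @property
    def v(self) -> np.ndarray:
        return self.v_plus + self.v_minus

    @property
    def p(self) -> np.ndarray:
        return self.u + self.v

    @property
    def p_plus(self) -> np.ndarray:
        return self.u_plus + self.v_plus

    @property
    def p_minus(self) -> np.ndarray:
        return self.u_minus + self.v_minus

    def copy(self) -> "PopulationState":
        return PopulationState(
            self.u_plus.copy(), self.u_minus.copy(),
            self.v_plus.copy(), self.v_minus.copy(), self.time,
        )

    def check_nonnegative(self) -> None:
        worst = min(
            self.u_plus.min(), self.u_minus.min(),
            self.v_plus.min(), self.v_minus.min(),
        )
        if worst < NEGATIVITY_TOL:
            raise RuntimeError(
                f"density fell below tolerance at t={self.time:g}: min={worst:g}; "
                "check the CFL condition and the turning-rate time-step bound"
            )


@dataclass(frozen=True)
class RunSpec:
    """Run control: horizon, step size, recording stride, model variant."""

    t_end: float
    model: str
    dt: float | None = None  # None: auto from CFL and turning-rate bounds
    snapshot_every: int = 50  # record every this-many steps
    cfl: float = 0.9

    def __post_init__(self) -> None:
        if not self.t_end > 0:
            raise ValueError("t_end must be positive")
        if self.model not in ("M1", "M2", "M3"):
            raise ValueError(f"unknown model {self.model!r}")
        if not 0 < self.cfl <= 1:
            raise ValueError("CFL number must lie in (0, 1]")


@dataclass
class SimulationResult:
    """Recorded trajectory of one run."""

    times: np.ndarray
    snapshots: list[PopulationState]
    params: ModelParams
    grid: Grid
    model: str
    dt: float
    leader_center_unwrapped: np.ndarray | None = None  # M1 only

    def mass_history(self, species: str = "u") -> np.ndarray:
        """∫ density dx per snapshot for ``species`` in {"u", "v", "p"}."""
        return np.array(
            [getattr(s, species).sum() * self.grid.dx for s in self.snapshots]
        )

    def to_frame(self):
        """Snapshots as a tidy DataFrame (x, t, u_plus, ..., v_minus)."""
        import pandas as pd

        rows = []
        for t, s in zip(self.times, self.snapshots):
            rows.append(pd.DataFrame({
                "t": t, "x": self.grid.cell_centers,
                "u_plus": s.u_plus, "u_minus": s.u_minus,
                "v_plus": s.v_plus, "v_minus": s.v_minus,
            }))
        return pd.concat(rows, ignore_index=True)


def default_dt(params: ModelParams, grid: Grid, model: str, cfl: float = 0.9) -> float:
    """Largest positivity-preserving explicit step.

    The upwind/Euler update multiplies each density by
    ``1 − c·dt/dx − dt·λ``, so non-negativity needs the *combined* bound
    ``dt·(v_max/dx + λ₁ + λ₂) ≤ 1``; the CFL safety factor is applied to
    the whole sum.
    """
    speeds = [params.gamma]
    if model != "M1":
        speeds += [params.beta_plus, params.beta_minus]
    vmax = max(speeds)
    total = vmax / grid.dx + params.lambda1 + params.lambda2
    if total <= 0:
        raise ValueError("all speeds and turning rates are zero; nothing to evolve")
    return cfl / total


def _advect_plus(f: np.ndarray, c: float, dt: float, dx: float) -> np.ndarray:
    """Upwind update of the transport part for a rightward field."""
    return f - (c * dt / dx) * (f - np.roll(f, 1))


def _advect_minus(f: np.ndarray, c: float, dt: float, dx: float) -> np.ndarray:
    return f + (c * dt / dx) * (np.roll(f, -1) - f)


def step(
    state: PopulationState,
    params: ModelParams,
    kernels: KernelSet,
    grid: Grid,
    dt: float,
    model: str,
) -> PopulationState:
    """Advance the state by one explicit step of size dt.

    Under M1 only the follower fields are evolved (the leader field is
    prescribed and must be refreshed by the caller).
    """
    vmax = params.gamma if model == "M1" else max(
        params.gamma, params.beta_plus, params.beta_minus
    )
    if vmax * dt / grid.dx > 1.0 + 1e-12:
        raise ValueError(
            f"CFL violation: v*dt/dx = {vmax * dt / grid.dx:g} > 1"
        )

    tf = assemble_turning(state, params, kernels, grid, model)
    exch_u = -tf.lam_u_plus * state.u_plus + tf.lam_u_minus * state.u_minus
    u_plus = _advect_plus(state.u_plus, params.gamma, dt, grid.dx) + dt * exch_u
    u_minus = _advect_minus(state.u_minus, params.gamma, dt, grid.dx) - dt * exch_u

    if model == "M1":
        v_plus, v_minus = state.v_plus, state.v_minus
    else:
        exch_v = -tf.lam_v_plus * state.v_plus + tf.lam_v_minus * state.v_minus
        v_plus = _advect_plus(state.v_plus, params.beta_plus, dt, grid.dx) + dt * exch_v
        v_minus = _advect_minus(state.v_minus, params.beta_minus, dt, grid.dx) - dt * exch_v

    new = PopulationState(u_plus, u_minus, v_plus, v_minus, state.time + dt)
    new.check_nonnegative()
    return new


def _plan_steps(t_end: float, dt: float) -> tuple[int, float]:
    n_steps = max(1, int(np.ceil(t_end / dt - 1e-12)))
    return n_steps, t_end / n_steps


def run_m1(
    params: ModelParams,
    follower_ic: InitialConditionSpec,
    leader_ic: InitialConditionSpec,
    run_spec: RunSpec,
    grid: Grid,
    kernels: KernelSet | None = None,
) -> SimulationResult:
    """Simulate the indifferent-leader model.

    The leader density is a rigid rightward-translating pulse evaluated
    analytically at every step; only the followers evolve. The unwrapped
    leader center is recorded for covered-distance accounting.
    """
    if run_spec.model != "M1":
        raise ValueError("run_spec.model must be 'M1'")
    if kernels is None:
        kernels = build_kernels(params, grid)
    dt = run_spec.dt or default_dt(params, grid, "M1", run_spec.cfl)
    n_steps, dt = _plan_steps(run_spec.t_end, dt)

    u_p, u_m = build_follower_ic(follower_ic, grid)
    v_p, v_m, center = prescribed_leader_field(0.0, params, leader_ic, grid)
    state = PopulationState(u_p, u_m, v_p, v_m, 0.0)

    times, snaps, centers = [0.0], [state.copy()], [center]
    for k in range(1, n_steps + 1):
        state = step(state, params, kernels, grid, dt, "M1")
        state.time = k * dt  # avoid accumulated roundoff in recorded times
        v_p, v_m, center = prescribed_leader_field(k * dt, params, leader_ic, grid)
        state.v_plus, state.v_minus = v_p, v_m
        if k % run_spec.snapshot_every == 0 or k == n_steps:
            times.append(state.time)
            snaps.append(state.copy())
            centers.append(center)

    return SimulationResult(
        np.array(times), snaps, params, grid, "M1", dt,
        leader_center_unwrapped=np.array(centers),
    )


def run_m2m3(
    params: ModelParams,
    follower_ic: InitialConditionSpec,
    leader_ic: InitialConditionSpec,
    run_spec: RunSpec,
    grid: Grid,
    kernels: KernelSet | None = None,
    initial_state: PopulationState | None = None,
) -> SimulationResult:
    """Simulate the observant (M2) or persuadable (M3) leader model.

    All four fields evolve; a speed bias (β₊ > β₋) acts purely through the
    transport speeds. ``initial_state`` overrides the pulse initial
    conditions (used e.g. to start from a homogeneous steady state).
    """
    model = run_spec.model
    if model not in ("M2", "M3"):
        raise ValueError("run_spec.model must be 'M2' or 'M3'")
    if kernels is None:
        kernels = build_kernels(params, grid)
    dt = run_spec.dt or default_dt(params, grid, model, run_spec.cfl)
    n_steps, dt = _plan_steps(run_spec.t_end, dt)

    if initial_state is None:
        u_p, u_m = build_follower_ic(follower_ic, grid)
        v_p, v_m = build_leader_ic(leader_ic, grid)
        state = PopulationState(u_p, u_m, v_p, v_m, 0.0)
    else:
        state = initial_state.copy()
        state.time = 0.0

    times, snaps = [0.0], [state.copy()]
    for k in range(1, n_steps + 1):
        state = step(state, params, kernels, grid, dt, model)
        state.time = k * dt
        if k % run_spec.snapshot_every == 0 or k == n_steps:
            times.append(state.time)
            snaps.append(state.copy())

    return SimulationResult(np.array(times), snaps, params, grid, model, dt)
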