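"""Spatially homogeneous steady states of the reactive-leader models.

Dropping space, the right-moving follower and leader fractions (u*, v*)
obey a two-variable ODE whose equilibria are the roots of a pair of
residual functions; the left-moving fractions follow from conservation,
u** = A_u − u* and v** = A_v − v*. The composite parameter
λ = 0.5λ₂/(0.5λ₂ + λ₁) collapses the turning rates, and the kernel
half-line mass is taken as 1 (idealized-kernel convention). For observant
leaders (M2) the leader equation decouples and has a closed-form unique
root; for persuadable leaders (M3) the pair is genuinely coupled and can
exhibit multistability and hysteresis under conflicting cues.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

__all__ = [
    "NonSpatialParams",
    "SteadyState",
    "BifurcationBranch",
    "h_u",
    "h_v_m2",
    "v_star_closed_form",
    "h_v_m3",
    "find_steady_states",
    "sweep_branches",
    "continue_branch",
]

RESIDUAL_TOL = 1e-10
DEDUP_TOL = 1e-8


@dataclass(frozen=True)
class NonSpatialParams:
    """Parameters of the non-spatial (space-free) problem.

    ``lam`` is the composite turning parameter 0.5λ₂/(0.5λ₂ + λ₁); it is
    derived from ``lambda1``/``lambda2`` unless passed explicitly.
    """

    Au: float = 1.0
    Av: float = 1.0
    ql: float = 0.5
    alpha_plus: float = 1.0
    alpha_minus: float = 1.0
    eta: float = 0.0
    y0: float = 2.0
    lambda1: float = 0.8
    lambda2: float = 3.6
    lam: float | None = None

    def __post_init__(self) -> None:
        if self.lam is None:
            denom = 0.5 * self.lambda2 + self.lambda1
            if denom <= 0:
                raise ValueError("lambda1 + lambda2/2 must be positive")
            object.__setattr__(self, "lam", 0.5 * self.lambda2 / denom)
        if not 0 <= self.lam <= 1:
            raise ValueError(f"composite lam must lie in [0, 1], got {self.lam}")
        for name in ("Au", "Av"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def A(self) -> float:
        return self.Au + self.Av

    def with_(self, **changes) -> "NonSpatialParams":
        if ("lambda1" in changes or "lambda2" in changes) and "lam" not in changes:
            changes["lam"] = None
        return replace(self, **changes)


@dataclass(frozen=True)
class SteadyState:
    """One homogeneous equilibrium with its time-only stability."""

    u_star: float
    u_starstar: float
    v_star: float
    v_starstar: float
    stability: str  # "stable" | "unstable"
    eigenvalues: tuple[complex, complex]
    model: str

    @property
    def stable(self) -> bool:
        return self.stability == "stable"

    @property
    def right_fraction_u(self) -> float:
        """Proportion of right-moving followers, u*/A_u."""
        return self.u_star / (self.u_star + self.u_starstar)

    @property
    def right_fraction_v(self) -> float:
        return self.v_star / (self.v_star + self.v_starstar)


def _bracket(nsp: NonSpatialParams, u_star, v_star):
    """Shared alignment bracket 2 q_l [A_u − 2u* + α⁻(A_v − v*) − α⁺ v*]."""
    return 2.0 * nsp.ql * (
        nsp.Au - 2.0 * np.asarray(u_star)
        + nsp.alpha_minus * (nsp.Av - np.asarray(v_star))
        - nsp.alpha_plus * np.asarray(v_star)
    )


def h_u(u_star, v_star, nsp: NonSpatialParams):
    """Follower equilibrium residual (identical for M2 and M3).

    Zero where the flux of followers turning right equals the flux turning
    left; independent of the environmental bias η, which only reaches
    followers through the leader state v*.
    """
    B = _bracket(nsp, u_star, v_star)
    u_star = np.asarray(u_star)
    return (
        -u_star * (1.0 + nsp.lam * np.tanh(B - nsp.y0))
        + (nsp.Au - u_star) * (1.0 + nsp.lam * np.tanh(-B - nsp.y0))
    )


def h_v_m2(v_star, nsp: NonSpatialParams):
    """Observant-leader equilibrium residual: bias-only alignment."""
    v_star = np.asarray(v_star)
    t_minus = np.tanh(-nsp.ql * nsp.eta - nsp.y0)
    t_plus = np.tanh(nsp.ql * nsp.eta - nsp.y0)
    return (
        -v_star * (1.0 + nsp.lam * t_minus)
        + (nsp.Av - v_star) * (1.0 + nsp.lam * t_plus)
    )


def v_star_closed_form(nsp: NonSpatialParams) -> float:
    """The unique observant-leader equilibrium v*.

    The residual is affine and strictly decreasing in v*, so the root is
    unique: v* = A_v[1 + λ tanh(q_l η − y₀)] /
    [2 + λ tanh(−q_l η − y₀) + λ tanh(q_l η − y₀)].
    """
    t_minus = np.tanh(-nsp.ql * nsp.eta - nsp.y0)
    t_plus = np.tanh(nsp.ql * nsp.eta - nsp.y0)
    return nsp.Av * (1.0 + nsp.lam * t_plus) / (
        2.0 + nsp.lam * t_minus + nsp.lam * t_plus
    )


def h_v_m3(u_star, v_star, nsp: NonSpatialParams):
    """Persuadable-leader equilibrium residual: social bracket plus η bias."""
    B = _bracket(nsp, u_star, v_star)
    v_star = np.asarray(v_star)
    shift = nsp.ql * nsp.eta
    return (
        -v_star * (1.0 + nsp.lam * np.tanh(B - shift - nsp.y0))
        + (nsp.Av - v_star) * (1.0 + nsp.lam * np.tanh(-B + shift - nsp.y0))
    )


def _residuals(model: str):
    if model == "M2":
        return lambda u, v, nsp: (h_u(u, v, nsp), h_v_m2(v, nsp))
    if model == "M3":
        return lambda u, v, nsp: (h_u(u, v, nsp), h_v_m3(u, v, nsp))
    raise ValueError(f"unknown model {model!r}; expected 'M2' or 'M3'")


def _jacobian(u: float, v: float, nsp: NonSpatialParams, model: str,
              h: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of the reduced (u*, v*) ODE right side."""
    res = _residuals(model)
    J = np.empty((2, 2))
    for j, (du, dv) in enumerate(((h, 0.0), (0.0, h))):
        fp = res(u + du, v + dv, nsp)
        fm = res(u - du, v - dv, nsp)
        J[0, j] = (fp[0] - fm[0]) / (2 * h)
        J[1, j] = (fp[1] - fm[1]) / (2 * h)
    return J


def _classify(u: float, v: float, nsp: NonSpatialParams, model: str) -> SteadyState:
    eig = np.linalg.eigvals(_jacobian(u, v, nsp, model))
    stability = "stable" if np.all(eig.real < 0) else "unstable"
    return SteadyState(
        u_star=u, u_starstar=nsp.Au - u, v_star=v, v_starstar=nsp.Av - v,
        stability=stability, eigenvalues=(complex(eig[0]), complex(eig[1])),
        model=model,
    )


def _roots_hu_given_v(nsp: NonSpatialParams, v_star: float,
                      n_brackets: int = 400) -> list[float]:
    """All roots of h_u(·, v*) in [0, A_u] by dense bracketing + brentq."""
    if nsp.Au == 0:
        return [0.0]
    grid = np.linspace(0.0, nsp.Au, n_brackets + 1)
    vals = h_u(grid, v_star, nsp)
    roots: list[float] = []
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if fa == 0.0:
            roots.append(float(a))
        elif fa * fb < 0:
            roots.append(float(optimize.brentq(
                lambda u: float(h_u(u, v_star, nsp)), a, b, xtol=1e-14, rtol=1e-15
            )))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    return _dedup_1d(roots)


def _dedup_1d(xs: list[float], tol: float = DEDUP_TOL) -> list[float]:
    out: list[float] = []
    for x in sorted(xs):
        if not out or abs(x - out[-1]) > tol:
            out.append(x)
    return out


def find_steady_states(
    nsp: NonSpatialParams,
    model: str,
    n_seeds: int = 100,
    seeds: list[tuple[float, float]] | None = None,
) -> list[SteadyState]:
    """All homogeneous equilibria of the given model, with stability.

    M2: the leader root is the closed form; follower roots come from dense
    bracketing of h_u on [0, A_u]. M3: candidate seeds are the local minima
    of the squared residual norm on an ``n_seeds``×``n_seeds`` lattice over
    [0, A_u]×[0, A_v] (plus any caller-provided seeds), each polished by a
    Newton-type solver; non-convergent seeds are dropped, never fabricated.
    Roots are deduplicated at 1e-8 and must satisfy both residuals < 1e-10.
    """
    if model == "M2":
        v = v_star_closed_form(nsp)
        pairs = [(u, v) for u in _roots_hu_given_v(nsp, v)]
    elif model == "M3":
        pairs = _find_m3_roots(nsp, n_seeds, seeds or [])
    else:
        raise ValueError(f"unknown model {model!r}; expected 'M2' or 'M3'")

    res = _residuals(model)
    states = []
    for u, v in pairs:
        ru, rv = res(u, v, nsp)
        if abs(float(ru)) < RESIDUAL_TOL and abs(float(rv)) < RESIDUAL_TOL:
            states.append(_classify(u, v, nsp, model))
    return sorted(states, key=lambda s: (s.u_star, s.v_star))


def _find_m3_roots(nsp: NonSpatialParams, n_seeds: int,
                   extra_seeds: list[tuple[float, float]]) -> list[tuple[float, float]]:
    res = _residuals("M3")
    uu = np.linspace(0.0, nsp.Au, n_seeds)
    vv = np.linspace(0.0, nsp.Av, n_seeds)
    U, V = np.meshgrid(uu, vv, indexing="ij")
    ru, rv = res(U, V, nsp)
    norm = ru**2 + rv**2
    # local minima of the residual norm on the lattice (8-neighbourhood)
    pad = np.pad(norm, 1, constant_values=np.inf)
    is_min = np.ones_like(norm, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == dj == 0:
                continue
            nb = pad[1 + di: 1 + di + norm.shape[0], 1 + dj: 1 + dj + norm.shape[1]]
            is_min &= norm <= nb
    cand = [(float(U[i, j]), float(V[i, j])) for i, j in zip(*np.nonzero(is_min))]
    cand += list(extra_seeds)

    roots: list[tuple[float, float]] = []
    slack = 1e-6  # allow boundary roots within solver wobble
    for u0, v0 in cand:
        sol = optimize.root(
            lambda x: np.array(res(x[0], x[1], nsp), dtype=float),
            x0=[u0, v0], method="hybr", tol=1e-13,
        )
        if not sol.success:
            continue
        u, v = float(sol.x[0]), float(sol.x[1])
        if -slack <= u <= nsp.Au + slack and -slack <= v <= nsp.Av + slack:
            roots.append((min(max(u, 0.0), nsp.Au), min(max(v, 0.0), nsp.Av)))
    return _dedup_2d(roots)


def _dedup_2d(pairs: list[tuple[float, float]],
              tol: float = DEDUP_TOL) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    for u, v in sorted(pairs):
        if all(abs(u - a) > tol or abs(v - b) > tol for a, b in out):
            out.append((u, v))
    return out


@dataclass
class BifurcationBranch:
    """Equilibria along a one-parameter sweep."""

    parameter: str
    values: np.ndarray
    states: list[list[SteadyState]]  # one list per parameter value

    def counts(self) -> np.ndarray:
        """Number of equilibria at each parameter value."""
        return np.array([len(s) for s in self.states])

    def to_frame(self):
        """Tidy table: one row per (parameter value, equilibrium)."""
        import pandas as pd

        rows = []
        for val, states in zip(self.values, self.states):
            for s in states:
                rows.append({
                    self.parameter: val, "u_star": s.u_star, "v_star": s.v_star,
                    "stability": s.stability,
                    "eig1": s.eigenvalues[0], "eig2": s.eigenvalues[1],
                })
        return pd.DataFrame(rows)


SWEEPABLE = ("ql", "eta", "alpha_plus", "alpha_minus", "alpha_ratio")


def _apply_sweep(nsp: NonSpatialParams, parameter: str, value: float) -> NonSpatialParams:
    if parameter == "alpha_ratio":
        # vary alpha_plus at fixed alpha_minus so alpha_plus/alpha_minus = value
        return nsp.with_(alpha_plus=value * nsp.alpha_minus)
    if parameter not in SWEEPABLE:
        raise ValueError(f"cannot sweep {parameter!r}; choose from {SWEEPABLE}")
    return nsp.with_(**{parameter: value})


def sweep_branches(
    nsp: NonSpatialParams,
    parameter: str,
    values: np.ndarray,
    model: str,
    n_seeds: int = 60,
) -> BifurcationBranch:
    """Equilibria at every value of one swept parameter.

    Each value is solved from scratch plus seeded with the previous value's
    roots, so thin branches are not lost between sweep steps.
    """
    values = np.asarray(values, dtype=float)
    all_states: list[list[SteadyState]] = []
    prev_seeds: list[tuple[float, float]] = []
    for val in values:
        nsp_i = _apply_sweep(nsp, parameter, float(val))
        states = find_steady_states(nsp_i, model, n_seeds=n_seeds, seeds=prev_seeds)
        all_states.append(states)
        prev_seeds = [(s.u_star, s.v_star) for s in states]
    return BifurcationBranch(parameter, values, all_states)


def continue_branch(
    nsp: NonSpatialParams,
    parameter: str,
    values: np.ndarray,
    model: str,
    start: tuple[float, float] | None = None,
) -> np.ndarray:
    """Natural continuation of a single followed equilibrium along a sweep.

    At each parameter value the previous root is polished by a Newton-type
    solve; when a fold is passed the solver jumps to the nearest remaining
    branch, which is exactly the physical hysteresis behaviour. Run once
    with increasing and once with decreasing ``values`` to expose a
    hysteresis loop. Returns an array of (u*, v*) pairs, NaN where the
    solve failed.
    """
    values = np.asarray(values, dtype=float)
    res = _residuals(model)
    out = np.full((len(values), 2), np.nan)

    nsp0 = _apply_sweep(nsp, parameter, float(values[0]))
    if start is None:
        stable = [s for s in find_steady_states(nsp0, model) if s.stable]
        if not stable:
            raise RuntimeError("no stable state to start continuation from")
        current = (stable[0].u_star, stable[0].v_star)
    else:
        current = start

    for i, val in enumerate(values):
        nsp_i = _apply_sweep(nsp, parameter, float(val))
        sol = optimize.root(
            lambda x: np.array(res(x[0], x[1], nsp_i), dtype=float),
            x0=list(current), method="hybr", tol=1e-12,
        )
        uv = None
        if sol.success and np.abs(sol.fun).max() < 1e-9:
            u = min(max(float(sol.x[0]), 0.0), nsp_i.Au)
            v = min(max(float(sol.x[1]), 0.0), nsp_i.Av)
            if _classify(u, v, nsp_i, model).stable:
                uv = (u, v)
        if uv is None:
            # fold passed or polish failed: fall to the nearest remaining
            # stable equilibrium, as the dynamics would
            states = find_steady_states(nsp_i, model, seeds=[current])
            stable = [s for s in states if s.stable]
            if stable:
                uv = min(
                    ((s.u_star, s.v_star) for s in stable),
                    key=lambda p: (p[0] - current[0]) ** 2
                    + (p[1] - current[1]) ** 2,
                )
        if uv is not None:
            current = uv
            out[i] = current
    return out
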