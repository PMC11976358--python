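"""Model parameters, spatial grid, and initial conditions.

The model describes a one-dimensional swarm of "followers" (naive
individuals) and "leaders" (individuals with some knowledge of a target
direction, taken to be rightward/+). Each population is split into right-
and left-moving subpopulations that advect at fixed speed and switch
direction at density-dependent turning rates. This module holds the
parameter set, the periodic grid, and the pulse-like initial conditions
used throughout: Gaussian density bumps whose orientation split carries a
small seeded uniform perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelParams",
    "Grid",
    "InitialConditionSpec",
    "build_follower_ic",
    "build_leader_ic",
    "prescribed_leader_field",
]


@dataclass(frozen=True)
class ModelParams:
    """All rate, strength, and range parameters of the model family.

    Speeds are in space/time units, turning rates in 1/time; interaction
    strengths and conspicuousness weights are dimensionless.

    Parameters
    ----------
    gamma : follower speed γ (> 0).
    beta_plus, beta_minus : leader speeds toward/away from the target
        (≥ 0). The indifferent-leader model (M1) uses ``beta_plus`` as its
        single leader speed β. A speed bias ("Sbias") is
        ``beta_plus > beta_minus``.
    lambda1 : baseline (random) turning rate λ₁ (≥ 0).
    lambda2 : maximum directed turning rate λ₂ (≥ 0).
    y0 : shift of the turning response, chosen so the directed component
        is nearly off for a neutral signal (f(0) ≪ 1).
    qa, ql : attraction and alignment strengths (≥ 0).
    alpha : M1-only weight prioritising leader orientation in follower
        alignment (≥ 0).
    alpha_plus, alpha_minus : conspicuousness weights of (+)/(−)-moving
        leaders in alignment sums (≥ 0); ``alpha_plus > alpha_minus`` is
        the conspicuousness bias ("Cbias").
    eta : environmental orientation bias perceived by leaders ("Obias");
        positive values favour the target (+) direction.
    sa, sl : attraction/alignment half-ranges (> 0).
    ma, ml : kernel widths; default to ``sa/8`` and ``sl/8`` so that over
        98% of each kernel's mass lies on the positive half-line.
    L : domain length (> 0).
    """

    gamma: float = 0.1
    beta_plus: float = 0.1
    beta_minus: float = 0.1
    lambda1: float = 0.2
    lambda2: float = 0.9
    y0: float = 2.0
    qa: float = 0.5
    ql: float = 0.5
    alpha: float = 1.0
    alpha_plus: float = 1.0
    alpha_minus: float = 1.0
    eta: float = 0.0
    sa: float = 1.0
    sl: float = 0.5
    ma: float | None = None
    ml: float | None = None
    L: float = 40.0

    def __post_init__(self) -> None:
        if self.ma is None:
            object.__setattr__(self, "ma", self.sa / 8.0)
        if self.ml is None:
            object.__setattr__(self, "ml", self.sl / 8.0)
        strictly_positive = {
            "gamma": self.gamma, "y0": self.y0, "sa": self.sa,
            "sl": self.sl, "ma": self.ma, "ml": self.ml, "L": self.L,
        }
        for name, value in strictly_positive.items():
            if not value > 0:
                raise ValueError(f"parameter {name!r} must be > 0, got {value}")
        nonnegative = {
            "beta_plus": self.beta_plus, "beta_minus": self.beta_minus,
            "lambda1": self.lambda1, "lambda2": self.lambda2,
            "qa": self.qa, "ql": self.ql, "alpha": self.alpha,
            "alpha_plus": self.alpha_plus, "alpha_minus": self.alpha_minus,
        }
        for name, value in nonnegative.items():
            if not value >= 0:
                raise ValueError(f"parameter {name!r} must be >= 0, got {value}")

    @property
    def beta(self) -> float:
        """Single leader speed of the indifferent-leader model (M1)."""
        return self.beta_plus

    def with_(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        # ma/ml rederive from the new ranges unless explicitly pinned
        if ("sa" in changes and "ma" not in changes):
            changes["ma"] = None
        if ("sl" in changes and "ml" not in changes):
            changes["ml"] = None
        return replace(self, **changes)


@dataclass(frozen=True)
class Grid:
    """Uniform periodic grid of cell centers on [0, L)."""

    n_cells: int
    L: float
    dx: float = field(init=False)
    cell_centers: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_cells < 8:
            raise ValueError(f"n_cells must be >= 8, got {self.n_cells}")
        if not self.L > 0:
            raise ValueError(f"L must be > 0, got {self.L}")
        object.__setattr__(self, "dx", self.L / self.n_cells)
        centers = (np.arange(self.n_cells) + 0.5) * self.dx
        centers.flags.writeable = False
        object.__setattr__(self, "cell_centers", centers)

    def wrap(self, displacement: np.ndarray | float) -> np.ndarray | float:
        """Map a displacement to the minimal image in [-L/2, L/2)."""
        return (np.asarray(displacement) + 0.5 * self.L) % self.L - 0.5 * self.L


@dataclass(frozen=True)
class InitialConditionSpec:
    """Gaussian-pulse initial condition with a seeded orientation split.

    The total density is ``M * exp(-0.5 (x - x0)^2)``; the right/left split
    at each cell is ``(1 ± r(x))/2`` with ``r`` iid uniform on
    ``[-amplitude, +amplitude]``.
    """

    M: float
    x0: float
    amplitude: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.M >= 0:
            raise ValueError(f"peak density M must be >= 0, got {self.M}")
        if not 0 <= self.amplitude < 1:
            raise ValueError(
                "perturbation amplitude must lie in [0, 1) to keep densities "
                f"non-negative, got {self.amplitude}"
            )


def _gaussian_pulse(M: float, x0: float, grid: Grid) -> np.ndarray:
    # minimal-image displacement so the pulse wraps cleanly on the circle
    d = grid.wrap(grid.cell_centers - x0)
    return M * np.exp(-0.5 * d**2)


def build_follower_ic(
    spec: InitialConditionSpec, grid: Grid
) -> tuple[np.ndarray, np.ndarray]:
    """Build the (u⁺, u⁻) follower initial condition.

    Returns the right- and left-moving follower densities; their sum is the
    unperturbed Gaussian pulse regardless of the seed, so total mass does
    not depend on the perturbation draw.
    """
    total = _gaussian_pulse(spec.M, spec.x0, grid)
    rng = np.random.default_rng(spec.seed)
    r = rng.uniform(-spec.amplitude, spec.amplitude, size=grid.n_cells)
    u_plus = total * (1.0 + r) / 2.0
    u_minus = total * (1.0 - r) / 2.0
    return u_plus, u_minus


def build_leader_ic(
    spec: InitialConditionSpec, grid: Grid
) -> tuple[np.ndarray, np.ndarray]:
    """Build the (v⁺, v⁻) leader initial condition (M2/M3 runs).

    Identical construction to the follower pulse; use a distinct seed so
    the two populations' perturbations are independent.
    """
    return build_follower_ic(spec, grid)


def prescribed_leader_field(
    t: float, params: ModelParams, spec: InitialConditionSpec, grid: Grid
) -> tuple[np.ndarray, np.ndarray, float]:
    """Evaluate the prescribed (non-reactive) M1 leader density at time t.

    The leader group is a rigid Gaussian pulse translating rightward at
    constant speed β, wrapped onto the periodic domain. Returns
    ``(v_plus, v_minus, center_unwrapped)`` where the unwrapped center
    ``x0 + β t`` tracks the total distance covered by the leaders.
    """
    center = spec.x0 + params.beta * t
    v_plus = _gaussian_pulse(spec.M, center % grid.L, grid)
    v_minus = np.zeros(grid.n_cells)
    return v_plus, v_minus, center
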