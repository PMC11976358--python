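"""Swarm diagnostics: cohesion, speed, detachment, and regime labels.

Success of a guidance strategy is judged by whether the follower group
moves toward the target while staying compact. The diagnostics here are
computed on the periodic domain in an unwrapped frame centered on the
group's circular center of mass: inter-decile extension d = x₈₀ − x₂₀, the
cohesion index d₀/d_end (≈1 means coherence maintained, ≪1 dispersion),
the mean speed of the follower mass median, and the detachment time at
which follower-leader overlap first drops below 5% of its initial value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import Grid
from .simulate import PopulationState, SimulationResult

__all__ = [
    "SwarmMetrics",
    "RegimeThresholds",
    "circular_center",
    "follower_deciles",
    "mass_quantile",
    "extension_trajectory",
    "median_trajectory",
    "cohesion_index",
    "mean_speed",
    "detachment_time",
    "classify_regime",
    "compute_metrics",
]


@dataclass(frozen=True)
class RegimeThresholds:
    """Thresholds of the regime decision tree (labels come from the model's
    phenomenology; the numeric cutoffs are package conventions and are all
    adjustable here)."""

    stationary_speed_frac: float = 0.1   # |speed| < frac·γ counts as at rest
    dispersion_cohesion: float = 0.25    # d0/d_end below this is dispersion
    success_cohesion: float = 0.75       # compactness required for "success"
    pulsation_rel_amplitude: float = 0.2
    pulsation_min_extrema: int = 3
    collected_excursion: float = 2.0     # d(t) max > this × d0, then …
    collected_return: float = 1.3        # … back below this × d0


@dataclass
class SwarmMetrics:
    """All diagnostics of one run, plus the regime label."""

    x20: float
    x80: float
    d0: float
    d_end: float
    cohesion_index: float
    mean_speed: float
    detachment_time: float | None
    covered_fraction: float
    regime: str

    @property
    def success(self) -> bool:
        """Target-directed and compact (thresholds per RegimeThresholds)."""
        return self.mean_speed > 0 and self.cohesion_index >= 0.75


def circular_center(density: np.ndarray, grid: Grid) -> float:
    """Mass center of a density on the circle, in [0, L)."""
    total = density.sum()
    if total <= 0:
        raise ValueError("zero total mass")
    theta = 2.0 * np.pi * grid.cell_centers / grid.L
    angle = np.arctan2((density * np.sin(theta)).sum(), (density * np.cos(theta)).sum())
    return float((angle * grid.L / (2.0 * np.pi)) % grid.L)


def mass_quantile(density: np.ndarray, grid: Grid, q) -> np.ndarray:
    """Positions where the cumulative mass crosses fraction(s) ``q``.

    The cumulative distribution is built in an unwrapped frame centered on
    the circular center of mass and linearly interpolated within cells;
    returned positions live in that frame (they may fall slightly outside
    [0, L) near the seam).
    """
    total = density.sum()
    if total <= 0:
        raise ValueError("zero total mass")
    c = circular_center(density, grid)
    rel = grid.wrap(grid.cell_centers - c)
    order = np.argsort(rel)
    rel_sorted = rel[order]
    w = density[order] / total
    cdf_mid = np.cumsum(w) - 0.5 * w  # CDF evaluated at cell centers
    pos = np.interp(np.asarray(q, dtype=float), cdf_mid, rel_sorted)
    return c + pos


def follower_deciles(state: PopulationState, grid: Grid,
                     species: str = "u") -> tuple[float, float]:
    """Second and eighth deciles (x₂₀, x₈₀) of a population's distribution."""
    density = getattr(state, species)
    x20, x80 = mass_quantile(density, grid, [0.2, 0.8])
    return float(x20), float(x80)


def extension_trajectory(result: SimulationResult, species: str = "u") -> np.ndarray:
    """Inter-decile extension d(t) = x₈₀ − x₂₀ at every snapshot."""
    out = np.empty(len(result.snapshots))
    for i, s in enumerate(result.snapshots):
        x20, x80 = follower_deciles(s, result.grid, species)
        out[i] = x80 - x20
    return out


def median_trajectory(result: SimulationResult, species: str = "u") -> np.ndarray:
    """Mass-median position per snapshot, unwrapped across the seam.

    Each snapshot's median is taken relative to the previous one by the
    minimal image, so a group that circles the periodic domain accumulates
    displacement instead of jumping back.
    """
    meds = np.empty(len(result.snapshots))
    for i, s in enumerate(result.snapshots):
        meds[i] = mass_quantile(getattr(s, species), result.grid, 0.5)
    L = result.grid.L
    out = np.empty_like(meds)
    out[0] = meds[0]
    for i in range(1, len(meds)):
        delta = (meds[i] - meds[i - 1] + 0.5 * L) % L - 0.5 * L
        out[i] = out[i - 1] + delta
    return out


def cohesion_index(result: SimulationResult, species: str = "u") -> float:
    """d₀/d_end between the first and last recorded snapshots."""
    if len(result.snapshots) < 2:
        raise ValueError("need at least two snapshots")
    d = extension_trajectory(result, species)
    if d[-1] <= 0:
        raise ValueError("final extension is zero")
    return float(d[0] / d[-1])


def mean_speed(result: SimulationResult, species: str = "u") -> float:
    """Net displacement rate of the mass median over the observation time."""
    if len(result.snapshots) < 2:
        raise ValueError("need at least two snapshots")
    med = median_trajectory(result, species)
    return float((med[-1] - med[0]) / (result.times[-1] - result.times[0]))


def detachment_time(result: SimulationResult) -> float | None:
    """First recorded time with follower-leader overlap below 5% of initial.

    Overlap is the cell-sum quadrature ∫ u·v dx. ``None`` if the overlap
    never drops below threshold within the run.
    """
    dx = result.grid.dx
    overlaps = np.array([(s.u * s.v).sum() * dx for s in result.snapshots])
    if overlaps[0] <= 0:
        raise ValueError("initial follower-leader overlap is zero")
    below = np.nonzero(overlaps < 0.05 * overlaps[0])[0]
    if len(below) == 0:
        return None
    return float(result.times[below[0]])


def _leader_displacement(result: SimulationResult) -> float:
    if result.leader_center_unwrapped is not None:
        c = result.leader_center_unwrapped
        return float(c[-1] - c[0])
    med = median_trajectory(result, "v")
    return float(med[-1] - med[0])


def _count_pulsations(d: np.ndarray, rel_amplitude: float) -> int:
    """Alternating extrema of d(t) whose swing exceeds the given fraction
    of the mean extension.

    Returns 0 unless the oscillation persists, i.e. the last qualifying
    extremum falls in the final quarter of the record — a settling
    transient (one overshoot then a plateau) is not a pulsating pattern.
    """
    scale = d.mean()
    if scale <= 0:
        return 0
    interior = np.arange(1, len(d) - 1)
    is_max = (d[interior] >= d[interior - 1]) & (d[interior] > d[interior + 1])
    is_min = (d[interior] <= d[interior - 1]) & (d[interior] < d[interior + 1])
    ext_idx = interior[is_max | is_min]
    if len(ext_idx) == 0:
        return 0
    count = 0
    prev = d[0]
    last_hit = 0
    for i in ext_idx:
        if abs(d[i] - prev) > rel_amplitude * scale:
            count += 1
            prev = d[i]
            last_hit = i
    if last_hit < 0.75 * (len(d) - 1):
        return 0
    return count


def classify_regime(
    result: SimulationResult,
    metrics: SwarmMetrics | None = None,
    thresholds: RegimeThresholds = RegimeThresholds(),
) -> str:
    """Assign one of the qualitative swarm-outcome labels.

    Labels: ``stationary-aggregate``, ``coherent-target-directed``,
    ``counter-directed``, ``dispersion``, ``splitting-I`` (followers pull
    ahead of the leaders), ``splitting-II`` (leaders leave followers
    behind), ``pulsating``, ``dispersed-then-collected``, or
    ``unclassified``. Deterministic given the run and thresholds.
    """
    if metrics is None:
        metrics = compute_metrics(result, classify=False)
    th = thresholds
    gamma = result.params.gamma
    d_traj = extension_trajectory(result)
    med = median_trajectory(result)

    if _count_pulsations(d_traj, th.pulsation_rel_amplitude) >= th.pulsation_min_extrema:
        return "pulsating"
    if d_traj.max() > th.collected_excursion * d_traj[0] and \
            d_traj[-1] < th.collected_return * d_traj[0]:
        return "dispersed-then-collected"

    if metrics.detachment_time is not None:
        # post-split fate: reversal, or which population ends up ahead
        tail = max(2, len(med) // 4)
        tspan = result.times[-1] - result.times[-tail]
        late_speed = (med[-1] - med[-tail]) / tspan if tspan > 0 else 0.0
        if late_speed < -th.stationary_speed_frac * gamma:
            return "counter-directed"
        follower_disp = med[-1] - med[0]
        if _leader_displacement(result) > follower_disp:
            return "splitting-II"
        return "splitting-I"

    if metrics.cohesion_index < th.dispersion_cohesion:
        return "dispersion"
    if abs(metrics.mean_speed) < th.stationary_speed_frac * gamma:
        return "stationary-aggregate"
    if metrics.mean_speed > 0:
        return "coherent-target-directed"
    if metrics.mean_speed < 0:
        return "counter-directed"
    return "unclassified"


def compute_metrics(
    result: SimulationResult,
    thresholds: RegimeThresholds = RegimeThresholds(),
    classify: bool = True,
) -> SwarmMetrics:
    """All diagnostics of one run (deciles, cohesion, speed, detachment,
    covered distance relative to leaders, regime label)."""
    d = extension_trajectory(result)
    x20, x80 = follower_deciles(result.snapshots[-1], result.grid)
    med = median_trajectory(result)
    speed = float((med[-1] - med[0]) / (result.times[-1] - result.times[0]))
    try:
        t_detach = detachment_time(result)
    except ValueError:
        t_detach = None
    leader_disp = _leader_displacement(result)
    covered = float((med[-1] - med[0]) / leader_disp) if leader_disp != 0 else np.nan

    metrics = SwarmMetrics(
        x20=x20, x80=x80, d0=float(d[0]), d_end=float(d[-1]),
        cohesion_index=float(d[0] / d[-1]), mean_speed=speed,
        detachment_time=t_detach, covered_fraction=covered,
        regime="unclassified",
    )
    if classify:
        metrics.regime = classify_regime(result, metrics, thresholds)
    return metrics
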