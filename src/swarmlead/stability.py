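"""Numerical growth-rate probe of the spatially uniform state.

Whether a homogeneous steady state breaks up into spatial groups is
decided by the growth or decay of small periodic perturbations. Instead of
an analytic dispersion relation, this module measures growth rates
directly: it seeds low Fourier modes of the uniform state with tiny
random-phase cosines, advances the full nonlinear model over a short
horizon, and fits an exponential to each mode's amplitude. A positive
dominant growth rate signals pattern formation (aggregation); in the
models here that requires sufficiently strong attraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .params import Grid, ModelParams
from .simulate import PopulationState, RunSpec, SimulationResult, run_m2m3
from .steady import SteadyState

__all__ = ["GrowthSpectrum", "probe_growth"]

SATURATION_FACTOR = 100.0  # amplitudes beyond this × ε are nonlinear


@dataclass(frozen=True)
class GrowthSpectrum:
    """Per-mode growth rates fitted from a perturbation run."""

    wavenumbers: np.ndarray      # k_j = 2πj/L, j = 1..J
    growth_rates: np.ndarray     # 1/time; positive = growing
    fit_residuals: np.ndarray    # RMS residual of each log-amplitude fit
    dominant_mode: int           # j of the fastest-growing mode (1-based)

    @property
    def dominant_rate(self) -> float:
        return float(self.growth_rates[self.dominant_mode - 1])

    @property
    def pattern_forming(self) -> bool:
        """True if some probed mode grows."""
        return self.dominant_rate > 0


def _mode_amplitudes(field: np.ndarray, n_modes: int) -> np.ndarray:
    spec = np.fft.rfft(field)
    return 2.0 * np.abs(spec[1: n_modes + 1]) / len(field)


def probe_growth(
    params: ModelParams,
    steady: SteadyState | tuple[float, float, float, float],
    grid: Grid,
    model: str = "M3",
    epsilon: float = 1e-5,
    t_probe: float = 30.0,
    n_modes: int = 8,
    seed: int = 0,
    snapshot_every: int = 2,
) -> GrowthSpectrum:
    """Estimate perturbation growth rates about a uniform steady state.

    The four fields are set to the homogeneous equilibrium densities (per
    unit length) and each receives an independent random-phase cosine
    perturbation of amplitude ``epsilon`` in every probed mode. Mode
    amplitudes of the total density are then tracked through a short
    simulation and fitted by log-linear regression; if a mode saturates
    (amplitude beyond 100ε) its fit window is shortened to the linear
    stretch.

    ``steady`` may be a :class:`~swarmlead.steady.SteadyState` (whose
    densities are interpreted as spatial mean densities) or a raw
    ``(u⁺, u⁻, v⁺, v⁻)`` tuple of uniform levels.
    """
    if isinstance(steady, SteadyState):
        levels = (steady.u_star, steady.u_starstar,
                  steady.v_star, steady.v_starstar)
    else:
        levels = tuple(steady)
    min_level = min(lv for lv in levels if lv > 0)
    if epsilon > 1e-4 * min_level:
        raise ValueError(
            f"epsilon {epsilon:g} too large for linear probing; need "
            f"<= {1e-4 * min_level:g} (1e-4 × smallest nonzero density)"
        )

    rng = np.random.default_rng(seed)
    x = grid.cell_centers
    k = 2.0 * np.pi * np.arange(1, n_modes + 1) / grid.L
    fields = []
    for level in levels:
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_modes)
        delta = (epsilon * np.cos(np.outer(k, x) + phases[:, None])).sum(axis=0)
        fields.append(np.maximum(level + delta, 0.0))
    state = PopulationState(*fields, time=0.0)

    run_spec = RunSpec(t_end=t_probe, model=model, snapshot_every=snapshot_every)
    result = run_m2m3(params, None, None, run_spec, grid, initial_state=state)

    amps = np.array([
        _mode_amplitudes(s.p, n_modes) for s in result.snapshots
    ])  # shape (n_times, n_modes)
    times = result.times

    rates = np.empty(n_modes)
    residuals = np.empty(n_modes)
    for j in range(n_modes):
        a = amps[:, j]
        # restrict to the linear window before saturation
        sat = np.nonzero(a > SATURATION_FACTOR * epsilon)[0]
        stop = sat[0] if len(sat) else len(a)
        stop = max(stop, 3)
        valid = a[:stop] > 0
        t_fit, y_fit = times[:stop][valid], np.log(a[:stop][valid])
        if len(t_fit) < 3:
            rates[j], residuals[j] = np.nan, np.nan
            continue
        fit = stats.linregress(t_fit, y_fit)
        rates[j] = fit.slope
        residuals[j] = float(np.sqrt(np.mean(
            (y_fit - (fit.intercept + fit.slope * t_fit)) ** 2
        )))

    dominant = int(np.nanargmax(rates)) + 1
    return GrowthSpectrum(k, rates, residuals, dominant)


def spectrum_result(result: SimulationResult, n_modes: int) -> np.ndarray:
    """Mode-amplitude history of the total density for an existing run."""
    return np.array([_mode_amplitudes(s.p, n_modes) for s in result.snapshots])
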