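"""Discretized nonlocal interaction kernels and social-signal operators.

Individuals sense neighbours through translated-Gaussian kernels supported
on the positive half-line: attraction acts on the total density (turning
is less likely toward higher densities), alignment on the orientation
split of neighbours. This module discretizes the kernels on the periodic
grid and evaluates the attraction and alignment sums for every model
variant (M1 indifferent, M2 observant, M3 persuadable leaders).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .params import Grid, ModelParams

__all__ = [
    "KernelSet",
    "analytic_halfline_mass",
    "discretize_kernel",
    "build_kernels",
    "attraction_term",
    "alignment_follower_M1",
    "alignment_follower_M23",
    "alignment_leader_M2",
    "alignment_leader_M3",
]

# kernels are truncated at s_i + TRUNC_SIGMAS * m_i; beyond this the
# Gaussian weight is negligible (8 sigma from the mean)
TRUNC_SIGMAS = 8.0


def analytic_halfline_mass(s_i: float, m_i: float) -> float:
    """Exact mass of the translated Gaussian kernel on [0, ∞).

    ∫₀^∞ N(s; s_i, m_i²) ds = Φ(s_i/m_i) = ½(1 + erf(s_i/(√2 m_i))).
    For the standard width choice m_i = s_i/8 this exceeds 0.98 by design.
    """
    return 0.5 * (1.0 + erf(s_i / (np.sqrt(2.0) * m_i)))


def discretize_kernel(
    s_i: float, m_i: float, grid: Grid
) -> tuple[np.ndarray, np.ndarray, float]:
    """Midpoint-rule discretization of a translated-Gaussian kernel.

    Offsets are the positive cell separations ``s_j = j·dx`` for
    ``j = 1..J`` with the truncation ``J·dx ≥ s_i + 8 m_i``; weights are
    ``K(s_j)·dx``. The kernel is *not* renormalized after truncation; the
    returned discrete mass is used wherever the half-line integral of the
    kernel appears, keeping discrete identities exact.

    Returns ``(offsets, weights, mass)``.
    """
    if not (s_i > 0 and m_i > 0):
        raise ValueError("kernel range and width must be positive")
    reach = s_i + TRUNC_SIGMAS * m_i
    if reach >= grid.L / 2:
        raise ValueError(
            f"kernel reach {reach:g} exceeds half the domain ({grid.L / 2:g}); "
            "enlarge the domain or shorten the interaction range"
        )
    J = int(np.ceil(reach / grid.dx))
    offsets = np.arange(1, J + 1) * grid.dx
    weights = (
        np.exp(-((offsets - s_i) ** 2) / (2.0 * m_i**2))
        / np.sqrt(2.0 * np.pi * m_i**2)
        * grid.dx
    )
    return offsets, weights, float(weights.sum())


@dataclass(frozen=True)
class KernelSet:
    """Discretized attraction/alignment kernels bound to a grid.

    Holds the quadrature weights and the periodic gather indices used to
    evaluate one-sided neighbourhood sums, plus the discrete half-line
    masses ``kappa_a`` and ``kappa_l``.
    """

    offsets_a: np.ndarray
    weights_a: np.ndarray
    kappa_a: float
    offsets_l: np.ndarray
    weights_l: np.ndarray
    kappa_l: float
    # index matrices: idx_*_p[j, i] = i + (j+1) mod n; idx_*_m wraps i - (j+1)
    idx_a_p: np.ndarray
    idx_a_m: np.ndarray
    idx_l_p: np.ndarray
    idx_l_m: np.ndarray

    def to_table(self) -> "np.ndarray":
        """Offsets and weights as a plain array for text export."""
        n = max(len(self.offsets_a), len(self.offsets_l))
        out = np.full((n, 4), np.nan)
        out[: len(self.offsets_a), 0] = self.offsets_a
        out[: len(self.weights_a), 1] = self.weights_a
        out[: len(self.offsets_l), 2] = self.offsets_l
        out[: len(self.weights_l), 3] = self.weights_l
        return out


def _gather_indices(J: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    i = np.arange(n)[None, :]
    j = np.arange(1, J + 1)[:, None]
    return (i + j) % n, (i - j) % n


def build_kernels(params: ModelParams, grid: Grid) -> KernelSet:
    """Discretize both interaction kernels for the given grid."""
    off_a, w_a, kap_a = discretize_kernel(params.sa, params.ma, grid)
    off_l, w_l, kap_l = discretize_kernel(params.sl, params.ml, grid)
    ia_p, ia_m = _gather_indices(len(off_a), grid.n_cells)
    il_p, il_m = _gather_indices(len(off_l), grid.n_cells)
    return KernelSet(off_a, w_a, kap_a, off_l, w_l, kap_l, ia_p, ia_m, il_p, il_m)


def _onesided(field: np.ndarray, weights: np.ndarray,
              idx_p: np.ndarray, idx_m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted one-sided neighbourhood sums Σⱼ wⱼ f(x ± sⱼ)."""
    right = weights @ field[idx_p]
    left = weights @ field[idx_m]
    return right, left


def _both(field: np.ndarray, kernels: KernelSet) -> np.ndarray:
    """Two-sided alignment sum Σⱼ wⱼ (f(x+sⱼ) + f(x−sⱼ))."""
    r, l = _onesided(field, kernels.weights_l, kernels.idx_l_p, kernels.idx_l_m)
    return r + l


def attraction_term(
    p_total: np.ndarray, params: ModelParams, kernels: KernelSet, grid: Grid
) -> tuple[np.ndarray, np.ndarray]:
    """Attraction signal for right- and left-movers from the total density.

    ``Qa±(x) = −q_a Σⱼ w_a,ⱼ (p(x±sⱼ) − p(x∓sⱼ))``; antisymmetric by
    construction (``Qa⁺ = −Qa⁻`` pointwise). A denser region ahead of a
    right-mover makes its signal negative, lowering its turning rate.
    """
    right, left = _onesided(p_total, kernels.weights_a, kernels.idx_a_p, kernels.idx_a_m)
    qa_plus = -params.qa * (right - left)
    return qa_plus, -qa_plus


def alignment_follower_M1(
    u_plus: np.ndarray,
    u_minus: np.ndarray,
    v_plus: np.ndarray,
    params: ModelParams,
    kernels: KernelSet,
    grid: Grid,
) -> tuple[np.ndarray, np.ndarray]:
    """Follower alignment with indifferent leaders (M1).

    Followers compare left- against right-moving neighbours; the prescribed
    rightward leader field enters with prioritisation weight α. Only v⁺
    appears because indifferent leaders never move leftward.
    """
    s = _both(u_minus, kernels) - _both(u_plus, kernels) - params.alpha * _both(v_plus, kernels)
    ql_plus = params.ql * s
    return ql_plus, -ql_plus


def alignment_follower_M23(
    u_plus: np.ndarray,
    u_minus: np.ndarray,
    v_plus: np.ndarray,
    v_minus: np.ndarray,
    params: ModelParams,
    kernels: KernelSet,
    grid: Grid,
) -> tuple[np.ndarray, np.ndarray]:
    """Follower alignment for the reactive-leader models (M2/M3).

    Leaders are weighted by conspicuousness: α⁺ for target-directed (+)
    leaders, α⁻ for (−) leaders, so α⁺ > α⁻ biases followers rightward
    even without any environmental cue.
    """
    s = (
        _both(u_minus, kernels)
        + params.alpha_minus * _both(v_minus, kernels)
        - _both(u_plus, kernels)
        - params.alpha_plus * _both(v_plus, kernels)
    )
    ql_plus = params.ql * s
    return ql_plus, -ql_plus


def alignment_leader_M2(
    params: ModelParams, kernels: KernelSet
) -> tuple[float, float]:
    """Observant-leader alignment: a constant environmental bias only.

    ``Ql^{v±} = ∓ q_l η κ_l`` with κ_l the discrete kernel mass; η > 0
    keeps right-movers on course and turns left-movers around.
    """
    bias = params.ql * params.eta * kernels.kappa_l
    return -bias, bias


def alignment_leader_M3(
    u_plus: np.ndarray,
    u_minus: np.ndarray,
    v_plus: np.ndarray,
    v_minus: np.ndarray,
    params: ModelParams,
    kernels: KernelSet,
    grid: Grid,
) -> tuple[np.ndarray, np.ndarray]:
    """Persuadable-leader alignment: social pooling plus environmental bias.

    Equals the follower alignment of M2/M3 shifted by the constant Obias
    term ``∓ q_l η κ_l``.
    """
    ql_plus, ql_minus = alignment_follower_M23(
        u_plus, u_minus, v_plus, v_minus, params, kernels, grid
    )
    bias = params.ql * params.eta * kernels.kappa_l
    return ql_plus - bias, ql_minus + bias
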