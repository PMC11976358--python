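"""Turning-rate fields: compose nonlocal signals into switching rates.

Each subpopulation switches direction at rate λ = λ₁ + λ₂ f(y), where the
control variable y sums the attraction and alignment signals perceived by
that subpopulation and f is a smooth sigmoidal response. The shift y₀ is
chosen so a neutral signal (y = 0) leaves the directed component nearly
off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import (
    KernelSet,
    alignment_follower_M1,
    alignment_follower_M23,
    alignment_leader_M2,
    alignment_leader_M3,
    attraction_term,
)
from .params import Grid, ModelParams

__all__ = ["TurningField", "turning_response", "turning_rate", "assemble_turning"]

MODELS = ("M1", "M2", "M3")


@dataclass(frozen=True)
class TurningField:
    """Control variables and turning rates for all subpopulations.

    Leader entries are ``None`` under M1, where the leader field is
    prescribed rather than evolved.
    """

    y_u_plus: np.ndarray
    y_u_minus: np.ndarray
    lam_u_plus: np.ndarray
    lam_u_minus: np.ndarray
    y_v_plus: np.ndarray | None = None
    y_v_minus: np.ndarray | None = None
    lam_v_plus: np.ndarray | None = None
    lam_v_minus: np.ndarray | None = None


def turning_response(y):
    """Sigmoidal directed-turning modulation f(y) = ½ + ½ tanh(y − y₀)...

    without the shift: this is the raw ``0.5 + 0.5·tanh`` response; the
    shift is applied by the caller so f can be probed directly.
    """
    return 0.5 + 0.5 * np.tanh(y)


def turning_rate(y, lambda1: float, lambda2: float, y0: float):
    """Turning rate λ(y) = λ₁ + λ₂·(½ + ½ tanh(y − y₀)).

    Smooth and strictly increasing in the control variable y; bounded in
    (λ₁, λ₁ + λ₂).
    """
    return lambda1 + lambda2 * turning_response(np.asarray(y, dtype=float) - y0)


def assemble_turning(
    state,
    params: ModelParams,
    kernels: KernelSet,
    grid: Grid,
    model: str,
) -> TurningField:
    """Build control variables and turning rates for one model variant.

    ``state`` is a :class:`~swarmlead.simulate.PopulationState`. Attraction
    always acts on the total density p = u + v; the alignment operator is
    selected per variant. Speed bias never enters here: it acts only in
    transport.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")

    u_p, u_m, v_p, v_m = state.u_plus, state.u_minus, state.v_plus, state.v_minus
    p = u_p + u_m + v_p + v_m
    qa_p, qa_m = attraction_term(p, params, kernels, grid)

    if model == "M1":
        ql_p, ql_m = alignment_follower_M1(u_p, u_m, v_p, params, kernels, grid)
        y_up, y_um = qa_p + ql_p, qa_m + ql_m
        lam = lambda y: turning_rate(y, params.lambda1, params.lambda2, params.y0)
        return TurningField(y_up, y_um, lam(y_up), lam(y_um))

    ql_p, ql_m = alignment_follower_M23(u_p, u_m, v_p, v_m, params, kernels, grid)
    y_up, y_um = qa_p + ql_p, qa_m + ql_m
    if model == "M2":
        b_p, b_m = alignment_leader_M2(params, kernels)
        y_vp, y_vm = qa_p + b_p, qa_m + b_m
    else:  # M3
        lv_p, lv_m = alignment_leader_M3(u_p, u_m, v_p, v_m, params, kernels, grid)
        y_vp, y_vm = qa_p + lv_p, qa_m + lv_m

    lam = lambda y: turning_rate(y, params.lambda1, params.lambda2, params.y0)
    return TurningField(
        y_up, y_um, lam(y_up), lam(y_um),
        y_vp, y_vm, lam(y_vp), lam(y_vm),
    )
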