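import numpy as np
import pytest

import swarmlead as sl


@pytest.fixture
def small_grid() -> sl.Grid:
    """64-cell periodic grid, large enough for the default sensing ranges."""
    return sl.Grid(64, 40.0)


@pytest.fixture
def default_params() -> sl.ModelParams:
    return sl.ModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def random_state(small_grid, rng) -> sl.PopulationState:
    """Strictly positive random density fields on the small grid."""
    f = [rng.uniform(0.2, 2.0, small_grid.n_cells) for _ in range(4)]
    return sl.PopulationState(*f)


def brute_force_attraction(p_total, params, kernels, n):
    """Direct double-loop quadrature of the attraction signal (oracle)."""
    qa_plus = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j, w in enumerate(kernels.weights_a, start=1):
            acc += w * (p_total[(i + j) % n] - p_total[(i - j) % n])
        qa_plus[i] = -params.qa * acc
    return qa_plus, -qa_plus


def brute_force_both(field, kernels, n, i):
    return sum(
        w * (field[(i + j) % n] + field[(i - j) % n])
        for j, w in enumerate(kernels.weights_l, start=1)
    )


def brute_force_alignment_m1(u_p, u_m, v_p, params, kernels, n):
    out = np.zeros(n)
    for i in range(n):
        out[i] = params.ql * (
            brute_force_both(u_m, kernels, n, i)
            - brute_force_both(u_p, kernels, n, i)
            - params.alpha * brute_force_both(v_p, kernels, n, i)
        )
    return out, -out


def brute_force_alignment_m23(u_p, u_m, v_p, v_m, params, kernels, n):
    out = np.zeros(n)
    for i in range(n):
        out[i] = params.ql * (
            brute_force_both(u_m, kernels, n, i)
            + params.alpha_minus * brute_force_both(v_m, kernels, n, i)
            - brute_force_both(u_p, kernels, n, i)
            - params.alpha_plus * brute_force_both(v_p, kernels, n, i)
        )
    return out, -out
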