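"""Component right-hand-side functions: closed-form values and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somnet import (
    ModelParameters,
    NetworkState,
    PathwayWeights,
    heaviside,
    homeostatic_rhs,
    network_rhs,
    steady_state_rate,
    synaptic_input,
    transmitter_steady_state,
)

SETTINGS = dict(deadline=None, derandomize=True, max_examples=100)


# -- heaviside ---------------------------------------------------------------

@pytest.mark.parametrize("z,expected", [(-1.0, 0.0), (0.0, 1.0), (2.5, 1.0), (-1e-12, 0.0)])
def test_heaviside_step_convention(z, expected):
    assert heaviside(z) == expected


@pytest.mark.parametrize("bad", [math.nan, math.inf, -math.inf])
def test_heaviside_rejects_non_finite(bad):
    with pytest.raises(ValueError):
        heaviside(bad)


# -- steady-state firing rate ------------------------------------------------

def test_rate_half_maximum_at_threshold(params):
    assert steady_state_rate("W", params.beta_W, 0.0, params) == pytest.approx(
        params.W_max / 2, rel=1e-12
    )
    # NREM threshold is k_N * H: argument zero at I = k_N * H
    H = 0.4
    assert steady_state_rate("N", params.k_N * H, H, params) == pytest.approx(
        params.N_max / 2, rel=1e-12
    )


def test_rate_closed_form_value():
    p = ModelParameters(W_max=4.0, alpha_W=1.0, beta_W=0.0)
    expected = 4.0 * 0.5 * (1.0 + math.tanh(1.0))  # = 3.5231883...
    assert steady_state_rate("W", 1.0, 0.0, p) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(3.5231883119115297, rel=1e-12)


def test_rate_saturates_at_maximum(params):
    assert steady_state_rate("R", 1e6, 0.0, params) == pytest.approx(params.R_max)
    assert steady_state_rate("R", -1e6, 0.0, params) == pytest.approx(0.0, abs=1e-12)


def test_rate_unknown_population_rejected(params):
    with pytest.raises(KeyError):
        steady_state_rate("Q", 0.0, 0.0, params)


@settings(**SETTINGS)
@given(
    population=st.sampled_from(["W", "N", "R"]),
    I=st.floats(-50, 50),
    I2=st.floats(-50, 50),
    H=st.floats(0, 1),
)
def test_rate_bounded_and_monotone(population, I, I2, H):
    p = ModelParameters()
    lo, hi = sorted([I, I2])
    r_lo = steady_state_rate(population, lo, H, p)
    r_hi = steady_state_rate(population, hi, H, p)
    assert 0.0 <= r_lo <= p.max_rate(population)
    assert 0.0 <= r_hi <= p.max_rate(population)
    assert r_lo <= r_hi + 1e-12


# -- synaptic input ----------------------------------------------------------

def test_input_empty_drive_is_zero(params):
    assert synaptic_input("W", 0.0, 0.0, 0.0, params.weights, 0.0) == 0.0


def test_input_hand_arithmetic_wake():
    w = PathwayWeights(g_NWi=-2.0, g_RWe=1.0)
    I = synaptic_input("W", 0.0, 0.5, 0.25, w, noise_draw=0.01)
    assert I == pytest.approx(-0.74, rel=1e-12)


def test_input_hand_arithmetic_rem():
    w = PathwayWeights(g_WRi=-4.0, g_NRi=-1.3, g_RRe=1.6)
    I = synaptic_input("R", 1.0, 1.0, 0.0, w, noise_draw=0.0)
    assert I == pytest.approx(-5.3, rel=1e-12)


def test_input_uses_only_afferent_pathways(params):
    # NREM receives only the Wake projection
    w = params.weights
    assert synaptic_input("N", 0.7, 0.9, 0.9, w) == pytest.approx(w.g_WNi * 0.7)


# -- transmitter release -----------------------------------------------------

def test_transmitter_zero_rate_zero_release():
    assert transmitter_steady_state(0.0, 2.0) == 0.0


def test_transmitter_at_release_scale():
    assert transmitter_steady_state(3.0, 3.0) == pytest.approx(math.tanh(1.0), rel=1e-12)


def test_transmitter_saturates_below_one():
    # strictly below 1 over the representable range (tanh < 1 mathematically;
    # at extreme arguments the double rounds to 1.0)
    assert transmitter_steady_state(30.0, 2.0) < 1.0
    assert transmitter_steady_state(30.0, 2.0) == pytest.approx(1.0)


def test_transmitter_rejects_negative_rate():
    with pytest.raises(ValueError):
        transmitter_steady_state(-0.1, 2.0)


@settings(**SETTINGS)
@given(F=st.floats(0, 100), F2=st.floats(0, 100), gamma=st.floats(0.1, 10))
def test_transmitter_bounded_monotone(F, F2, gamma):
    lo, hi = sorted([F, F2])
    c_lo = transmitter_steady_state(lo, gamma)
    c_hi = transmitter_steady_state(hi, gamma)
    assert 0.0 <= c_lo <= 1.0 and 0.0 <= c_hi <= 1.0
    assert c_lo <= c_hi


# -- homeostatic drive -------------------------------------------------------

def test_homeostat_fixed_points(params):
    assert homeostatic_rhs(params.H_max, params.theta_W + 1.0, params) == 0.0
    assert homeostatic_rhs(0.0, 0.0, params) == 0.0


def test_homeostat_decay_rate():
    p = ModelParameters(tau_hs=2.0)
    assert homeostatic_rhs(1.0, 0.5 * p.theta_W, p) == pytest.approx(-0.5, rel=1e-12)


def test_homeostat_signs(params):
    assert homeostatic_rhs(0.3, params.theta_W + 1.0, params) > 0
    assert homeostatic_rhs(0.3, params.theta_W - 1.0, params) < 0
    # at the threshold exactly, both step terms are active (step(0) = 1)
    p = params
    expected = (p.H_max - 0.3) / p.tau_hw - 0.3 / p.tau_hs
    assert homeostatic_rhs(0.3, p.theta_W, p) == pytest.approx(expected, rel=1e-12)


# -- assembled network RHS ---------------------------------------------------

def _self_consistent_wake_state(p: ModelParameters) -> NetworkState:
    """Fixed-point iteration for the awake equilibrium at H = H_max."""
    F = np.array([p.W_max, 0.0, 0.0])
    for _ in range(500):
        C = np.array(
            [
                transmitter_steady_state(F[0], p.gamma_C_W),
                transmitter_steady_state(F[1], p.gamma_C_N),
                transmitter_steady_state(F[2], p.gamma_C_R),
            ]
        )
        I = [synaptic_input(pop, *C, p.weights) for pop in ("W", "N", "R")]
        F = np.array(
            [steady_state_rate(pop, I[i], p.H_max, p) for i, pop in enumerate(("W", "N", "R"))]
        )
    return NetworkState(F[0], F[1], F[2], C[0], C[1], C[2], p.H_max)


def test_rhs_zero_at_self_consistent_fixed_point():
    # weak homeostatic coupling so a sustained-wake equilibrium exists
    p = ModelParameters(k_N=-0.5)
    state = _self_consistent_wake_state(p)
    assert state.F_W >= p.theta_W
    d = network_rhs(state, p).as_array()
    assert np.allclose(d, 0.0, atol=1e-9)


def test_rhs_from_silent_origin(params):
    state = NetworkState(0, 0, 0, 0, 0, 0, 0)
    d = network_rhs(state, params)
    assert d.F_W == pytest.approx(steady_state_rate("W", 0.0, 0.0, params) / params.tau_W)
    assert d.F_N == pytest.approx(steady_state_rate("N", 0.0, 0.0, params) / params.tau_N)
    assert d.F_R == pytest.approx(steady_state_rate("R", 0.0, 0.0, params) / params.tau_R)
    assert d.C_W == 0.0 and d.C_N == 0.0 and d.C_R == 0.0 and d.H == 0.0


@settings(**SETTINGS)
@given(
    fw=st.floats(0, 5), fn=st.floats(0, 5), fr=st.floats(0, 5),
    cw=st.floats(0, 1), cn=st.floats(0, 1), cr=st.floats(0, 1),
    h=st.floats(0, 1),
    xi=st.tuples(st.floats(-0.05, 0.05), st.floats(-0.05, 0.05), st.floats(-0.05, 0.05)),
)
def test_rhs_composed_exactly_from_components(fw, fn, fr, cw, cn, cr, h, xi):
    p = ModelParameters()
    s = NetworkState(fw, fn, fr, cw, cn, cr, h)
    d = network_rhs(s, p, xi)
    for i, pop in enumerate(("W", "N", "R")):
        I = synaptic_input(pop, cw, cn, cr, p.weights, xi[i])
        expected = (steady_state_rate(pop, I, h, p) - [fw, fn, fr][i]) / (
            p.tau_W, p.tau_N, p.tau_R)[i]
        assert getattr(d, f"F_{pop}") == expected  # bitwise: same ops, same order
    assert d.H == homeostatic_rhs(h, fw, p)


@settings(**SETTINGS)
@given(
    fw=st.floats(0, 5), fn=st.floats(0, 5), fr=st.floats(0, 5),
    h=st.floats(0, 1), face=st.integers(0, 13),
)
def test_rhs_points_into_state_box_on_boundary(fw, fn, fr, h, face):
    """Sign stability on every face of [0,max]^3 x [0,1]^3 x [0,H_max]:
    the flow never leaves the box, so trajectories are forward invariant."""
    p = ModelParameters()
    s = NetworkState(fw, fn, fr, 0.5, 0.5, 0.5, h)
    var = ("F_W", "F_N", "F_R", "C_W", "C_N", "C_R", "H")[face % 7]
    hi = dict(F_W=p.W_max, F_N=p.N_max, F_R=p.R_max, C_W=1.0, C_N=1.0, C_R=1.0, H=p.H_max)[var]
    setattr(s, var, 0.0 if face < 7 else hi)
    d = getattr(network_rhs(s, p), var)
    assert d >= 0.0 if face < 7 else d <= 0.0


def test_rhs_deterministic_bitwise(params):
    s = NetworkState(3.1, 0.2, 0.7, 0.9, 0.1, 0.3, 0.55)
    a = network_rhs(s, params, (0.01, 0.02, 0.03)).as_array()
    b = network_rhs(s, params, (0.01, 0.02, 0.03)).as_array()
    assert np.array_equal(a, b)
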