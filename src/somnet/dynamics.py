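"""Right-hand-side functions of the coupled sleep-wake ODE system.

The model is

    dF_X/dt = (F_Xinf(I_X) - F_X) / tau_X          (population firing rates)
    dC_Y/dt = (C_Yinf(F_Y) - C_Y) / tau_C_Y        (transmitter concentrations)
    dH/dt   = (H_max - H)/tau_hw * step(F_W - theta_W)
              - H/tau_hs * step(theta_W - F_W)     (homeostatic sleep drive)

with sigmoidal steady states

    F_Winf = W_max * 0.5 * (1 + tanh((I_W - beta_W)/alpha_W))
    F_Ninf = N_max * 0.5 * (1 + tanh((I_N - k_N*H)/alpha_N))
    F_Rinf = R_max * 0.5 * (1 + tanh((I_R - beta_R)/alpha_R))
    C_Yinf = tanh(F_Y / gamma_C_Y)

and synaptic inputs (xi is the additive noise draw, one per population)

    I_W = g_NWi*C_N + g_RWe*C_R + xi
    I_N = g_WNi*C_W + xi
    I_R = g_WRi*C_W + g_NRi*C_N + g_RRe*C_R + xi

These pure-Python functions are the reference implementation: they define the
contract, are used directly by the tests and by the generic RK4 stepper, and
the compiled integration kernel in :mod:`somnet.simulate` is checked against
them step-for-step.
"""

from __future__ import annotations

import math

import numpy as np

from .params import ModelParameters, NetworkState, PathwayWeights

__all__ = [
    "heaviside",
    "steady_state_rate",
    "synaptic_input",
    "transmitter_steady_state",
    "homeostatic_rhs",
    "network_rhs",
]


def heaviside(z: float) -> float:
    """Unit step: 0 for z < 0, 1 for z >= 0 (right-continuous convention)."""
    if not math.isfinite(z):
        raise ValueError(f"heaviside argument must be finite, got {z}")
    return 1.0 if z >= 0.0 else 0.0


def steady_state_rate(
    population: str, input_I: float, H: float, params: ModelParameters
) -> float:
    """Steady-state firing rate F_Xinf of one population for a given input.

    The NREM population has no fixed activation threshold; its threshold is
    k_N * H, so the homeostatic drive H gates NREM activation (k_N < 0 makes
    rising H promote NREM onset).  H is ignored for the other populations.
    """
    if population == "W":
        arg = (input_I - params.beta_W) / params.alpha_W
        return params.W_max * 0.5 * (1.0 + math.tanh(arg))
    if population == "N":
        arg = (input_I - params.k_N * H) / params.alpha_N
        return params.N_max * 0.5 * (1.0 + math.tanh(arg))
    if population == "R":
        arg = (input_I - params.beta_R) / params.alpha_R
        return params.R_max * 0.5 * (1.0 + math.tanh(arg))
    raise KeyError(f"unknown population {population!r}; expected W, N or R")


def synaptic_input(
    population: str,
    C_W: float,
    C_N: float,
    C_R: float,
    weights: PathwayWeights,
    noise_draw: float = 0.0,
) -> float:
    """Summed synaptic input I_X: weighted transmitter concentrations + noise."""
    if population == "W":
        return weights.g_NWi * C_N + weights.g_RWe * C_R + noise_draw
    if population == "N":
        return weights.g_WNi * C_W + noise_draw
    if population == "R":
        return weights.g_WRi * C_W + weights.g_NRi * C_N + weights.g_RRe * C_R + noise_draw
    raise KeyError(f"unknown population {population!r}; expected W, N or R")


def transmitter_steady_state(F_Y: float, gamma: float) -> float:
    """Steady-state transmitter concentration tanh(F_Y / gamma), in [0, 1)."""
    if F_Y < 0:
        raise ValueError(f"firing rate must be >= 0, got {F_Y}")
    if gamma <= 0:
        raise ValueError(f"release scale gamma must be > 0, got {gamma}")
    return math.tanh(F_Y / gamma)


def homeostatic_rhs(H: float, F_W: float, params: ModelParameters) -> float:
    """dH/dt: build-up toward H_max while the Wake rate exceeds theta_W,
    exponential decay toward 0 while below it.  With the right-continuous
    step convention both terms are active at F_W == theta_W exactly (a
    measure-zero point in practice)."""
    build = (params.H_max - H) / params.tau_hw * heaviside(F_W - params.theta_W)
    decay = H / params.tau_hs * heaviside(params.theta_W - F_W)
    return build - decay


def network_rhs(
    state: NetworkState,
    params: ModelParameters,
    noise_draws: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> NetworkState:
    """Full 7-component derivative, assembled from the component functions.

    ``noise_draws`` are the per-population additive input terms (xi_W, xi_N,
    xi_R); noise enters the dynamics only through the synaptic inputs.
    """
    xi_W, xi_N, xi_R = noise_draws
    w = params.weights
    I_W = synaptic_input("W", state.C_W, state.C_N, state.C_R, w, xi_W)
    I_N = synaptic_input("N", state.C_W, state.C_N, state.C_R, w, xi_N)
    I_R = synaptic_input("R", state.C_W, state.C_N, state.C_R, w, xi_R)
    dF_W = (steady_state_rate("W", I_W, state.H, params) - state.F_W) / params.tau_W
    dF_N = (steady_state_rate("N", I_N, state.H, params) - state.F_N) / params.tau_N
    dF_R = (steady_state_rate("R", I_R, state.H, params) - state.F_R) / params.tau_R
    dC_W = (transmitter_steady_state(state.F_W, params.gamma_C_W) - state.C_W) / params.tau_C_W
    dC_N = (transmitter_steady_state(state.F_N, params.gamma_C_N) - state.C_N) / params.tau_C_N
    dC_R = (transmitter_steady_state(state.F_R, params.gamma_C_R) - state.C_R) / params.tau_C_R
    dH = homeostatic_rhs(state.H, state.F_W, params)
    return NetworkState(dF_W, dF_N, dF_R, dC_W, dC_N, dC_R, dH)


def network_rhs_array(
    y: np.ndarray,
    params: ModelParameters,
    noise_draws: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Array-in/array-out wrapper of :func:`network_rhs` for generic steppers."""
    return network_rhs(NetworkState.from_array(y), params, noise_draws).as_array()
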