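"""Core types for the three-population sleep-wake network.

The model couples a Wake-, a NREM- and a REM-promoting neural population.
Each population is a firing-rate unit whose steady-state activation is a
sigmoid (tanh) of its summed synaptic input; populations communicate through
released neurotransmitter concentrations and the NREM unit is gated by a slow
homeostatic sleep drive.  All tunable constants of that system live in
:class:`ModelParameters`; the six directed synaptic weights live in
:class:`PathwayWeights`; the seven-dimensional dynamical state lives in
:class:`NetworkState`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PathwayWeights",
    "ModelParameters",
    "NetworkState",
    "ParameterError",
    "PATHWAYS",
    "EXCITATORY_PATHWAYS",
    "INHIBITORY_PATHWAYS",
    "STATE_VARIABLES",
]

#: Directed pathways, named source-letter + target-letter + e(xcitatory)/i(nhibitory).
PATHWAYS = ("RRe", "RWe", "WNi", "WRi", "NRi", "NWi")
EXCITATORY_PATHWAYS = ("RRe", "RWe")
INHIBITORY_PATHWAYS = ("WNi", "WRi", "NRi", "NWi")

#: Order of the dynamical state vector used throughout the package.
STATE_VARIABLES = ("F_W", "F_N", "F_R", "C_W", "C_N", "C_R", "H")


class ParameterError(ValueError):
    """Raised when a parameter set violates the model's sign or positivity rules."""


def _require(cond: bool, key: str, message: str) -> None:
    if not cond:
        raise ParameterError(f"{key}: {message}")


@dataclass(frozen=True)
class PathwayWeights:
    """The six synaptic weights (arbitrary units).

    The REM population releases an excitatory transmitter, so its two output
    weights are non-negative; the Wake and NREM populations are inhibitory,
    so their four output weights are non-positive.  The defaults are the
    control (unmanipulated) condition; perturbation experiments scale each
    weight by {0, 1/8, 1/4, 1/2, 1, 2, 4, 8}.
    """

    g_RRe: float = 1.6   # REM -> REM recurrent excitation
    g_RWe: float = 1.0   # REM -> Wake excitation
    g_WNi: float = -2.0  # Wake -> NREM inhibition
    g_WRi: float = -4.0  # Wake -> REM inhibition
    g_NRi: float = -1.3  # NREM -> REM inhibition
    g_NWi: float = -1.68  # NREM -> Wake inhibition

    def __post_init__(self) -> None:
        for name in EXCITATORY_PATHWAYS:
            _require(self[name] >= 0.0, f"g_{name}", "excitatory weight must be >= 0")
        for name in INHIBITORY_PATHWAYS:
            _require(self[name] <= 0.0, f"g_{name}", "inhibitory weight must be <= 0")
        for name in PATHWAYS:
            _require(math.isfinite(self[name]), f"g_{name}", "weight must be finite")

    def __getitem__(self, pathway: str) -> float:
        if pathway not in PATHWAYS:
            raise KeyError(f"unknown pathway {pathway!r}; expected one of {PATHWAYS}")
        return getattr(self, f"g_{pathway}")

    def scaled(self, pathway: str, scale: float) -> "PathwayWeights":
        """Return a copy with one pathway's weight multiplied by ``scale``.

        ``scale=0`` is a lesion, ``scale=1`` the control condition.
        """
        if pathway not in PATHWAYS:
            raise KeyError(f"unknown pathway {pathway!r}; expected one of {PATHWAYS}")
        if scale < 0:
            raise ParameterError("scale must be >= 0 (weights never change sign)")
        return dataclasses.replace(self, **{f"g_{pathway}": self[pathway] * scale})

    def as_dict(self) -> dict[str, float]:
        return {f"g_{p}": self[p] for p in PATHWAYS}


@dataclass(frozen=True)
class ModelParameters:
    """Every constant of the coupled ODE system plus noise/integration settings.

    Units: firing rates and their thresholds in Hz, all time constants in
    seconds, transmitter concentrations and the homeostatic drive in arbitrary
    units.  ``k_N`` couples the homeostatic drive H into the NREM activation
    threshold; it is *negative* here so that a rising H lowers the effective
    threshold and promotes NREM onset.

    The numeric defaults are a calibrated reference configuration: they were
    chosen once so that the noise-free 24 h run cycles through wakefulness,
    NREM and REM sleep with rodent-like architecture (see docs/methods.md),
    and they are frozen in the packaged ``defaults.yaml``.
    """

    # population activation
    W_max: float = 5.0
    N_max: float = 5.0
    R_max: float = 5.0
    alpha_W: float = 0.3
    alpha_N: float = 0.2
    alpha_R: float = 0.3
    beta_W: float = -0.8
    beta_R: float = -1.3
    k_N: float = -2.5

    # population membrane time constants (s)
    tau_W: float = 25.0
    tau_N: float = 10.0
    tau_R: float = 15.0

    # homeostatic sleep drive
    H_max: float = 1.0
    theta_W: float = 2.0
    tau_hw: float = 6000.0
    tau_hs: float = 3000.0

    # transmitter kinetics: decay time constant (s) and release half-saturation
    # scale (Hz) per source population.  They default to equal numbers so the
    # single-symbol form C_inf = tanh(F/tau) is recovered, but are independently
    # configurable.
    tau_C_W: float = 2.0
    tau_C_N: float = 2.0
    tau_C_R: float = 2.0
    gamma_C_W: float = 2.0
    gamma_C_N: float = 2.0
    gamma_C_R: float = 2.0

    weights: PathwayWeights = field(default_factory=PathwayWeights)

    # additive Gaussian input noise (Hz), drawn per population per step
    noise_mean: float = 0.01
    noise_sd: float = 0.005

    # integration grid
    dt: float = 1e-3
    duration: float = 86400.0

    def __post_init__(self) -> None:
        positive = (
            "W_max", "N_max", "R_max",
            "alpha_W", "alpha_N", "alpha_R",
            "tau_W", "tau_N", "tau_R",
            "H_max", "theta_W", "tau_hw", "tau_hs",
            "tau_C_W", "tau_C_N", "tau_C_R",
            "gamma_C_W", "gamma_C_N", "gamma_C_R",
            "dt", "duration",
        )
        for key in positive:
            value = getattr(self, key)
            _require(math.isfinite(value) and value > 0, key, "must be finite and > 0")
        for key in ("beta_W", "beta_R", "k_N", "noise_mean"):
            _require(math.isfinite(getattr(self, key)), key, "must be finite")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.duration >= self.dt, "duration", "must be >= dt")
        if not isinstance(self.weights, PathwayWeights):
            object.__setattr__(self, "weights", PathwayWeights(**dict(self.weights)))

    # -- convenience -------------------------------------------------------

    def replace(self, **changes) -> "ModelParameters":
        weight_keys = {k for k in changes if k.startswith("g_")}
        if weight_keys:
            weights = dataclasses.replace(
                changes.pop("weights", self.weights),
                **{k: changes.pop(k) for k in weight_keys},
            )
            changes["weights"] = weights
        return dataclasses.replace(self, **changes)

    def max_rate(self, population: str) -> float:
        try:
            return {"W": self.W_max, "N": self.N_max, "R": self.R_max}[population]
        except KeyError:
            raise KeyError(f"unknown population {population!r}; expected W, N or R") from None

    def to_flat_dict(self) -> dict[str, float]:
        """Flat key -> value mapping (weights inlined as g_* keys)."""
        out = {}
        for f in dataclasses.fields(self):
            if f.name == "weights":
                out.update(self.weights.as_dict())
            else:
                out[f.name] = getattr(self, f.name)
        return out

    @classmethod
    def from_flat_dict(cls, data: dict[str, float]) -> "ModelParameters":
        field_names = {f.name for f in dataclasses.fields(cls)} - {"weights"}
        weight_keys = {f"g_{p}" for p in PATHWAYS}
        kwargs: dict = {}
        wkwargs: dict = {}
        for key, value in data.items():
            if key in weight_keys:
                wkwargs[key] = float(value)
            elif key in field_names:
                kwargs[key] = float(value)
            else:
                raise ParameterError(f"{key}: unknown parameter key")
        kwargs["weights"] = PathwayWeights(**{**PathwayWeights().as_dict(), **wkwargs})
        return cls(**kwargs)

    def digest(self) -> str:
        """Stable hex digest of the resolved parameter values."""
        payload = json.dumps(self.to_flat_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class NetworkState:
    """The 7-dimensional dynamical state.

    ``F_X``: population firing rates (Hz), bounded by the population maxima;
    ``C_Y``: transmitter concentration released by source population Y,
    normalised to [0, 1]; ``H``: homeostatic sleep drive in [0, H_max].
    """

    F_W: float
    F_N: float
    F_R: float
    C_W: float
    C_N: float
    C_R: float
    H: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.F_W, self.F_N, self.F_R, self.C_W, self.C_N, self.C_R, self.H],
            dtype=float,
        )

    @classmethod
    def from_array(cls, y: np.ndarray) -> "NetworkState":
        y = np.asarray(y, dtype=float)
        if y.shape != (7,):
            raise ValueError(f"state vector must have shape (7,), got {y.shape}")
        return cls(*[float(v) for v in y])

    def validate(self, params: ModelParameters, tol: float = 1e-9) -> None:
        for name, hi in (("F_W", params.W_max), ("F_N", params.N_max), ("F_R", params.R_max)):
            v = getattr(self, name)
            _require(-tol <= v <= hi + tol, name, f"firing rate outside [0, {hi}]")
        for name in ("C_W", "C_N", "C_R"):
            v = getattr(self, name)
            _require(-tol <= v <= 1.0 + tol, name, "concentration outside [0, 1]")
        _require(-tol <= self.H <= params.H_max + tol, "H", f"drive outside [0, {params.H_max}]")


def initial_state(params: ModelParameters) -> NetworkState:
    """Canonical initial condition: fully awake, no accumulated sleep drive.

    The Wake population starts at its maximum rate, NREM and REM silent,
    transmitter concentrations at their steady states for those rates, H = 0.
    """
    return NetworkState(
        F_W=params.W_max,
        F_N=0.0,
        F_R=0.0,
        C_W=math.tanh(params.W_max / params.gamma_C_W),
        C_N=0.0,
        C_R=0.0,
        H=0.0,
    )
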