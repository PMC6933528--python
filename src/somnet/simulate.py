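"""Fixed-step RK4 integration of the stochastic sleep-wake network.

Two integration paths exist on purpose:

* :func:`rk4_step` is a small, generic, pure-Python classical Runge-Kutta
  step used by the tests (convergence order, fixed-point preservation) and
  for spot-checking the compiled path.
* :func:`run_simulation` drives a numba-compiled kernel over the full grid
  (a 24 h day at dt = 1 ms is 86.4 million steps) and is the production path.
  The kernel reimplements the same arithmetic as :mod:`somnet.dynamics`; the
  test suite asserts step-for-step agreement between the two.

Noise convention: one Gaussian draw per population per time step (order W, N,
R within a step), frozen across the four RK4 stages of that step, entering
the dynamics additively through the synaptic inputs.  Draws come from a
seeded ``numpy.random.Generator`` (PCG64), so a (parameters, seed) pair fully
determines the trajectory.  ``seed=None`` selects the noise-free system
(xi == 0), used for deterministic tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import __version__
from .params import ModelParameters, NetworkState, STATE_VARIABLES, initial_state

__all__ = [
    "IntegrationError",
    "TimeSeries",
    "rk4_step",
    "sample_noise",
    "run_simulation",
    "write_timeseries",
    "read_timeseries",
]

#: Absolute tolerance for clipping RK4 overshoot back onto the invariant box
#: [0, F_max] x [0, 1] x [0, H_max].  Every vector field component points into
#: the box on its boundary, so genuine excursions are truncation-level; a
#: larger excursion indicates a defect and raises instead of being hidden.
BOX_TOL = 1e-9

_RNG_ALGORITHM = "numpy.random.Generator(PCG64)"
_NOISE_ORDER = "W,N,R per step, frozen across RK4 stages"
_CHUNK_STEPS = 2_000_000


class IntegrationError(RuntimeError):
    """Integration failure, carrying the offending step and state component."""

    def __init__(self, message: str, step: int | None = None, component: str | None = None):
        super().__init__(message)
        self.step = step
        self.component = component


@dataclass
class TimeSeries:
    """A sampled trajectory of the network state on a uniform time grid.

    ``values`` has one row per stored sample and the seven columns of
    ``STATE_VARIABLES``.  ``metadata`` records seed, parameter digest, grid,
    storage stride and RNG provenance so any run can be reproduced.
    """

    times: np.ndarray
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 7:
            raise ValueError("values must be an (n, 7) array")
        if self.times.shape != (self.values.shape[0],):
            raise ValueError("times and values lengths differ")
        if len(self.times) == 0:
            raise ValueError("empty trajectory")
        if len(self.times) > 1:
            steps = np.diff(self.times)
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12) or steps[0] <= 0:
                raise ValueError("time grid must be strictly increasing with constant spacing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def sample_dt(self) -> float:
        """Spacing of the *stored* grid (integration dt times storage stride)."""
        if len(self.times) > 1:
            return float(self.times[1] - self.times[0])
        return float(self.metadata.get("dt", 0.0)) * int(self.metadata.get("store_stride", 1))

    def column(self, name: str) -> np.ndarray:
        return self.values[:, STATE_VARIABLES.index(name)]

    @property
    def F_W(self) -> np.ndarray:
        return self.column("F_W")

    @property
    def F_N(self) -> np.ndarray:
        return self.column("F_N")

    @property
    def F_R(self) -> np.ndarray:
        return self.column("F_R")

    @property
    def H(self) -> np.ndarray:
        return self.column("H")

    def state_at(self, i: int) -> NetworkState:
        return NetworkState.from_array(self.values[i])

    def in_box(self, params: ModelParameters, tol: float = 1e-7) -> bool:
        """True if every stored sample lies in the invariant state box."""
        lo, hi = _state_bounds(params)
        return bool(
            np.all(self.values >= lo - tol) and np.all(self.values <= hi + tol)
        )


# ---------------------------------------------------------------------------
# generic RK4 (reference path)
# ---------------------------------------------------------------------------

def _state_bounds(params: ModelParameters) -> tuple[np.ndarray, np.ndarray]:
    lo = np.zeros(7)
    hi = np.array([params.W_max, params.N_max, params.R_max, 1.0, 1.0, 1.0, params.H_max])
    return lo, hi


def rk4_step(y, dt, frozen_rhs, bounds=None, clip_tol=BOX_TOL):
    """One classical 4th-order Runge-Kutta step of ``dy/dt = frozen_rhs(y)``.

    ``frozen_rhs`` must be deterministic for the duration of the step (noise,
    if any, is frozen into it).  If ``bounds=(lo, hi)`` is given, the result
    is clipped back onto the box when the overshoot is below ``clip_tol``;
    a larger overshoot or a non-finite stage raises :class:`IntegrationError`.
    """
    y = np.asarray(y, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    k1 = np.asarray(frozen_rhs(y), dtype=float)
    k2 = np.asarray(frozen_rhs(y + 0.5 * dt * k1), dtype=float)
    k3 = np.asarray(frozen_rhs(y + 0.5 * dt * k2), dtype=float)
    k4 = np.asarray(frozen_rhs(y + dt * k3), dtype=float)
    for k in (k1, k2, k3, k4):
        if not np.all(np.isfinite(k)):
            comp = int(np.flatnonzero(~np.isfinite(k))[0])
            raise IntegrationError(
                f"non-finite RK4 stage value in component {comp}", component=str(comp)
            )
    out = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if bounds is not None:
        lo, hi = bounds
        if np.any(out < lo - clip_tol) or np.any(out > hi + clip_tol):
            comp = int(np.flatnonzero((out < lo - clip_tol) | (out > hi + clip_tol))[0])
            raise IntegrationError(
                f"state left the invariant box in component {comp}", component=str(comp)
            )
        out = np.clip(out, lo, hi)
    return out


def sample_noise(rng: np.random.Generator, n_steps: int, mean: float, sd: float) -> np.ndarray:
    """Per-step, per-population Gaussian input noise draws, shape (n_steps, 3).

    Row i holds the draws for step i in the fixed order (W, N, R).  The same
    seeded generator yields a bitwise-identical sequence, and the sequence is
    independent of how it is chunked because draws are consumed row-major.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    return rng.normal(loc=mean, scale=sd, size=(n_steps, 3))


# ---------------------------------------------------------------------------
# compiled kernel (production path)
# ---------------------------------------------------------------------------

# Order of the packed constant vector consumed by the kernel.
_CONST_KEYS = (
    "W_max", "N_max", "R_max",            # 0..2
    "alpha_W", "alpha_N", "alpha_R",      # 3..5
    "beta_W", "beta_R", "k_N",            # 6..8
    "tau_W", "tau_N", "tau_R",            # 9..11
    "H_max", "theta_W", "tau_hw", "tau_hs",  # 12..15
    "tau_C_W", "tau_C_N", "tau_C_R",      # 16..18
    "gamma_C_W", "gamma_C_N", "gamma_C_R",  # 19..21
    "g_RRe", "g_RWe", "g_WNi", "g_WRi", "g_NRi", "g_NWi",  # 22..27
)


def _pack_constants(params: ModelParameters) -> np.ndarray:
    flat = params.to_flat_dict()
    return np.array([flat[k] for k in _CONST_KEYS], dtype=float)


@njit(inline="always")
def _rhs_kernel(FW, FN, FR, CW, CN, CR, H, xw, xn, xr, c):
    IW = c[27] * CN + c[23] * CR + xw
    IN = c[24] * CW + xn
    IR = c[25] * CW + c[26] * CN + c[22] * CR + xr
    FWinf = c[0] * 0.5 * (1.0 + math.tanh((IW - c[6]) / c[3]))
    FNinf = c[1] * 0.5 * (1.0 + math.tanh((IN - c[8] * H) / c[4]))
    FRinf = c[2] * 0.5 * (1.0 + math.tanh((IR - c[7]) / c[5]))
    dFW = (FWinf - FW) / c[9]
    dFN = (FNinf - FN) / c[10]
    dFR = (FRinf - FR) / c[11]
    dCW = (math.tanh(FW / c[19]) - CW) / c[16]
    dCN = (math.tanh(FN / c[20]) - CN) / c[17]
    dCR = (math.tanh(FR / c[21]) - CR) / c[18]
    # both step terms are active at FW == theta_W exactly (H(0) = 1), matching
    # the reference implementation literally
    if FW > c[13]:
        dH = (c[12] - H) / c[14]
    elif FW < c[13]:
        dH = -H / c[15]
    else:
        dH = (c[12] - H) / c[14] - H / c[15]
    return dFW, dFN, dFR, dCW, dCN, dCR, dH


@njit(cache=True)
def _integrate_chunk(y, c, noise, dt, stride, start_step, out):
    """Advance ``y`` in place over ``noise.shape[0]`` steps, storing decimated
    samples into ``out``.  Hot path: clips every component onto the invariant
    box branchlessly and returns the largest excursion seen; the caller
    escalates to :func:`_integrate_chunk_checked` when that exceeds BOX_TOL
    (or when a non-finite value survives to the end of the chunk)."""
    FW, FN, FR, CW, CN, CR, H = y[0], y[1], y[2], y[3], y[4], y[5], y[6]
    hiW, hiN, hiR, hiH = c[0], c[1], c[2], c[12]
    n = noise.shape[0]
    overshoot = 0.0
    since = start_step % stride
    k = start_step // stride
    for i in range(n):
        xw = noise[i, 0]
        xn = noise[i, 1]
        xr = noise[i, 2]
        a1, b1, r1, p1, q1, s1, h1 = _rhs_kernel(FW, FN, FR, CW, CN, CR, H, xw, xn, xr, c)
        a2, b2, r2, p2, q2, s2, h2 = _rhs_kernel(
            FW + 0.5 * dt * a1, FN + 0.5 * dt * b1, FR + 0.5 * dt * r1,
            CW + 0.5 * dt * p1, CN + 0.5 * dt * q1, CR + 0.5 * dt * s1,
            H + 0.5 * dt * h1, xw, xn, xr, c)
        a3, b3, r3, p3, q3, s3, h3 = _rhs_kernel(
            FW + 0.5 * dt * a2, FN + 0.5 * dt * b2, FR + 0.5 * dt * r2,
            CW + 0.5 * dt * p2, CN + 0.5 * dt * q2, CR + 0.5 * dt * s2,
            H + 0.5 * dt * h2, xw, xn, xr, c)
        a4, b4, r4, p4, q4, s4, h4 = _rhs_kernel(
            FW + dt * a3, FN + dt * b3, FR + dt * r3,
            CW + dt * p3, CN + dt * q3, CR + dt * s3,
            H + dt * h3, xw, xn, xr, c)
        w = dt / 6.0
        FW += w * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
        FN += w * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
        FR += w * (r1 + 2.0 * r2 + 2.0 * r3 + r4)
        CW += w * (p1 + 2.0 * p2 + 2.0 * p3 + p4)
        CN += w * (q1 + 2.0 * q2 + 2.0 * q3 + q4)
        CR += w * (s1 + 2.0 * s2 + 2.0 * s3 + s4)
        H += w * (h1 + 2.0 * h2 + 2.0 * h3 + h4)

        fw = min(max(FW, 0.0), hiW)
        fn = min(max(FN, 0.0), hiN)
        fr = min(max(FR, 0.0), hiR)
        cw = min(max(CW, 0.0), 1.0)
        cn = min(max(CN, 0.0), 1.0)
        cr = min(max(CR, 0.0), 1.0)
        hh = min(max(H, 0.0), hiH)
        overshoot = max(
            overshoot,
            abs(FW - fw) + abs(FN - fn) + abs(FR - fr)
            + abs(CW - cw) + abs(CN - cn) + abs(CR - cr) + abs(H - hh),
        )
        FW, FN, FR, CW, CN, CR, H = fw, fn, fr, cw, cn, cr, hh

        since += 1
        if since == stride:
            since = 0
            k += 1
            out[k, 0] = FW
            out[k, 1] = FN
            out[k, 2] = FR
            out[k, 3] = CW
            out[k, 4] = CN
            out[k, 5] = CR
            out[k, 6] = H
    y[0], y[1], y[2], y[3], y[4], y[5], y[6] = FW, FN, FR, CW, CN, CR, H
    return overshoot


@njit(cache=True)
def _integrate_chunk_checked(y, c, noise, dt, start_step, box_tol):
    """Slow diagnostic twin of :func:`_integrate_chunk`: checks every step
    and returns (status, global_step, component) locating the first failure
    (status 1: non-finite, status 2: out-of-box, 0: clean)."""
    FW, FN, FR, CW, CN, CR, H = y[0], y[1], y[2], y[3], y[4], y[5], y[6]
    hi0, hi1, hi2, hi6 = c[0], c[1], c[2], c[12]
    n = noise.shape[0]
    for i in range(n):
        xw = noise[i, 0]
        xn = noise[i, 1]
        xr = noise[i, 2]
        a1, b1, r1, p1, q1, s1, h1 = _rhs_kernel(FW, FN, FR, CW, CN, CR, H, xw, xn, xr, c)
        a2, b2, r2, p2, q2, s2, h2 = _rhs_kernel(
            FW + 0.5 * dt * a1, FN + 0.5 * dt * b1, FR + 0.5 * dt * r1,
            CW + 0.5 * dt * p1, CN + 0.5 * dt * q1, CR + 0.5 * dt * s1,
            H + 0.5 * dt * h1, xw, xn, xr, c)
        a3, b3, r3, p3, q3, s3, h3 = _rhs_kernel(
            FW + 0.5 * dt * a2, FN + 0.5 * dt * b2, FR + 0.5 * dt * r2,
            CW + 0.5 * dt * p2, CN + 0.5 * dt * q2, CR + 0.5 * dt * s2,
            H + 0.5 * dt * h2, xw, xn, xr, c)
        a4, b4, r4, p4, q4, s4, h4 = _rhs_kernel(
            FW + dt * a3, FN + dt * b3, FR + dt * r3,
            CW + dt * p3, CN + dt * q3, CR + dt * s3,
            H + dt * h3, xw, xn, xr, c)
        w = dt / 6.0
        FW += w * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
        FN += w * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
        FR += w * (r1 + 2.0 * r2 + 2.0 * r3 + r4)
        CW += w * (p1 + 2.0 * p2 + 2.0 * p3 + p4)
        CN += w * (q1 + 2.0 * q2 + 2.0 * q3 + q4)
        CR += w * (s1 + 2.0 * s2 + 2.0 * s3 + s4)
        H += w * (h1 + 2.0 * h2 + 2.0 * h3 + h4)

        y[0], y[1], y[2], y[3], y[4], y[5], y[6] = FW, FN, FR, CW, CN, CR, H
        for j in range(7):
            v = y[j]
            if not math.isfinite(v):
                return 1, start_step + i, j
            if j == 0:
                hij = hi0
            elif j == 1:
                hij = hi1
            elif j == 2:
                hij = hi2
            elif j == 6:
                hij = hi6
            else:
                hij = 1.0
            if v < -box_tol or v > hij + box_tol:
                return 2, start_step + i, j
            if v < 0.0:
                y[j] = 0.0
            elif v > hij:
                y[j] = hij
        FW, FN, FR, CW, CN, CR, H = y[0], y[1], y[2], y[3], y[4], y[5], y[6]
    return 0, start_step + n, -1


def run_simulation(
    params: ModelParameters,
    seed: int | None = None,
    store_stride: int = 1,
    initial: NetworkState | None = None,
) -> TimeSeries:
    """Integrate the full model over ``params.duration`` at step ``params.dt``.

    ``seed=None`` runs the noise-free system (xi == 0); an integer seed runs
    the stochastic system with reproducible draws.  ``store_stride`` keeps
    every stride-th sample (plus the initial condition): integration always
    happens on the dt grid, only storage is decimated.
    """
    if store_stride < 1 or int(store_stride) != store_stride:
        raise ValueError("store_stride must be a positive integer")
    store_stride = int(store_stride)
    n_steps = int(math.floor(params.duration / params.dt + 1e-9))
    n_store = n_steps // store_stride + 1
    state0 = initial if initial is not None else initial_state(params)
    state0.validate(params)

    c = _pack_constants(params)
    y = state0.as_array()
    out = np.empty((n_store, 7), dtype=float)
    out[0] = y
    rng = None if seed is None else np.random.default_rng(seed)

    done = 0
    while done < n_steps:
        m = min(_CHUNK_STEPS, n_steps - done)
        if rng is None:
            noise = np.zeros((m, 3))
        else:
            noise = sample_noise(rng, m, params.noise_mean, params.noise_sd)
        y_chunk_start = y.copy()
        overshoot = _integrate_chunk(y, c, noise, params.dt, store_stride, done, out)
        if overshoot > BOX_TOL or not np.all(np.isfinite(y)):
            # escalate: replay the chunk step-by-step to locate the failure
            status, step, comp = _integrate_chunk_checked(
                y_chunk_start, c, noise, params.dt, done, BOX_TOL
            )
            name = STATE_VARIABLES[comp] if comp >= 0 else "unknown"
            reason = "non-finite value" if status == 1 else "left the invariant state box"
            raise IntegrationError(
                f"integration failed at step {step} ({step * params.dt:.3f} s): "
                f"component {name} {reason}",
                step=step,
                component=name,
            )
        done += m

    times = np.arange(n_store, dtype=float) * (params.dt * store_stride)
    metadata = {
        "seed": seed,
        "params_digest": params.digest(),
        "dt": params.dt,
        "duration": params.duration,
        "store_stride": store_stride,
        "noise_free": seed is None,
        "rng": _RNG_ALGORITHM,
        "noise_order": _NOISE_ORDER,
        "numpy_version": np.__version__,
        "somnet_version": __version__,
    }
    return TimeSeries(times=times, values=out, metadata=metadata)


# ---------------------------------------------------------------------------
# trajectory I/O (tab-separated, metadata in comment header)
# ---------------------------------------------------------------------------

def write_timeseries(ts: TimeSeries, path) -> None:
    """Write a trajectory as TSV: '# key: value' metadata header, then columns
    time_s, F_W, F_N, F_R, C_W, C_N, C_R, H at full float precision."""
    with open(path, "w") as fh:
        for key in sorted(ts.metadata):
            fh.write(f"# {key}: {ts.metadata[key]!r}\n")
        fh.write("time_s\t" + "\t".join(STATE_VARIABLES) + "\n")
        data = np.column_stack([ts.times, ts.values])
        np.savetxt(fh, data, fmt="%.17g", delimiter="\t")


def read_timeseries(path) -> TimeSeries:
    """Read a trajectory written by :func:`write_timeseries` (bit-exact round
    trip at the stored precision)."""
    import ast

    metadata: dict = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, raw = line[1:].partition(":")
                try:
                    metadata[key.strip()] = ast.literal_eval(raw.strip())
                except (ValueError, SyntaxError):
                    metadata[key.strip()] = raw.strip()
                n_header += 1
            else:
                break
    data = np.loadtxt(path, skiprows=n_header + 1, delimiter="\t", ndmin=2)
    return TimeSeries(times=data[:, 0], values=data[:, 1:], metadata=metadata)
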