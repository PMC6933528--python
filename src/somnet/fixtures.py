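"""Synthetic hypnograms, synthetic trajectories and independent oracles.

These generators make the scoring and statistics layers testable without the
ODE core: piecewise-constant rate traces with known classification, random
hypnograms with known episode structure (explicit episode lists or a seeded
first-order Markov chain whose dwell times are geometric at the sample
resolution - a test device, not a biological claim), and a deliberately
naive per-sample metrics oracle that shares no code with the run-length
implementation in :mod:`somnet.scoring`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import ModelParameters
from .scoring import Hypnogram, MetricsRecord, NREM, REM, STATES, WAKE
from .simulate import TimeSeries

__all__ = [
    "SyntheticHypnogramSpec",
    "make_synthetic_hypnogram",
    "brute_force_metrics_oracle",
    "make_test_timeseries",
]

_CODE = {WAKE: 0, NREM: 1, REM: 2}
_LABEL = {v: k for k, v in _CODE.items()}


@dataclass(frozen=True)
class SyntheticHypnogramSpec:
    """Either an explicit episode list or Markov episode statistics.

    Explicit mode: ``episodes`` is a sequence of (state, duration_s) pairs
    realised exactly.  Markov mode: ``transition_probs`` is a 3x3 row-
    stochastic matrix over (WAKE, NREM, REM) giving the next-episode state
    distribution, ``mean_durations_s`` the per-state mean episode duration
    (dwell times are geometric at dt resolution), and episodes are drawn
    until ``total_duration_s`` is filled.
    """

    dt: float = 1.0
    episodes: tuple[tuple[str, float], ...] | None = None
    transition_probs: tuple[tuple[float, float, float], ...] | None = None
    mean_durations_s: dict[str, float] | None = None
    total_duration_s: float | None = None
    initial_state: str = WAKE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        explicit = self.episodes is not None
        markov = self.transition_probs is not None
        if explicit == markov:
            raise ValueError("specify exactly one of episodes / transition_probs")
        if explicit:
            for state, duration in self.episodes:
                if state not in STATES:
                    raise ValueError(f"unknown state {state!r}")
                if duration <= 0:
                    raise ValueError("episode durations must be > 0")
        else:
            P = np.asarray(self.transition_probs, dtype=float)
            if P.shape != (3, 3) or np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0):
                raise ValueError("transition_probs must be a 3x3 row-stochastic matrix")
            if self.mean_durations_s is None or self.total_duration_s is None:
                raise ValueError("Markov mode needs mean_durations_s and total_duration_s")
            for s in STATES:
                if self.mean_durations_s.get(s, 0.0) < self.dt:
                    raise ValueError(f"mean duration for {s} must be >= dt")
            if self.total_duration_s < self.dt:
                raise ValueError("total_duration_s must be >= dt")


def make_synthetic_hypnogram(spec: SyntheticHypnogramSpec) -> Hypnogram:
    """Realise the spec exactly (explicit mode) or stochastically (Markov
    mode; the same seed yields an identical hypnogram)."""
    if spec.episodes is not None:
        return Hypnogram.from_episodes(spec.episodes, spec.dt, {"synthetic": "explicit"})

    rng = np.random.default_rng(spec.seed)
    P = np.asarray(spec.transition_probs, dtype=float)
    n_total = int(round(spec.total_duration_s / spec.dt))
    codes = np.empty(n_total, dtype=np.int8)
    pos = 0
    state = _CODE[spec.initial_state]
    while pos < n_total:
        mean_samples = spec.mean_durations_s[_LABEL[state]] / spec.dt
        n = rng.geometric(1.0 / mean_samples)
        n = min(n, n_total - pos)
        codes[pos:pos + n] = state
        pos += n
        state = rng.choice(3, p=P[state])
    return Hypnogram(codes, spec.dt, {"synthetic": "markov", "seed": spec.seed})


def brute_force_metrics_oracle(h: Hypnogram) -> MetricsRecord:
    """Metrics by a plain per-sample scan (no run-length encoding, no numpy
    vector tricks).  Test oracle only; intentionally independent of
    :func:`somnet.scoring.compute_metrics`."""
    labels = [_LABEL[int(c)] for c in h.codes]
    duration = {s: 0.0 for s in STATES}
    episode_count = {s: 0 for s in STATES}
    transition_count = {(a, b): 0 for a in STATES for b in STATES if a != b}
    prev = None
    for lab in labels:
        duration[lab] += h.dt
        if lab != prev:
            episode_count[lab] += 1
            if prev is not None:
                transition_count[(prev, lab)] += 1
        prev = lab
    total = len(labels) * h.dt
    percent = {s: 100.0 * duration[s] / total for s in STATES}

    nrem_latency = math.nan
    rem_latency = math.nan
    prev = None
    for i, lab in enumerate(labels):
        if math.isnan(nrem_latency) and lab == NREM:
            nrem_latency = i * h.dt
        if (not math.isnan(nrem_latency)) and lab == REM and prev != REM:
            rem_latency = i * h.dt - nrem_latency
            break
        prev = lab
    return MetricsRecord(
        duration_s=duration,
        percent=percent,
        episode_count=episode_count,
        transition_count=transition_count,
        nrem_latency_s=nrem_latency,
        rem_latency_s=rem_latency,
        metadata={"oracle": "brute_force"},
    )


def make_test_timeseries(
    segments,
    dt: float = 1.0,
    C: tuple[float, float, float] = (0.5, 0.5, 0.5),
    H: float = 0.5,
    params: ModelParameters | None = None,
) -> TimeSeries:
    """Piecewise-constant rate trajectory for exercising the scoring layer.

    ``segments`` is a sequence of (start_s, end_s, F_W, F_N, F_R) tuples that
    must tile [0, total] contiguously from 0; gaps and overlaps are rejected.
    Concentrations and the homeostatic drive are filled with admissible
    constants.  The stored grid has a sample at every dt in [0, total].
    """
    if not segments:
        raise ValueError("at least one segment required")
    segments = sorted(segments, key=lambda s: s[0])
    expected_start = 0.0
    for start, end, *_rates in segments:
        if not math.isclose(start, expected_start, abs_tol=1e-9):
            raise ValueError(
                f"segments must tile the duration contiguously: gap/overlap at {start} s"
            )
        if end <= start:
            raise ValueError("segment end must exceed its start")
        expected_start = end
    total = segments[-1][1]
    n = int(round(total / dt)) + 1
    times = np.arange(n) * dt
    values = np.empty((n, 7))
    values[:, 3:6] = np.asarray(C, dtype=float)
    values[:, 6] = H
    for start, end, fw, fn, fr in segments:
        if min(fw, fn, fr) < 0:
            raise ValueError("rates must be >= 0")
        mask = (times >= start - 1e-12) & (times < end - 1e-12)
        values[mask, 0] = fw
        values[mask, 1] = fn
        values[mask, 2] = fr
    # final grid point belongs to the last segment
    values[-1, 0:3] = segments[-1][2:5]
    metadata = {"synthetic": "piecewise", "dt": dt, "store_stride": 1, "duration": total}
    ts = TimeSeries(times=times, values=values, metadata=metadata)
    if params is not None and not ts.in_box(params):
        raise ValueError("requested rates leave the model's state box")
    return ts
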