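"""Hypnogram scoring and sleep-architecture metrics.

State rule (applied per stored sample, thresholds 2 Hz by default, strict
inequalities): Wake if the Wake-promoting rate exceeds the wake threshold;
otherwise REM if the REM-promoting rate exceeds the REM threshold; otherwise
NREM.  No smoothing or minimum episode duration is applied by default; an
optional minimum-duration filter is available but off unless requested.

Metrics per run: total duration and percentage of time per state, episode
counts, ordered transition counts, NREM latency (onset of the first NREM
episode from t = 0) and REM latency (first REM onset at or after the first
NREM onset, minus that NREM onset).  A latency whose defining state never
occurs is NaN ("no occurrence").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .simulate import TimeSeries

__all__ = [
    "WAKE", "NREM", "REM", "STATES",
    "Episode", "Hypnogram", "MetricsRecord",
    "classify_sample", "classify_trace", "build_hypnogram",
    "compute_metrics", "latencies", "export_trajectory",
    "write_hypnogram", "read_hypnogram",
    "metrics_to_frame",
]

WAKE, NREM, REM = "WAKE", "NREM", "REM"
STATES = (WAKE, NREM, REM)
_CODE = {WAKE: 0, NREM: 1, REM: 2}
_LABEL = {v: k for k, v in _CODE.items()}

#: Classification thresholds (Hz): a state is assigned only when the rate is
#: strictly above its threshold.
WAKE_THRESHOLD = 2.0
REM_THRESHOLD = 2.0


class Episode(NamedTuple):
    state: str
    onset_s: float
    duration_s: float


def classify_sample(
    F_W: float,
    F_R: float,
    wake_threshold: float = WAKE_THRESHOLD,
    rem_threshold: float = REM_THRESHOLD,
) -> str:
    """Classify one sample.  Precedence: Wake rule first, then REM, else NREM.

    Both comparisons are strict, so a rate exactly at threshold falls through
    to the next rule.
    """
    if F_W < 0 or F_R < 0:
        raise ValueError("firing rates must be >= 0")
    if F_W > wake_threshold:
        return WAKE
    if F_R > rem_threshold:
        return REM
    return NREM


def classify_trace(
    F_W: np.ndarray,
    F_R: np.ndarray,
    wake_threshold: float = WAKE_THRESHOLD,
    rem_threshold: float = REM_THRESHOLD,
) -> np.ndarray:
    """Vectorised :func:`classify_sample`; returns int8 codes (0=WAKE, 1=NREM, 2=REM)."""
    F_W = np.asarray(F_W, dtype=float)
    F_R = np.asarray(F_R, dtype=float)
    if np.any(F_W < 0) or np.any(F_R < 0):
        raise ValueError("firing rates must be >= 0")
    codes = np.full(F_W.shape, _CODE[NREM], dtype=np.int8)
    codes[F_R > rem_threshold] = _CODE[REM]
    codes[F_W > wake_threshold] = _CODE[WAKE]
    return codes


@dataclass
class Hypnogram:
    """Per-sample vigilance-state labels on a uniform grid plus their
    run-length episode encoding."""

    codes: np.ndarray
    dt: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 1 or len(self.codes) == 0:
            raise ValueError("hypnogram must be a non-empty 1-D label sequence")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not np.all((self.codes >= 0) & (self.codes <= 2)):
            raise ValueError("labels must be 0 (WAKE), 1 (NREM) or 2 (REM)")

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def duration_s(self) -> float:
        return len(self.codes) * self.dt

    @property
    def labels(self) -> list[str]:
        return [_LABEL[int(c)] for c in self.codes]

    @property
    def episodes(self) -> list[Episode]:
        """Exact run-length encoding: adjacent episodes differ in state and
        episode durations sum to the total duration."""
        changes = np.flatnonzero(np.diff(self.codes)) + 1
        starts = np.concatenate([[0], changes])
        ends = np.concatenate([changes, [len(self.codes)]])
        return [
            Episode(_LABEL[int(self.codes[s])], s * self.dt, (e - s) * self.dt)
            for s, e in zip(starts, ends)
        ]

    @classmethod
    def from_episodes(
        cls, episodes: Iterable[tuple[str, float]], dt: float, metadata: dict | None = None
    ) -> "Hypnogram":
        """Build a hypnogram from (state, duration_s) pairs; each duration must
        be a positive whole number of samples."""
        parts = []
        for state, duration in episodes:
            n = duration / dt
            if duration <= 0 or abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"episode duration {duration} must be a positive multiple of dt={dt}"
                )
            parts.append(np.full(int(round(n)), _CODE[state], dtype=np.int8))
        if not parts:
            raise ValueError("at least one episode required")
        return cls(np.concatenate(parts), dt, metadata or {})

    def filtered(self, min_duration_s: float) -> "Hypnogram":
        """Optional minimum-episode-duration filter (off by default in the
        pipeline): episodes shorter than the minimum are merged into the
        preceding episode's state."""
        if min_duration_s <= 0:
            return self
        codes = self.codes.copy()
        pos = 0
        for ep in self.episodes:
            n = int(round(ep.duration_s / self.dt))
            if ep.duration_s < min_duration_s and pos > 0:
                codes[pos:pos + n] = codes[pos - 1]
            pos += n
        return Hypnogram(codes, self.dt, dict(self.metadata))


def build_hypnogram(
    ts: TimeSeries,
    wake_threshold: float = WAKE_THRESHOLD,
    rem_threshold: float = REM_THRESHOLD,
) -> Hypnogram:
    """Score a trajectory sample-by-sample on its stored grid."""
    codes = classify_trace(ts.F_W, ts.F_R, wake_threshold, rem_threshold)
    meta = {
        "sample_dt": ts.sample_dt,
        "wake_threshold": wake_threshold,
        "rem_threshold": rem_threshold,
        "scored_on_stride": ts.metadata.get("store_stride", 1),
    }
    meta.update({k: ts.metadata[k] for k in ("seed", "params_digest") if k in ts.metadata})
    return Hypnogram(codes, ts.sample_dt, meta)


@dataclass
class MetricsRecord:
    """One run's sleep-architecture summary."""

    duration_s: dict[str, float]
    percent: dict[str, float]
    episode_count: dict[str, int]
    transition_count: dict[tuple[str, str], int]
    nrem_latency_s: float
    rem_latency_s: float  # NaN when REM (or NREM) never occurs
    metadata: dict = field(default_factory=dict)

    @property
    def total_duration_s(self) -> float:
        return float(sum(self.duration_s.values()))

    @property
    def total_episodes(self) -> int:
        return int(sum(self.episode_count.values()))

    @property
    def total_transitions(self) -> int:
        return int(sum(self.transition_count.values()))

    def to_row(self) -> dict:
        row = dict(self.metadata)
        for s in STATES:
            row[f"duration_{s}_s"] = self.duration_s[s]
            row[f"percent_{s}"] = self.percent[s]
            row[f"episodes_{s}"] = self.episode_count[s]
        for a in STATES:
            for b in STATES:
                if a != b:
                    row[f"transitions_{a}_{b}"] = self.transition_count[(a, b)]
        row["nrem_latency_s"] = self.nrem_latency_s
        row["rem_latency_s"] = self.rem_latency_s
        return row


def compute_metrics(h: Hypnogram) -> MetricsRecord:
    """Totals, percentages, episode and ordered transition counts, latencies."""
    counts = np.bincount(h.codes, minlength=3)
    duration = {s: float(counts[_CODE[s]] * h.dt) for s in STATES}
    total = h.duration_s
    percent = {s: 100.0 * duration[s] / total for s in STATES}
    episodes = h.episodes
    episode_count = {s: 0 for s in STATES}
    transition_count = {(a, b): 0 for a in STATES for b in STATES if a != b}
    prev = None
    for ep in episodes:
        episode_count[ep.state] += 1
        if prev is not None:
            transition_count[(prev, ep.state)] += 1
        prev = ep.state
    nrem_lat, rem_lat = latencies(h)
    return MetricsRecord(
        duration_s=duration,
        percent=percent,
        episode_count=episode_count,
        transition_count=transition_count,
        nrem_latency_s=nrem_lat,
        rem_latency_s=rem_lat,
        metadata=dict(h.metadata),
    )


def latencies(h: Hypnogram) -> tuple[float, float]:
    """(NREM latency, REM latency), each NaN when undefined.

    NREM latency is the onset time of the first NREM episode from t = 0 (0 if
    the run starts in NREM).  REM latency is measured from that first NREM
    onset to the first REM onset at or after it; REM occurring before any
    NREM is ignored for the latency (it still counts in the other metrics).
    """
    nrem_onset = math.nan
    rem_latency = math.nan
    for ep in h.episodes:
        if math.isnan(nrem_onset):
            if ep.state == NREM:
                nrem_onset = ep.onset_s
        elif ep.state == REM:
            rem_latency = ep.onset_s - nrem_onset
            break
    return nrem_onset, rem_latency


def export_trajectory(ts: TimeSeries, marker_interval_s: float) -> pd.DataFrame:
    """Firing-rate trajectory table (time_s, F_W, F_N, F_R) with a boolean
    ``marker`` column flagging every ``marker_interval_s`` grid point, for
    external 3-D plotting of the state-space orbit."""
    step = ts.sample_dt
    ratio = marker_interval_s / step
    if marker_interval_s <= 0 or abs(ratio - round(ratio)) > 1e-6:
        raise ValueError("marker_interval_s must be a positive multiple of the stored grid step")
    every = int(round(ratio))
    marker = np.zeros(len(ts), dtype=bool)
    marker[::every] = True
    return pd.DataFrame(
        {
            "time_s": ts.times,
            "F_W": ts.F_W,
            "F_N": ts.F_N,
            "F_R": ts.F_R,
            "marker": marker,
        }
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_hypnogram(h: Hypnogram, path) -> None:
    """Run-length encoded CSV with columns state,onset_s,duration_s."""
    pd.DataFrame(h.episodes).to_csv(path, index=False)


def read_hypnogram(path, dt: float) -> Hypnogram:
    """Rebuild a hypnogram from its run-length CSV at grid step ``dt``."""
    frame = pd.read_csv(path)
    return Hypnogram.from_episodes(
        [(row.state, row.duration_s) for row in frame.itertuples()], dt
    )


def metrics_to_frame(records: Iterable[MetricsRecord]) -> pd.DataFrame:
    """One CSV-ready row per run."""
    return pd.DataFrame([r.to_row() for r in records])
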