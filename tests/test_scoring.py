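"""State classification, run-length hypnograms and architecture metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from somnet import (
    Hypnogram,
    build_hypnogram,
    classify_sample,
    compute_metrics,
    export_trajectory,
    latencies,
    make_test_timeseries,
)
from somnet.scoring import (
    Episode,
    NREM,
    REM,
    STATES,
    WAKE,
    classify_trace,
    metrics_to_frame,
    read_hypnogram,
    write_hypnogram,
)
from somnet.simulate import TimeSeries


def _hyp(labels, dt=1.0):
    code = {WAKE: 0, NREM: 1, REM: 2}
    return Hypnogram(np.array([code[s] for s in labels], dtype=np.int8), dt)


# -- classification ----------------------------------------------------------

@pytest.mark.parametrize(
    "fw,fr,expected",
    [
        (3.0, 5.0, WAKE),   # wake rule has precedence
        (1.0, 3.0, REM),
        (1.0, 1.0, NREM),
        (2.0, 2.0, NREM),   # strict '>' at both thresholds
        (2.0, 2.1, REM),
        (2.1, 0.0, WAKE),
    ],
)
def test_classifier_rule_and_precedence(fw, fr, expected):
    assert classify_sample(fw, fr) == expected


def test_classifier_rejects_negative_rates():
    with pytest.raises(ValueError):
        classify_sample(-0.1, 1.0)
    with pytest.raises(ValueError):
        classify_trace(np.array([1.0, -2.0]), np.array([0.0, 0.0]))


@settings(deadline=None, derandomize=True, max_examples=200)
@given(fw=st.floats(0, 10), fr=st.floats(0, 10))
def test_classifier_total(fw, fr):
    assert classify_sample(fw, fr) in STATES


def test_classify_trace_matches_scalar(rng):
    fw = rng.uniform(0, 5, 500)
    fr = rng.uniform(0, 5, 500)
    codes = classify_trace(fw, fr)
    scalar = [classify_sample(a, b) for a, b in zip(fw, fr)]
    assert [STATES[c] for c in codes] == scalar


# -- hypnogram construction --------------------------------------------------

def test_constant_trace_single_episode():
    ts = make_test_timeseries([(0.0, 10.0, 5.0, 0.0, 0.0)], dt=1.0)
    h = build_hypnogram(ts)
    assert h.episodes == [Episode(WAKE, 0.0, 11.0)]


def test_run_length_encoding_hand_example():
    # 6 samples at 1 s: W W N N N R
    values = np.zeros((6, 7))
    values[:, 0] = [5, 5, 0, 0, 0, 0]
    values[:, 2] = [0, 0, 0, 0, 0, 5]
    ts = TimeSeries(times=np.arange(6.0), values=values)
    h = build_hypnogram(ts)
    assert h.episodes == [
        Episode(WAKE, 0.0, 2.0),
        Episode(NREM, 2.0, 3.0),
        Episode(REM, 5.0, 1.0),
    ]


def test_episode_round_trip_idempotent(rng):
    codes = rng.integers(0, 3, 400).astype(np.int8)
    h = Hypnogram(codes, 0.5)
    rebuilt = Hypnogram.from_episodes(
        [(e.state, e.duration_s) for e in h.episodes], 0.5
    )
    assert np.array_equal(rebuilt.codes, h.codes)


def test_adjacent_episodes_differ_and_durations_sum(rng):
    codes = rng.integers(0, 3, 1000).astype(np.int8)
    h = Hypnogram(codes, 2.0)
    eps = h.episodes
    assert all(a.state != b.state for a, b in zip(eps, eps[1:]))
    assert sum(e.duration_s for e in eps) == pytest.approx(h.duration_s)


def test_empty_hypnogram_rejected():
    with pytest.raises(ValueError):
        Hypnogram(np.array([], dtype=np.int8), 1.0)


# -- metrics -----------------------------------------------------------------

def test_metrics_hand_counted_toy():
    h = _hyp([WAKE, WAKE, NREM, NREM, REM, NREM, WAKE])
    m = compute_metrics(h)
    assert m.duration_s == {WAKE: 3.0, NREM: 3.0, REM: 1.0}
    assert m.episode_count == {WAKE: 2, NREM: 2, REM: 1}
    assert m.transition_count[(WAKE, NREM)] == 1
    assert m.transition_count[(NREM, REM)] == 1
    assert m.transition_count[(REM, NREM)] == 1
    assert m.transition_count[(NREM, WAKE)] == 1
    assert m.transition_count[(WAKE, REM)] == 0
    assert m.total_transitions == m.total_episodes - 1


def test_metrics_single_state():
    m = compute_metrics(_hyp([REM] * 50))
    assert m.percent[REM] == 100.0
    assert m.episode_count == {WAKE: 0, NREM: 0, REM: 1}
    assert m.total_transitions == 0


@settings(deadline=None, derandomize=True, max_examples=50)
@given(seed=st.integers(0, 10_000), n=st.integers(1, 300))
def test_metrics_conservation_properties(seed, n):
    codes = np.random.default_rng(seed).integers(0, 3, n).astype(np.int8)
    h = Hypnogram(codes, 0.1)
    m = compute_metrics(h)
    assert sum(m.percent.values()) == pytest.approx(100.0)
    assert m.total_duration_s == pytest.approx(h.duration_s)
    assert m.total_transitions == m.total_episodes - 1


# -- latencies ---------------------------------------------------------------

def test_nrem_latency_simple():
    h = _hyp([WAKE] * 600 + [NREM] * 10)
    nrem, _ = latencies(h)
    assert nrem == 600.0


def test_rem_latency_from_first_nrem_onset():
    h = _hyp([WAKE] * 10 + [NREM] * 20 + [WAKE] * 5 + [REM] * 5)
    nrem, rem = latencies(h)
    assert nrem == 10.0
    assert rem == 25.0


def test_rem_latency_undefined_without_rem():
    _, rem = latencies(_hyp([WAKE] * 5 + [NREM] * 5))
    assert math.isnan(rem)
    nrem, rem = latencies(_hyp([WAKE] * 5))
    assert math.isnan(nrem) and math.isnan(rem)


def test_latency_zero_when_starting_asleep():
    nrem, _ = latencies(_hyp([NREM, NREM, WAKE]))
    assert nrem == 0.0


def test_rem_before_first_nrem_ignored_for_latency():
    h = _hyp([REM] * 5 + [WAKE] * 5 + [NREM] * 10 + [REM] * 5)
    nrem, rem = latencies(h)
    assert nrem == 10.0
    assert rem == 10.0
    # ...but the early episode still counts in the metrics
    assert compute_metrics(h).episode_count[REM] == 2


# -- trajectory export -------------------------------------------------------

def test_export_marks_every_interval():
    n = 1441  # 24 h at 60 s
    ts = TimeSeries(times=np.arange(n) * 60.0, values=np.zeros((n, 7)))
    table = export_trajectory(ts, marker_interval_s=1800.0)
    assert int(table["marker"].sum()) == 49  # 24*2 + 1
    assert list(table.columns) == ["time_s", "F_W", "F_N", "F_R", "marker"]


def test_export_endpoints_only():
    n = 11
    ts = TimeSeries(times=np.arange(n) * 1.0, values=np.zeros((n, 7)))
    table = export_trajectory(ts, marker_interval_s=10.0)
    assert table["marker"].tolist() == [True] + [False] * 9 + [True]


def test_export_rejects_off_grid_interval():
    ts = TimeSeries(times=np.arange(5) * 1.0, values=np.zeros((5, 7)))
    with pytest.raises(ValueError):
        export_trajectory(ts, marker_interval_s=2.5)


# -- optional episode filter and I/O ----------------------------------------

def test_minimum_duration_filter_merges_short_episodes():
    h = _hyp([WAKE] * 10 + [REM] * 1 + [NREM] * 10)
    filt = h.filtered(min_duration_s=2.0)
    assert [e.state for e in filt.episodes] == [WAKE, NREM]
    # default path applies no filter
    assert [e.state for e in h.episodes] == [WAKE, REM, NREM]


def test_hypnogram_csv_round_trip(tmp_path, rng):
    h = Hypnogram(rng.integers(0, 3, 200).astype(np.int8), 0.5)
    path = tmp_path / "hyp.csv"
    write_hypnogram(h, path)
    back = read_hypnogram(path, dt=0.5)
    assert np.array_equal(back.codes, h.codes)
    frame = pd.read_csv(path)
    assert list(frame.columns) == ["state", "onset_s", "duration_s"]


def test_metrics_frame_round_trip(tmp_path):
    m = compute_metrics(_hyp([WAKE, NREM, REM]))
    frame = metrics_to_frame([m])
    path = tmp_path / "metrics.csv"
    frame.to_csv(path, index=False)
    back = pd.read_csv(path)
    assert back.loc[0, "percent_WAKE"] == pytest.approx(m.percent[WAKE])
    assert back.loc[0, "episodes_REM"] == 1
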