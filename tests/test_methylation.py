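"""Methylation track processing: the coverage filter, CpG-index rolling
mean (against a pandas oracle), gene-body summaries and dip calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from segfuse import (
    CpGCall,
    InputError,
    ParameterError,
    aggregate_and_filter,
    detect_promoter_dip,
    gene_body_methylation,
    smooth_track,
)
from segfuse.methylation import track_from_frame


def _track(fractions, start=0, step=10, coverage=100):
    calls = [
        CpGCall(start + i * step, coverage, int(round(f * coverage)))
        for i, f in enumerate(fractions)
    ]
    return aggregate_and_filter(calls)


def test_coverage_five_discarded_six_retained():
    track = aggregate_and_filter([CpGCall(0, 5, 2), CpGCall(10, 6, 3)])
    assert list(track.positions) == [10]
    assert track.coverage[0] == 6


def test_duplicate_positions_merge_additively():
    track = aggregate_and_filter([CpGCall(7, 5, 3), CpGCall(7, 5, 2)])
    assert list(track.positions) == [7]
    assert track.coverage[0] == 10 and track.methylated[0] == 5
    assert track.fraction[0] == 0.5


def test_empty_input_gives_empty_track():
    track = aggregate_and_filter([])
    assert len(track) == 0
    assert len(smooth_track(track)) == 0


def test_filter_monotonicity():
    rng = np.random.default_rng(0)
    calls = [
        CpGCall(i, int(c), int(rng.integers(0, c + 1)))
        for i, c in enumerate(rng.poisson(8, 500))
        if c > 0
    ]
    retained = [len(aggregate_and_filter(calls, t)) for t in range(1, 15)]
    assert all(a >= b for a, b in zip(retained, retained[1:]))


def test_constant_track_invariant_under_smoothing():
    track = smooth_track(_track([0.5] * 40))
    assert np.allclose(track.smoothed, 0.5)


def test_single_spike_center_value():
    track = smooth_track(_track([0.0] * 7 + [1.0] + [0.0] * 7))
    assert track.smoothed[7] == pytest.approx(1 / 15)


def test_window_one_is_identity():
    t = _track([0.1, 0.9, 0.4, 0.7])
    s = smooth_track(t, window=1)
    assert np.allclose(s.smoothed, t.fraction, atol=1e-15)


def test_even_window_rejected():
    with pytest.raises(ParameterError):
        smooth_track(_track([0.5] * 5), window=4)


def test_smoothing_matches_pandas_rolling_oracle():
    """Centred shrunken-window rolling mean == pandas rolling(center=True,
    min_periods=1) across random track lengths and windows."""
    rng = np.random.default_rng(1)
    for _ in range(200):
        n = int(rng.integers(1, 60))
        window = int(rng.choice([1, 3, 5, 15, 31]))
        x = rng.random(n)
        track = _track(x, coverage=10**6)
        ours = smooth_track(track, window).smoothed
        oracle = (
            pd.Series(track.fraction).rolling(window, center=True, min_periods=1).mean()
        )
        assert np.allclose(ours, oracle.to_numpy(), atol=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=15, max_size=15))
def test_smoothed_center_bounded_by_window_extremes(vals):
    track = smooth_track(_track(vals, coverage=10**6))
    lo = min(track.fraction)
    hi = max(track.fraction)
    assert lo - 1e-12 <= track.smoothed[7] <= hi + 1e-12


def test_methylated_above_coverage_rejected():
    with pytest.raises(InputError):
        CpGCall(0, 3, 4)


def test_gene_body_mean_and_missing():
    track = _track([0.8] * 10, start=100, step=10)
    mean, n = gene_body_methylation(track, (100, 200))
    assert mean == pytest.approx(0.8) and n == 10
    assert gene_body_methylation(track, (5000, 6000)) == (None, 0)
    with pytest.raises(InputError):
        gene_body_methylation(track, (10, 10))


def test_all_zero_track_dip_spans_window():
    track = smooth_track(_track([0.0] * 50, start=0, step=10))
    call = detect_promoter_dip(track, tss=500, search_bp=500, paralog_id="p")
    assert call.called
    assert call.dip_start == 0 and call.min_smoothed == 0.0


def test_dip_requires_min_run():
    vals = [0.8] * 20 + [0.0] * 3 + [0.8] * 20  # too short a run
    track = smooth_track(_track(vals), window=1)
    call = detect_promoter_dip(track, tss=10 * len(vals), search_bp=10 * len(vals))
    assert not call.called


def test_dip_reports_interval_and_flank():
    vals = [0.8] * 20 + [0.05] * 10 + [0.8] * 10
    track = smooth_track(_track(vals), window=1)
    call = detect_promoter_dip(track, tss=400, search_bp=400)
    assert call.called
    assert call.dip_start == 200 and call.min_smoothed == pytest.approx(0.05)
    assert call.flank_level == pytest.approx(0.8)


def test_tss_outside_track_gives_missing_call():
    track = smooth_track(_track([0.5] * 10))
    assert detect_promoter_dip(track, tss=10_000, search_bp=100) is None


def test_unsmoothed_track_rejected_for_dip():
    with pytest.raises(InputError):
        detect_promoter_dip(_track([0.5] * 10), tss=50)


def test_track_from_frame_round_trip():
    df = pd.DataFrame(
        {"chrom": ["c"] * 3, "start": [5, 1, 9], "coverage": [10, 6, 5],
         "percent_methylated": [50.0, 100.0, 20.0]}
    )
    track = track_from_frame(df)
    assert list(track.positions) == [1, 5]  # coverage-5 site dropped, sorted
    assert list(track.methylated) == [6, 5]
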