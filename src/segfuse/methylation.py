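"""CpG methylation profiling and promoter-dip detection.

The processing chain mirrors standard long-read methylation practice:
per-CpG calls are merged and coverage-filtered (sites covered by five or
fewer reads are discarded), the methylation fraction is smoothed with a
centred rolling mean over 15 consecutive CpG sites — in CpG-index space,
not base-pair space, with shrunken windows at the edges — and an active
promoter is called as a run of consecutive smoothed values below an
absolute threshold in the window upstream of a TSS. Gene-body methylation
is the unweighted mean of retained per-CpG fractions between TSS and TTS.

The dip thresholds (0.25 absolute, run of >= 5 CpGs, 5 kb search window)
separate a hypomethylated promoter (~0.1) from a methylated background;
all three are parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .simulate import CpGCall

__all__ = [
    "MethylTrack",
    "PromoterCall",
    "aggregate_and_filter",
    "smooth_track",
    "gene_body_methylation",
    "detect_promoter_dip",
    "track_from_frame",
]

MIN_COVERAGE = 6  # sites with coverage <= 5 are discarded


@dataclass
class MethylTrack:
    """Retained CpG records, position-sorted, with raw and (optionally)
    smoothed methylation fractions."""

    positions: np.ndarray
    coverage: np.ndarray
    methylated: np.ndarray
    fraction: np.ndarray
    smoothed: np.ndarray | None = None
    window: int | None = None

    def __len__(self):
        return self.positions.size


@dataclass(frozen=True)
class PromoterCall:
    paralog_id: str
    tss: int
    called: bool
    dip_start: int | None = None
    dip_end: int | None = None
    min_smoothed: float | None = None
    flank_level: float | None = None
    n_cpgs_in_window: int = 0


def aggregate_and_filter(calls, min_coverage: int = MIN_COVERAGE) -> MethylTrack:
    """Merge duplicate positions by summing counts, then drop sites below
    the coverage floor (default: keep coverage >= 6)."""
    agg: dict[int, list[int]] = {}
    for c in calls:
        if c.methylated > c.coverage:
            raise InputError(f"methylated > coverage at {c.position}")
        rec = agg.setdefault(c.position, [0, 0])
        rec[0] += c.coverage
        rec[1] += c.methylated
    positions = np.array(sorted(agg), dtype=np.int64)
    cov = np.array([agg[p][0] for p in positions], dtype=np.int64)
    meth = np.array([agg[p][1] for p in positions], dtype=np.int64)
    keep = cov >= min_coverage
    positions, cov, meth = positions[keep], cov[keep], meth[keep]
    frac = meth / cov if cov.size else np.empty(0)
    return MethylTrack(positions, cov, meth, frac)


def _rolling_mean_shrunken(x: np.ndarray, window: int) -> np.ndarray:
    """Centred rolling mean over index space with shrunken edge windows,
    via cumulative sums."""
    n = x.size
    if n == 0:
        return x.copy()
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def smooth_track(track: MethylTrack, window: int = 15) -> MethylTrack:
    """Attach the centred rolling mean over ``window`` consecutive CpGs.

    The window counts CpG sites, not base pairs; it must be odd so the
    mean is centred. Edges use shrunken windows, preserving track length.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError("smoothing window must be odd and >= 1")
    return MethylTrack(
        track.positions,
        track.coverage,
        track.methylated,
        track.fraction,
        smoothed=_rolling_mean_shrunken(track.fraction, window),
        window=window,
    )


def gene_body_methylation(track: MethylTrack, interval) -> tuple[float | None, int]:
    """Unweighted mean retained-CpG fraction within [start, end); returns
    (mean, n_cpgs), with mean None when no retained CpG overlaps."""
    start, end = interval
    if start >= end:
        raise InputError("empty gene interval")
    sel = (track.positions >= start) & (track.positions < end)
    n = int(sel.sum())
    if n == 0:
        return None, 0
    return float(track.fraction[sel].mean()), n


def detect_promoter_dip(
    track: MethylTrack,
    tss: int,
    strand: str = "+",
    search_bp: int = 5000,
    dip_threshold: float = 0.25,
    min_run: int = 5,
    paralog_id: str = "",
) -> PromoterCall | None:
    """Call a promoter dip upstream of a TSS.

    Within ``search_bp`` upstream of the TSS (strand-aware), the call is
    positive iff there is a run of at least ``min_run`` consecutive
    smoothed values below ``dip_threshold``; the longest such run defines
    the dip interval. The flank level is the median smoothed value in the
    search window outside the run. Returns None when the window holds no
    smoothed CpGs (TSS outside the track span).
    """
    if track.smoothed is None:
        raise InputError("smooth the track before dip detection")
    if strand == "+":
        lo, hi = tss - search_bp, tss
    else:
        lo, hi = tss, tss + search_bp
    sel = np.flatnonzero((track.positions >= lo) & (track.positions < hi))
    if sel.size == 0:
        return None
    vals = track.smoothed[sel]
    below = vals < dip_threshold
    best_run = None
    i = 0
    while i < below.size:
        if below[i]:
            j = i
            while j < below.size and below[j]:
                j += 1
            if j - i >= min_run and (best_run is None or j - i > best_run[1] - best_run[0]):
                best_run = (i, j)
            i = j
        else:
            i += 1
    if best_run is None:
        return PromoterCall(paralog_id, tss, False, n_cpgs_in_window=int(sel.size))
    i, j = best_run
    outside = np.concatenate([vals[:i], vals[j:]])
    return PromoterCall(
        paralog_id,
        tss,
        True,
        dip_start=int(track.positions[sel[i]]),
        dip_end=int(track.positions[sel[j - 1]]) + 2,
        min_smoothed=float(vals[i:j].min()),
        flank_level=float(np.median(outside)) if outside.size else None,
        n_cpgs_in_window=int(sel.size),
    )


def track_from_frame(df: pd.DataFrame, min_coverage: int = MIN_COVERAGE) -> MethylTrack:
    """Build a track from a bedMethyl-style table (chrom, start, coverage,
    percent_methylated). Methylated read counts are reconstructed by
    rounding coverage * percent / 100."""
    calls = [
        CpGCall(
            int(r.start),
            int(r.coverage),
            int(getattr(r, "methylated", round(r.coverage * r.percent_methylated / 100.0))),
        )
        for r in df.itertuples(index=False)
    ]
    return aggregate_and_filter(calls, min_coverage)
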