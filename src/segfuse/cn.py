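"""Read-depth copy-number estimation against unique diploid controls.

Copy number of a region is estimated as twice the ratio of its mean
windowed depth to the mean depth of designated unique (CN=2) control
regions — the region-average normalisation used with short-read k-mer
depth profiling. The estimator is scale-invariant in the global
sequencing depth; GC correction is a deliberate no-op hook.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .simulate import DepthTrack

__all__ = ["CopyNumberEstimate", "depth_track", "estimate_cn", "estimate_all"]


@dataclass(frozen=True)
class CopyNumberEstimate:
    region: str
    mean_cn: float
    window_count: int
    control_depth: float


def depth_track(
    read_starts,
    reference_length: int,
    window_bp: int = 1000,
    chrom: str = "ref",
    region: str = "ref",
) -> DepthTrack:
    """Bin read-start positions (or k-mer hit positions) into fixed
    windows over one reference; the raw material for CN estimation."""
    if window_bp <= 0:
        raise ParameterError("window_bp must be > 0")
    starts = np.asarray(sorted(read_starts), dtype=np.int64)
    if starts.size and (starts.min() < 0 or starts.max() >= reference_length):
        raise InputError("read start outside reference")
    n_windows = (reference_length + window_bp - 1) // window_bp
    counts = np.bincount(starts // window_bp, minlength=n_windows)
    rows = [
        {
            "region": region,
            "chrom": chrom,
            "start": w * window_bp,
            "end": min((w + 1) * window_bp, reference_length),
            "count": int(c),
        }
        for w, c in enumerate(counts)
    ]
    return DepthTrack(pd.DataFrame(rows), control_regions=[])


def _region_counts(track: DepthTrack, region) -> np.ndarray:
    df = track.windows
    if isinstance(region, str):
        sel = df["region"] == region
    else:  # (chrom, start, end) interval: windows fully inside
        chrom, start, end = region
        sel = (df["chrom"] == chrom) & (df["start"] >= start) & (df["end"] <= end)
    return df.loc[sel, "count"].to_numpy()


def estimate_cn(track: DepthTrack, query, controls=None) -> CopyNumberEstimate:
    """Average copy number over ``query``: 2 x mean(query windows) /
    mean(control windows). ``query`` and each control may be a region name
    or a (chrom, start, end) interval; controls default to the track's
    designated control regions."""
    controls = controls if controls is not None else track.control_regions
    if not controls:
        raise ParameterError("at least one control region is required")
    control_counts = np.concatenate([_region_counts(track, c) for c in controls])
    if control_counts.size == 0 or control_counts.mean() == 0:
        raise InputError("control regions have no depth")
    q = _region_counts(track, query)
    if q.size == 0:
        raise InputError(f"no windows in query region {query!r}")
    control_depth = float(control_counts.mean())
    return CopyNumberEstimate(
        region=str(query),
        mean_cn=float(2.0 * q.mean() / control_depth),
        window_count=int(q.size),
        control_depth=control_depth,
    )


def estimate_all(track: DepthTrack, queries=None, controls=None) -> pd.DataFrame:
    """CN estimates for every named region (default: all non-control
    regions in the track)."""
    controls = controls if controls is not None else track.control_regions
    if queries is None:
        queries = [
            r for r in track.windows["region"].unique() if r not in set(controls)
        ]
    rows = []
    for q in queries:
        est = estimate_cn(track, q, controls)
        rows.append(
            {
                "region": est.region,
                "mean_cn": est.mean_cn,
                "window_count": est.window_count,
                "control_depth": est.control_depth,
            }
        )
    return pd.DataFrame(rows)
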