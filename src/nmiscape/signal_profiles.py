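"""Aggregate-signal machinery: point-centred profiles, length-ranked
interval heatmaps and gene-scaled metagene profiles.

All three produce per-row bin means of a coverage track.  Windows clipped
at chromosome edges carry NaN in the out-of-bounds bins, and column means
ignore NaNs, so edge rows contribute only where they have data.  Body
rescaling in the metagene is area-preserving (mean over fractional bins of
the cumulative signal) rather than nearest-position sampling, which is
unbiased for genes shorter than the bin count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import CoverageTrack, GeneModel, GenomicInterval, IntervalSet

TssPoint = Tuple[str, int, str]


@dataclass
class AverageProfile:
    mean_signal: np.ndarray
    n_rows: int
    bin_scheme: str


@dataclass
class ProfileMatrix:
    values: np.ndarray           # rows x bins, NaN where clipped
    row_metadata: pd.DataFrame   # one row per matrix row
    bin_scheme: str
    n_dropped: int = 0

    def average(self) -> AverageProfile:
        with np.errstate(invalid="ignore"):
            means = np.nanmean(self.values, axis=0) if len(self.values) \
                else np.zeros(self.values.shape[1])
        return AverageProfile(means, len(self.values), self.bin_scheme)


def _window_bins(track: CoverageTrack, chrom: str, start: int, end: int,
                 n_bins: int) -> np.ndarray:
    """Bin means over [start, end); out-of-chromosome bins are NaN."""
    L = track.chrom_sizes[chrom]
    width = end - start
    edges = start + np.round(np.linspace(0, width, n_bins + 1)).astype(int)
    vals = np.full(n_bins, np.nan)
    clipped0, clipped1 = max(0, start), min(L, end)
    if clipped1 <= clipped0:
        return vals
    per_base = track.values(chrom, clipped0, clipped1)
    pref = np.concatenate(([0.0], np.cumsum(per_base)))
    for i in range(n_bins):
        a, b = max(edges[i], 0), min(edges[i + 1], L)
        if b > a:
            vals[i] = (pref[b - clipped0] - pref[a - clipped0]) / (b - a)
    return vals


def point_profile(track: CoverageTrack, points: Sequence[TssPoint],
                  width: int = 6000, n_bins: int = 120,
                  orient_by_strand: bool = True) -> ProfileMatrix:
    """Signal matrix over fixed windows centred on points (e.g. TSSs).

    Rows of minus-strand points are reversed when ``orient_by_strand`` so
    bin 0 is always 5' of the point; points lying off their chromosome are
    dropped with a count recorded on the result.
    """
    if width % n_bins:
        raise ValueError("width must be divisible by n_bins")
    rows: List[np.ndarray] = []
    meta = []
    dropped = 0
    for chrom, pos, strand in points:
        if chrom not in track.chrom_sizes \
                or not (0 <= pos < track.chrom_sizes[chrom]):
            dropped += 1
            continue
        vals = _window_bins(track, chrom, pos - width // 2,
                            pos + width // 2, n_bins)
        if orient_by_strand and strand == "-":
            vals = vals[::-1]
        rows.append(vals)
        meta.append((chrom, pos, strand))
    values = np.array(rows) if rows else np.empty((0, n_bins))
    return ProfileMatrix(values,
                         pd.DataFrame(meta, columns=["chrom", "pos", "strand"]),
                         f"fixed_window({width},{n_bins})", dropped)


def interval_heatmap(track: CoverageTrack, intervals: IntervalSet,
                     classes: Optional[Sequence[str]] = None,
                     width: int = 5000, n_bins: int = 100) -> ProfileMatrix:
    """Midpoint-centred heatmap matrix, rows grouped by class then ranked
    by descending interval length (ties by (chrom, start))."""
    if classes is None:
        classes = ["all"] * len(intervals)
    if len(classes) != len(intervals):
        raise ValueError("one class label per interval required")
    order = sorted(range(len(intervals.intervals)),
                   key=lambda i: (classes[i],
                                  -intervals.intervals[i].length,
                                  intervals.intervals[i].sort_key()))
    rows = []
    meta = []
    for i in order:
        iv = intervals.intervals[i]
        mid = iv.midpoint
        rows.append(_window_bins(track, iv.chrom, mid - width // 2,
                                 mid + width // 2, n_bins))
        meta.append((iv.chrom, iv.start, iv.end, iv.length, classes[i]))
    values = np.array(rows) if rows else np.empty((0, n_bins))
    return ProfileMatrix(values,
                         pd.DataFrame(meta, columns=["chrom", "start", "end",
                                                     "length", "class"]),
                         f"fixed_window({width},{n_bins})")


def _resample_region(track: CoverageTrack, chrom: str, start: float,
                     end: float, n_bins: int) -> np.ndarray:
    """Area-preserving resampling of [start, end) into ``n_bins`` means;
    fractional and out-of-bounds edges handled (NaN when fully outside)."""
    L = track.chrom_sizes[chrom]
    lo = int(np.floor(max(0.0, start)))
    hi = int(np.ceil(min(float(L), end)))
    out = np.full(n_bins, np.nan)
    if hi <= lo:
        return out
    per_base = track.values(chrom, lo, hi)
    pref = np.concatenate(([0.0], np.cumsum(per_base)))

    def cum(x: float) -> float:  # linear interpolation of the prefix sum
        x = min(max(x, float(lo)), float(hi))
        return float(np.interp(x - lo, np.arange(hi - lo + 1), pref))

    edges = np.linspace(start, end, n_bins + 1)
    for i in range(n_bins):
        a, b = edges[i], edges[i + 1]
        a_c, b_c = max(a, 0.0), min(b, float(L))
        if b_c - a_c <= 0:
            continue
        out[i] = (cum(b_c) - cum(a_c)) / (b_c - a_c)
    return out


def metagene_profile(track: CoverageTrack, genes: Sequence[GeneModel],
                     n_body_bins: int = 100, flank_gene_lengths: float = 1,
                     n_flank_bins: int = 100,
                     return_matrix: bool = False):
    """Gene-scaled average profile: each body rescaled to ``n_body_bins``,
    each flank of ``flank_gene_lengths`` gene lengths rescaled to
    ``n_flank_bins``; minus-strand genes reversed so the profile runs
    5' -> 3'.  Flank bins beyond the chromosome are excluded from means."""
    total_bins = n_body_bins + 2 * n_flank_bins
    rows = []
    for g in genes:
        flank = flank_gene_lengths * g.length
        left = _resample_region(track, g.chrom, g.start - flank, g.start,
                                n_flank_bins)
        body = _resample_region(track, g.chrom, g.start, g.end, n_body_bins)
        right = _resample_region(track, g.chrom, g.end, g.end + flank,
                                 n_flank_bins)
        row = np.concatenate([left, body, right])
        if g.strand == "-":
            row = row[::-1]
        rows.append(row)
    values = np.array(rows) if rows else np.empty((0, total_bins))
    matrix = ProfileMatrix(
        values,
        pd.DataFrame([(g.gene_id, g.length) for g in genes],
                     columns=["gene_id", "length"]),
        f"scaled_gene({n_body_bins},{flank_gene_lengths},{n_flank_bins})")
    return matrix if return_matrix else matrix.average()


def write_profile_matrix(matrix: ProfileMatrix, path: str) -> None:
    df = pd.concat([matrix.row_metadata.reset_index(drop=True),
                    pd.DataFrame(matrix.values,
                                 columns=[f"bin{i}" for i in
                                          range(matrix.values.shape[1])])],
                   axis=1)
    df.to_csv(path, sep="\t", index=False)


def write_average_profile(profile: AverageProfile, path: str) -> None:
    pd.DataFrame({"bin": np.arange(len(profile.mean_signal)),
                  "mean_signal": profile.mean_signal}).to_csv(
        path, sep="\t", index=False)
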