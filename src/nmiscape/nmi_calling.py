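"""Non-methylated island calling from sample/input coverage.

A fully specified, windowed Poisson enrichment test stands in for a
general-purpose ChIP peak caller: Bio-CAP enrichment has no strand-shift
structure, so no fragment-model building is performed (an mfold model
range has no analogue here and is deliberately not implemented).  Sliding
windows of ``bandwidth`` bp (step ``bandwidth/2``) are tested against the
larger of the scaled local input expectation and the genome-wide sample
rate; p-values are Poisson upper tails, corrected genome-wide by
Benjamini-Hochberg, and windows passing the q-value and fold-enrichment
filters are merged into islands whose statistics are recomputed on the
merged interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .io_formats import CoverageTrack, GenomicInterval, IntervalSet

logger = logging.getLogger("nmiscape")


@dataclass
class CallerConfig:
    """Windowed enrichment-caller parameters."""
    bandwidth: int = 300
    q_threshold: float = 0.01
    min_fold: float = 2.0
    merge_gap: Optional[int] = None      # default: bandwidth
    input_scale: Optional[float] = None  # default: total sample / total input

    def __post_init__(self) -> None:
        if self.bandwidth < 1:
            raise ValueError("bandwidth must be >= 1")
        if not (0 < self.q_threshold < 1):
            raise ValueError("q_threshold must be in (0, 1)")

    @property
    def gap(self) -> int:
        return self.bandwidth if self.merge_gap is None else self.merge_gap


@dataclass
class PeakCall:
    """One called island with its enrichment statistics (absent for peaks
    loaded from an external BED)."""
    interval: GenomicInterval
    sample_reads: Optional[float] = None
    expected_reads: Optional[float] = None
    fold_enrichment: Optional[float] = None
    p_value: Optional[float] = None
    q_value: Optional[float] = None


def _track_reads(track: CoverageTrack, read_length: int) -> float:
    if track.total_reads > 0:
        return track.total_reads
    return track.total_area() / read_length


def _bh_step_up(p: np.ndarray, m: Optional[int] = None) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; ``m`` overrides the test count
    (used when adjusting a subset of a larger test family)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    if n == 0:
        return p.copy()
    m = n if m is None else max(m, n)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_nmis(sample: CoverageTrack, control: CoverageTrack,
              config: Optional[CallerConfig] = None,
              read_length: int = 51) -> List[PeakCall]:
    """Call enriched islands from a sample track against its matched input.

    Returns peaks sorted by (chrom, start).  With a zero-read input the
    caller falls back to the genome-wide uniform expectation with a
    warning; mismatched chromosome sets raise.
    """
    config = config or CallerConfig()
    if set(sample.data) != set(control.data) \
            or sample.bin_width != control.bin_width:
        raise ValueError("sample and input tracks must share chromosomes "
                         "and bin width")
    bw = config.bandwidth
    step = max(1, bw // 2)
    genome_len = sum(sample.chrom_sizes.values())
    total_sample = _track_reads(sample, read_length)
    total_input = _track_reads(control, read_length)
    if total_input <= 0:
        logger.warning("input track has zero reads; using genome-wide "
                       "uniform expectation")
        scale = 1.0
    else:
        scale = (config.input_scale if config.input_scale is not None
                 else total_sample / total_input)
    genome_rate = total_sample / genome_len  # sample reads per bp

    chroms: List[str] = []
    starts_all: List[np.ndarray] = []
    obs_all: List[np.ndarray] = []
    lam_all: List[np.ndarray] = []
    for chrom in sorted(sample.data):
        L = sample.chrom_sizes[chrom]
        if L < bw:
            continue
        s_pref = np.concatenate(([0.0], np.cumsum(sample.values(chrom, 0, L))))
        i_pref = np.concatenate(([0.0], np.cumsum(control.values(chrom, 0, L))))
        starts = np.arange(0, L - bw + 1, step)
        obs = np.rint((s_pref[starts + bw] - s_pref[starts])
                      / read_length).astype(int)
        if total_input > 0:
            local = (i_pref[starts + bw] - i_pref[starts]) \
                / read_length * scale
        else:
            local = np.zeros(len(starts))
        lam = np.maximum(local, genome_rate * bw)
        chroms.append(chrom)
        starts_all.append(starts)
        obs_all.append(obs)
        lam_all.append(lam)
    if not obs_all:
        return []

    obs_cat = np.concatenate(obs_all)
    lam_cat = np.concatenate(lam_all)
    with np.errstate(divide="ignore"):
        p_cat = stats.poisson.sf(obs_cat - 1, lam_cat)
    p_cat[obs_cat == 0] = 1.0
    q_cat = _bh_step_up(p_cat)
    n_windows = len(p_cat)

    fold_cat = np.divide(obs_cat, lam_cat,
                         out=np.zeros_like(lam_cat), where=lam_cat > 0)
    keep = (q_cat <= config.q_threshold) & (fold_cat >= config.min_fold)

    # merge significant windows into candidate islands per chromosome
    peaks: List[PeakCall] = []
    offset = 0
    candidate: List[Tuple[str, int, int]] = []
    for chrom, starts in zip(chroms, starts_all):
        n = len(starts)
        sel = keep[offset:offset + n]
        offset += n
        for s in starts[sel]:
            candidate.append((chrom, int(s), int(s) + bw))
    merged = IntervalSet([GenomicInterval(c, s, e) for c, s, e in candidate]) \
        .merge(gap=config.gap)

    p_peaks: List[float] = []
    for iv in merged.sorted():
        area = sample.area(iv.chrom, iv.start, iv.end)
        obs = int(round(area / read_length))
        local = control.area(iv.chrom, iv.start, iv.end) / read_length * scale
        lam = max(local if total_input > 0 else 0.0,
                  genome_rate * iv.length)
        p = float(stats.poisson.sf(obs - 1, lam)) if obs > 0 else 1.0
        fold = obs / lam if lam > 0 else 0.0
        peaks.append(PeakCall(GenomicInterval(iv.chrom, iv.start, iv.end,
                                              ".", f"NMI_{iv.chrom}_{iv.start}"),
                              obs, lam, fold, p, None))
        p_peaks.append(p)
    if peaks:
        q_peaks = _bh_step_up(np.array(p_peaks), m=n_windows)
        for pk, q in zip(peaks, q_peaks):
            pk.q_value = float(max(q, pk.p_value))
    peaks.sort(key=lambda pk: pk.interval.sort_key())
    return peaks


def load_external_nmis(path: str) -> List[PeakCall]:
    """Load peaks from BED (e.g. an external caller's output) as
    statistic-less :class:`PeakCall` records; overlapping intervals are
    merged with a reported count."""
    from .io_formats import read_bed
    raw = read_bed(path)
    merged = raw.merge()
    if len(merged) < len(raw):
        logger.info("merged %d overlapping input intervals into %d peaks",
                    len(raw), len(merged))
    return [PeakCall(iv) for iv in merged.sorted()]


def peaks_to_intervals(peaks: Sequence[PeakCall],
                       genome_id: str = "genome") -> IntervalSet:
    return IntervalSet([p.interval for p in peaks], genome_id)


def write_peaks_bed(peaks: Sequence[PeakCall], path: str) -> None:
    """BED6 with score = -10*log10(q), capped at 1000."""
    with open(path, "w") as fh:
        for pk in sorted(peaks, key=lambda p: p.interval.sort_key()):
            iv = pk.interval
            if pk.q_value is None or pk.q_value <= 0:
                score = 1000.0 if pk.q_value == 0 else 0.0
            else:
                score = min(1000.0, -10.0 * math.log10(pk.q_value))
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                     f"{score:.4g}\t{iv.strand}\n")


def write_peaks_tsv(peaks: Sequence[PeakCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tsample_reads\texpected_reads\t"
                 "fold_enrichment\tp_value\tq_value\n")
        for pk in sorted(peaks, key=lambda p: p.interval.sort_key()):
            iv = pk.interval
            fmt = lambda v: "NA" if v is None else f"{v:.6g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                     f"{fmt(pk.sample_reads)}\t{fmt(pk.expected_reads)}\t"
                     f"{fmt(pk.fold_enrichment)}\t{fmt(pk.p_value)}\t"
                     f"{fmt(pk.q_value)}\n")


def evaluate_calls(called: IntervalSet, truth: IntervalSet
                   ) -> Dict[str, float]:
    """Recall/precision of called vs planted intervals at >= 1 bp overlap."""
    if len(truth) == 0:
        return {"recall": float("nan"),
                "precision": float("nan") if len(called) == 0 else 0.0,
                "n_called": float(len(called)), "n_truth": 0.0}
    recall_hits = sum(1 for iv in truth
                      if called.overlaps_interval(iv.chrom, iv.start, iv.end))
    prec_hits = sum(1 for iv in called
                    if truth.overlaps_interval(iv.chrom, iv.start, iv.end))
    recall = recall_hits / len(truth)
    precision = prec_hits / len(called) if len(called) else 0.0
    return {"recall": recall, "precision": precision,
            "n_called": float(len(called)), "n_truth": float(len(truth))}
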