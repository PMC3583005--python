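"""CpG-island prediction and per-interval nucleotide statistics.

Implements the classic composition statistics for non-methylated DNA work:
GC content and the CpG observed/expected ratio

    CpG O/E = (N_CpG * L) / (N_C * N_G)

computed per interval together with a matched control region a fixed
distance upstream, plus a sliding-window CpG-island (CGI) predictor with
the classic thresholds (GC >= 0.5, O/E >= 0.6, length >= 200) as fully
configurable defaults.

Conventions: ambiguous (N) bases are excluded from the counted length and
from all counts; a CpG split across an interval edge is not counted; CpG
counting is strand-agnostic (the dinucleotide is its own reverse
complement).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .io_formats import GenomicInterval, IntervalSet

SequenceSource = Union[Dict[str, str], "object"]  # dict or pyfaidx.Fasta


def _fetch(sequences: SequenceSource, chrom: str, start: int, end: int) -> str:
    if isinstance(sequences, dict):
        return sequences[chrom][start:end]
    return str(sequences[chrom][start:end])  # pyfaidx.Fasta / FastaRecord


def _chrom_length(sequences: SequenceSource, chrom: str) -> int:
    return len(sequences[chrom])


@dataclass(frozen=True)
class BaseCounts:
    """Raw composition counts for one sequence stretch."""
    length: int        # non-ambiguous bases
    n_c: int
    n_g: int
    n_cpg: int

    @property
    def gc_content(self) -> float:
        return (self.n_c + self.n_g) / self.length if self.length else 0.0

    @property
    def cpg_oe(self) -> float:
        denom = self.n_c * self.n_g
        if denom == 0:
            return 0.0
        return self.n_cpg * self.length / denom


def count_bases(seq: str) -> BaseCounts:
    """Count C, G and CpG in ``seq`` excluding ambiguous bases.

    The counted length is the number of A/C/G/T bases; a CpG is counted
    when a C is immediately followed by a G within the sequence.
    """
    s = seq.upper()
    n_c = s.count("C")
    n_g = s.count("G")
    n_cpg = s.count("CG")
    length = sum(s.count(b) for b in "ACGT")
    return BaseCounts(length, n_c, n_g, n_cpg)


@dataclass
class NucleotideStats:
    """Composition of one interval and (optionally) its matched control."""
    interval: GenomicInterval
    length: int
    n_c: int
    n_g: int
    n_cpg: int
    gc_content: float
    cpg_oe: float
    control: Optional["NucleotideStats"] = None


@dataclass
class CgiParams:
    """Sliding-window CGI predictor thresholds (classic defaults)."""
    min_gc: float = 0.50
    min_oe: float = 0.60
    min_length: int = 200
    window: int = 200
    step: int = 1

    def __post_init__(self) -> None:
        if self.min_length < self.window:
            raise ValueError("min_length must be >= window")
        if not (0 < self.min_gc <= 1):
            raise ValueError("min_gc must be in (0, 1]")
        if self.min_oe <= 0:
            raise ValueError("min_oe must be > 0")
        if self.window < 2 or self.step < 1:
            raise ValueError("window >= 2 and step >= 1 required")


def interval_stats(sequences: SequenceSource, intervals: IntervalSet,
                   control_offset: int = 10_000) -> List[NucleotideStats]:
    """Composition stats per interval plus a same-size upstream control.

    The control region is ``[start - offset - L, start - offset)`` for an
    interval of length ``L``; controls that would underrun position 0 are
    flagged absent rather than shifted.
    """
    out: List[NucleotideStats] = []
    for iv in intervals:
        clen = _chrom_length(sequences, iv.chrom)
        if iv.end > clen:
            raise ValueError(f"interval {iv.chrom}:{iv.start}-{iv.end} "
                             f"beyond chromosome end ({clen})")
        bc = count_bases(_fetch(sequences, iv.chrom, iv.start, iv.end))
        stats = NucleotideStats(iv, bc.length, bc.n_c, bc.n_g, bc.n_cpg,
                                bc.gc_content, bc.cpg_oe)
        ctrl_start = iv.start - control_offset - iv.length
        if ctrl_start >= 0:
            cbc = count_bases(_fetch(sequences, iv.chrom, ctrl_start,
                                     ctrl_start + iv.length))
            civ = GenomicInterval(iv.chrom, ctrl_start, ctrl_start + iv.length)
            stats.control = NucleotideStats(civ, cbc.length, cbc.n_c, cbc.n_g,
                                            cbc.n_cpg, cbc.gc_content,
                                            cbc.cpg_oe)
        out.append(stats)
    return out


def _prefix_arrays(seq: str) -> Tuple[np.ndarray, ...]:
    s = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    is_c = s == ord("C")
    is_g = s == ord("G")
    is_acgt = is_c | is_g | (s == ord("A")) | (s == ord("T"))
    is_cpg = np.zeros(len(s), dtype=bool)
    if len(s) > 1:
        is_cpg[:-1] = is_c[:-1] & is_g[1:]
    cat = lambda a: np.concatenate(([0], np.cumsum(a)))
    return cat(is_acgt), cat(is_c), cat(is_g), cat(is_cpg)


def predict_cgis(sequences: SequenceSource, params: Optional[CgiParams] = None,
                 chroms: Optional[Sequence[str]] = None,
                 genome_id: str = "genome") -> IntervalSet:
    """Predict CpG islands by the merged-qualifying-window criterion.

    Every length-``window`` subwindow (at ``step`` spacing) passing both
    thresholds contributes its footprint; maximal runs of the union that
    are >= ``min_length`` bp and whose whole-run GC and O/E also pass both
    thresholds are reported.  Deterministic for a given sequence.
    """
    params = params or CgiParams()
    if chroms is None:
        chroms = (list(sequences) if isinstance(sequences, dict)
                  else list(sequences.keys()))
    islands: List[GenomicInterval] = []
    w = params.window
    for chrom in chroms:
        n = _chrom_length(sequences, chrom)
        if n < w:
            continue
        seq = _fetch(sequences, chrom, 0, n)
        prefix = _prefix_arrays(seq)
        acgt, c, g, cpg = prefix
        starts = np.arange(0, n - w + 1, params.step)
        length = acgt[starts + w] - acgt[starts]
        n_c = c[starts + w] - c[starts]
        n_g = g[starts + w] - g[starts]
        n_cpg = cpg[starts + w - 1] - cpg[starts]
        with np.errstate(divide="ignore", invalid="ignore"):
            gc = np.where(length > 0, (n_c + n_g) / np.maximum(length, 1), 0.0)
            denom = n_c * n_g
            oe = np.where(denom > 0, n_cpg * length / np.maximum(denom, 1), 0.0)
        ok = (gc >= params.min_gc) & (oe >= params.min_oe) & (length > 0)
        qstarts = starts[ok]
        if not len(qstarts):
            continue
        # union of [s, s+w) footprints -> maximal runs
        breaks = np.flatnonzero(np.diff(qstarts) > w)
        run_first = np.concatenate(([0], breaks + 1))
        run_last = np.concatenate((breaks, [len(qstarts) - 1]))
        for i, j in zip(run_first, run_last):
            s0, e0 = int(qstarts[i]), int(qstarts[j]) + w
            if e0 - s0 < params.min_length:
                continue
            bc = count_bases(seq[s0:e0])
            if bc.gc_content >= params.min_gc and bc.cpg_oe >= params.min_oe:
                islands.append(GenomicInterval(chrom, s0, e0, ".",
                                               f"CGI_{chrom}_{s0}"))
    return IntervalSet(islands, genome_id)


@dataclass(frozen=True)
class VennResult:
    """Element-wise and base-pair overlap between two interval sets."""
    a_only: int
    b_only: int
    overlapping: Tuple[int, int]   # (a intervals hitting b, b intervals hitting a)
    jaccard_bp: float


def overlap_venn(a: IntervalSet, b: IntervalSet) -> VennResult:
    """Two-way Venn counts (>= 1 bp overlap) plus base-pair Jaccard."""
    a_hits = sum(1 for iv in a if b.overlaps_interval(iv.chrom, iv.start, iv.end))
    b_hits = sum(1 for iv in b if a.overlaps_interval(iv.chrom, iv.start, iv.end))
    inter_bp = sum(b.overlap_bp(iv.chrom, iv.start, iv.end) for iv in a.merge())
    union_bp = a.total_bp() + b.total_bp() - inter_bp
    jac = inter_bp / union_bp if union_bp else 1.0
    return VennResult(len(a) - a_hits, len(b) - b_hits, (a_hits, b_hits), jac)
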