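"""Hierarchical genomic localisation of NMIs and TSS-overlap statistics.

Every NMI is assigned exactly one gene-relative category by a strict,
category-level hierarchy across all protein-coding genes:

    tss  >  gene_body  >  upstream/downstream (5-kb flank)  >  intergenic

where ``tss`` means >= 1 bp overlap with a window extending ``tss_window``
bp up- and downstream of a TSS.  Intergenic NMIs (> 5 kb from any
protein-coding gene by construction of the hierarchy) are then
sub-classified against regulatory annotation sets in a fixed priority
order: lncRNA TSSs, other non-coding RNA TSSs, other TSSs (pseudogenes and
processed transcripts), H3K4me1 enhancer peaks, novel RNA-seq TSSs, else
unexplained.  A randomization test provides overlap significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .io_formats import GeneModel, GenomicInterval, IntervalSet

GENE_CATEGORIES = ("tss", "gene_body", "upstream", "downstream", "intergenic")
INTERGENIC_CATEGORIES = ("lncRNA_tss", "other_ncRNA_tss", "other_tss",
                         "enhancer_H3K4me1", "novel_rnaseq_tss",
                         "unexplained", "not_applicable")


@dataclass
class AnnotationRecord:
    interval: GenomicInterval
    gene_category: str
    intergenic_category: str = "not_applicable"
    assigned_gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.gene_category not in GENE_CATEGORIES:
            raise ValueError(f"bad gene_category {self.gene_category!r}")
        if self.intergenic_category not in INTERGENIC_CATEGORIES:
            raise ValueError(
                f"bad intergenic_category {self.intergenic_category!r}")


@dataclass
class TssOverlapSummary:
    tss_total: int
    tss_with_nmi: int

    @property
    def fraction(self) -> float:
        return self.tss_with_nmi / self.tss_total if self.tss_total else 0.0


def tss_window_interval(chrom: str, tss: int, window: int) -> Tuple[int, int]:
    """Half-open span of the +-/- ``window`` bp promoter window around a
    TSS base (the window includes the TSS base itself)."""
    return max(0, tss - window), tss + window + 1


def _overlap(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def annotate_gene_relative(nmis: IntervalSet, genes: Sequence[GeneModel],
                           tss_window: int = 1000, flank: int = 5000,
                           stranded: bool = True) -> List[AnnotationRecord]:
    """Assign one gene-relative category per NMI (strict hierarchy across
    all protein-coding genes; nearest-TSS midpoint tie-break)."""
    pc = [g for g in genes if g.biotype == "protein_coding"]
    records: List[AnnotationRecord] = []
    for iv in nmis:
        hits: Dict[str, List[GeneModel]] = {c: [] for c in GENE_CATEGORIES}
        for g in pc:
            if g.chrom != iv.chrom:
                continue
            w0, w1 = tss_window_interval(g.chrom, g.tss, tss_window)
            if _overlap(iv.start, iv.end, w0, w1):
                hits["tss"].append(g)
            elif _overlap(iv.start, iv.end, g.start, g.end):
                hits["gene_body"].append(g)
            else:
                if stranded:
                    up = (g.start - flank, g.start) if g.strand == "+" \
                        else (g.end, g.end + flank)
                    down = (g.end, g.end + flank) if g.strand == "+" \
                        else (g.start - flank, g.start)
                else:
                    up = (g.start - flank, g.start)
                    down = (g.end, g.end + flank)
                if _overlap(iv.start, iv.end, max(0, up[0]), up[1]):
                    hits["upstream"].append(g)
                if _overlap(iv.start, iv.end, max(0, down[0]), down[1]):
                    hits["downstream"].append(g)
        category = "intergenic"
        winner: Optional[GeneModel] = None
        for cat in ("tss", "gene_body", "upstream", "downstream"):
            if hits[cat]:
                category = cat
                winner = min(hits[cat],
                             key=lambda g: (abs(iv.midpoint - g.tss),
                                            g.gene_id))
                break
        records.append(AnnotationRecord(
            iv, category,
            "unexplained" if category == "intergenic" else "not_applicable",
            winner.gene_id if winner else None))
    return records


def _expanded_overlap(iset: IntervalSet, iv: GenomicInterval,
                      pad: int) -> bool:
    return iset.overlaps_interval(iv.chrom, iv.start - pad, iv.end + pad)


def annotate_intergenic(records: List[AnnotationRecord],
                        lnc_tss: IntervalSet, ncrna_tss: IntervalSet,
                        other_tss: IntervalSet, h3k4me1: IntervalSet,
                        novel_tss: IntervalSet,
                        tss_window: int = 1000) -> List[AnnotationRecord]:
    """Sub-classify intergenic NMIs in the fixed priority order; TSS sets
    use +- ``tss_window`` windows, H3K4me1 uses raw >= 1 bp peak overlap.
    Records are updated in place and returned."""
    tiers = (("lncRNA_tss", lnc_tss, tss_window),
             ("other_ncRNA_tss", ncrna_tss, tss_window),
             ("other_tss", other_tss, tss_window),
             ("enhancer_H3K4me1", h3k4me1, 0),
             ("novel_rnaseq_tss", novel_tss, tss_window))
    for rec in records:
        if rec.gene_category != "intergenic":
            continue
        rec.intergenic_category = "unexplained"
        for name, iset, pad in tiers:
            if _expanded_overlap(iset, rec.interval, pad):
                rec.intergenic_category = name
                break
    return records


def category_counts(records: Sequence[AnnotationRecord]) -> Dict[str, Dict[str, int]]:
    """Category tallies (Fig-4-style pie data): every NMI lands in exactly
    one gene-relative bin, intergenic NMIs additionally in one sub-bin."""
    gene_counts = {c: 0 for c in GENE_CATEGORIES}
    inter_counts = {c: 0 for c in INTERGENIC_CATEGORIES if c != "not_applicable"}
    for rec in records:
        gene_counts[rec.gene_category] += 1
        if rec.gene_category == "intergenic":
            inter_counts[rec.intergenic_category] += 1
    return {"gene_relative": gene_counts, "intergenic": inter_counts}


TssPoint = Tuple[str, int, str]  # chrom, position, strand


def gene_tss_points(genes: Iterable[GeneModel]) -> List[TssPoint]:
    return [(g.chrom, g.tss, g.strand) for g in genes]


def tss_overlap(nmis: IntervalSet, tss_points: Sequence[TssPoint],
                window: int = 1000) -> TssOverlapSummary:
    """Fraction of TSSs whose +-``window`` promoter window touches an NMI."""
    hit = 0
    for chrom, pos, _strand in tss_points:
        w0, w1 = tss_window_interval(chrom, pos, window)
        if nmis.overlaps_interval(chrom, w0, w1):
            hit += 1
    return TssOverlapSummary(len(tss_points), hit)


def tss_overlap_by_set(nmis: IntervalSet,
                       tss_sets: Dict[str, Sequence[TssPoint]],
                       window: int = 1000) -> Dict[str, TssOverlapSummary]:
    """Per-set summaries plus one for the union of all sets (a TSS present
    in several sets counts once in the union)."""
    out = {name: tss_overlap(nmis, pts, window)
           for name, pts in tss_sets.items()}
    union = sorted({pt for pts in tss_sets.values() for pt in pts})
    out["union"] = tss_overlap(nmis, union, window)
    return out


def gene_tss_nmi_status(genes: Iterable[GeneModel], nmis: IntervalSet,
                        window: int = 1000) -> Dict[str, bool]:
    """Per-gene boolean: does an NMI touch the +-``window`` TSS window?
    (the status map consumed by the conservation module)."""
    status: Dict[str, bool] = {}
    for g in genes:
        w0, w1 = tss_window_interval(g.chrom, g.tss, window)
        status[g.gene_id] = nmis.overlaps_interval(g.chrom, w0, w1)
    return status


@dataclass
class RandomizationResult:
    observed: int
    null_mean: float
    empirical_p: float
    fold: float
    n_perm: int
    null_counts: np.ndarray = field(repr=False, default=None)


def overlap_randomization_test(query: IntervalSet, reference: IntervalSet,
                               workspace: Dict[str, int], n_perm: int,
                               seed: int) -> RandomizationResult:
    """Permutation overlap test: query intervals are re-placed uniformly on
    their own chromosomes (lengths preserved, overlap between placed
    intervals not forbidden) and the overlapping-interval count is compared
    with the observed one.  ``empirical_p = (1 + #{null >= obs}) /
    (n_perm + 1)``; deterministic under ``seed``.

    Note: uniform placement ignores composition structure, so for
    GC-correlated features the test is anti-conservative relative to
    isochore-matched sampling.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    observed = sum(1 for iv in query
                   if reference.overlaps_interval(iv.chrom, iv.start, iv.end))
    # merged reference endpoints per chromosome for vectorized hit tests
    ref: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom in reference.merge().chroms():
        ivs = [iv for iv in reference.merge() if iv.chrom == chrom]
        ref[chrom] = (np.array([iv.start for iv in ivs]),
                      np.array([iv.end for iv in ivs]))
    null = np.zeros(n_perm, dtype=int)
    for iv in query:
        G = workspace[iv.chrom]
        L = iv.length
        if L > G:
            raise ValueError(f"interval of length {L} longer than "
                             f"chromosome {iv.chrom} ({G} bp)")
        starts = rng.integers(0, G - L + 1, n_perm)
        if iv.chrom not in ref:
            continue
        rs, re = ref[iv.chrom]
        idx = np.searchsorted(re, starts, side="right")
        hit = (idx < len(rs)) & (rs[np.minimum(idx, len(rs) - 1)] < starts + L)
        null += hit
    null_mean = float(null.mean())
    emp_p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    fold = observed / null_mean if null_mean > 0 else float("nan")
    return RandomizationResult(observed, null_mean, emp_p, fold, n_perm, null)
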