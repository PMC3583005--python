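"""Broad-NMI gene classification, GO enrichment and chromatin association.

Genes are classified by the fraction of their genomic span (introns
included) covered by the merged NMI footprint: ``broad`` when the fraction
strictly exceeds 0.9, ``short`` when strictly between 0 and 0.1, ``none``
at exactly 0, ``intermediate`` otherwise — the four classes partition the
gene universe.  Broad-NMI genes are tested for GO-term over-representation
with a hypergeometric upper tail (the mapping is used as given; no
true-path ancestry propagation), and for chromatin-mark association
against canonical-NMI genes (TSS NMI but not broad) with a one-sided
Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import tss_window_interval
from .io_formats import GeneModel, GenomicInterval, IntervalSet
from .nmi_calling import _bh_step_up
from .tissue_comparison import fisher_one_sided, sample_odds_ratio

COVERAGE_CLASSES = ("broad", "intermediate", "short", "none")


@dataclass
class GeneCoverage:
    gene_id: str
    gene_length: int
    covered_bp: int
    fraction: float
    coverage_class: str


def _coverage_class(fraction: float) -> str:
    if fraction > 0.9:
        return "broad"
    if fraction == 0.0:
        return "none"
    if fraction < 0.1:
        return "short"
    return "intermediate"


def gene_nmi_coverage(genes: Sequence[GeneModel],
                      nmis: IntervalSet) -> List[GeneCoverage]:
    """Exact per-base NMI coverage of every gene span, classified by the
    strict >0.9 / <0.1 thresholds."""
    merged = nmis.merge()
    out: List[GeneCoverage] = []
    for g in genes:
        covered = merged.overlap_bp(g.chrom, g.start, g.end)
        frac = covered / g.length
        out.append(GeneCoverage(g.gene_id, g.length, covered, frac,
                                _coverage_class(frac)))
    return out


@dataclass
class GoEnrichment:
    term_id: str
    term_name: str
    ontology: str
    k: int      # query genes with the term
    K: int      # universe genes with the term
    n: int      # query size
    N: int      # universe size
    p_value: float
    q_value: float

    @property
    def enrichment_score(self) -> float:
        return -np.log10(self.p_value) if self.p_value > 0 else np.inf


def go_enrichment(query: Iterable[str], universe: Iterable[str],
                  mapping: pd.DataFrame,
                  max_p: Optional[float] = None) -> List[GoEnrichment]:
    """Hypergeometric over-representation of each term among ``query``.

    ``query`` must be a subset of ``universe``; genes without any term
    still count in N.  One upper-tail p per term with k >= 1, sorted by p,
    with a BH q column; ``max_p`` is an output filter only.
    """
    query_set: Set[str] = set(query)
    universe_set: Set[str] = set(universe)
    if not query_set:
        raise ValueError("empty query gene set")
    if not query_set <= universe_set:
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe_set), len(query_set)
    rows = []
    in_universe = mapping[mapping["gene_id"].isin(universe_set)]
    for (term_id, term_name, ontology), grp in in_universe.groupby(
            ["term_id", "term_name", "ontology"]):
        genes_with = set(grp["gene_id"])
        K = len(genes_with)
        k = len(genes_with & query_set)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, term_name, ontology, k, K, p))
    if not rows:
        return []
    ps = np.array([r[5] for r in rows])
    qs = _bh_step_up(ps)
    results = [GoEnrichment(tid, tname, ont, k, K, n, N, p, float(qv))
               for (tid, tname, ont, k, K, p), qv in zip(rows, qs)]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    if max_p is not None:
        results = [r for r in results if r.p_value < max_p]
    return results


@dataclass
class ChromatinAssociation:
    table: Tuple[Tuple[int, int], Tuple[int, int]]  # [[broad a, ~a], [canon a, ~a]]
    odds_ratio: float
    p_value: float
    rate_broad: float
    rate_canonical: float


def chromatin_association(coverage: Sequence[GeneCoverage],
                          mark_peaks: IntervalSet,
                          genes: Sequence[GeneModel],
                          nmis: IntervalSet,
                          tss_window: int = 1000,
                          overlap_mode: str = "nmi_footprint"
                          ) -> ChromatinAssociation:
    """Association of a chromatin mark with broad-NMI vs canonical-NMI
    genes.

    ``canonical`` genes have an NMI within +-``tss_window`` of their TSS
    but are not in the broad coverage class.  A gene is mark-associated
    when >= 1 bp of the mark peak set overlaps its NMI footprint (the NMI
    intervals touching its span or TSS window); ``overlap_mode =
    'gene_span'`` tests the mark against the gene span instead.
    """
    cls = {c.gene_id: c.coverage_class for c in coverage}
    merged = nmis.merge()
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)

    def associated(g: GeneModel) -> bool:
        w0, w1 = tss_window_interval(g.chrom, g.tss, tss_window)
        lo, hi = min(w0, g.start), max(w1, g.end)
        if overlap_mode == "gene_span":
            return mark_peaks.overlaps_interval(g.chrom, g.start, g.end)
        for iv in by_chrom.get(g.chrom, ()):
            if iv.start < hi and lo < iv.end \
                    and mark_peaks.overlaps_interval(iv.chrom, iv.start,
                                                     iv.end):
                return True
        return False

    broad = [g for g in genes if cls.get(g.gene_id) == "broad"]
    canonical = []
    for g in genes:
        if cls.get(g.gene_id) == "broad":
            continue
        w0, w1 = tss_window_interval(g.chrom, g.tss, tss_window)
        if merged.overlaps_interval(g.chrom, w0, w1):
            canonical.append(g)
    if not broad or not canonical:
        raise ValueError("both broad and canonical gene groups must be "
                         "non-empty")
    a = sum(1 for g in broad if associated(g))
    c = sum(1 for g in canonical if associated(g))
    table = ((a, len(broad) - a), (c, len(canonical) - c))
    return ChromatinAssociation(table, sample_odds_ratio(table),
                                fisher_one_sided(table),
                                a / len(broad), c / len(canonical))


def coverage_table(coverage: Sequence[GeneCoverage]) -> pd.DataFrame:
    return pd.DataFrame([(c.gene_id, c.gene_length, c.covered_bp,
                          c.fraction, c.coverage_class) for c in coverage],
                        columns=["gene_id", "gene_length", "covered_bp",
                                 "fraction", "coverage_class"])


def go_table(results: Sequence[GoEnrichment]) -> pd.DataFrame:
    return pd.DataFrame([(r.term_id, r.term_name, r.ontology, r.k, r.K,
                          r.n, r.N, r.p_value, r.q_value,
                          r.enrichment_score) for r in results],
                        columns=["term_id", "term_name", "ontology", "k",
                                 "K", "n", "N", "p_value", "q_value",
                                 "enrichment_score"])
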