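"""Tissue comparison: shared vs tissue-unique NMIs, simplified differential
expression, and the association between tissue-specific promoter NMIs and
differential expression.

An NMI is tissue-specific (``unique``) when it overlaps no NMI called in
the other tissue (zero-bp overlap), otherwise ``shared``.  Differential
expression deliberately replaces a negative-binomial dispersion model with
an exact binomial rate test on pooled median-of-ratios-normalized counts:
this is dispersion-free and anti-conservative under overdispersion, which
the fold-change filter (|fold| > 2, on pseudocounted normalized means)
largely absorbs; an external DE results table can be supplied instead via
:func:`de_results_from_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import tss_window_interval
from .cgi_nucleotide import SequenceSource, count_bases, _fetch
from .io_formats import CountMatrix, GeneModel, IntervalSet
from .nmi_calling import _bh_step_up


@dataclass
class TissueNmiClass:
    interval: "GenomicInterval"
    tissue_of_origin: str
    status: str                  # shared | unique
    at_tss: bool
    length: int
    cpg_per_bp: float            # NaN when no sequence given


def classify_tissue_nmis(set_a: IntervalSet, set_b: IntervalSet,
                         genes: Sequence[GeneModel],
                         tissue_a: str = "testes", tissue_b: str = "liver",
                         tss_window: int = 1000,
                         sequences: Optional[SequenceSource] = None
                         ) -> List[TissueNmiClass]:
    """Label every NMI of both tissues shared/unique, TSS-associated or
    not, with length and (when sequence is available) CpG density."""
    tss_windows = IntervalSet([
        _window_iv(g, tss_window) for g in genes
        if g.biotype == "protein_coding"])
    out: List[TissueNmiClass] = []
    for own, other, tissue in ((set_a, set_b, tissue_a),
                               (set_b, set_a, tissue_b)):
        for iv in own:
            shared = other.overlaps_interval(iv.chrom, iv.start, iv.end)
            at_tss = tss_windows.overlaps_interval(iv.chrom, iv.start, iv.end)
            dens = float("nan")
            if sequences is not None:
                bc = count_bases(_fetch(sequences, iv.chrom, iv.start, iv.end))
                dens = bc.n_cpg / bc.length if bc.length else 0.0
            out.append(TissueNmiClass(iv, tissue,
                                      "shared" if shared else "unique",
                                      at_tss, iv.length, dens))
    return out


def _window_iv(g: GeneModel, window: int):
    from .io_formats import GenomicInterval
    w0, w1 = tss_window_interval(g.chrom, g.tss, window)
    return GenomicInterval(g.chrom, w0, w1, g.strand, g.gene_id)


def strata_summary(classes: Sequence[TissueNmiClass],
                   quantiles: Sequence[float] = (0.25, 0.5, 0.75)
                   ) -> pd.DataFrame:
    """Length and CpG-density quantiles for the tissue x status strata."""
    rows = []
    df = pd.DataFrame([{"tissue": c.tissue_of_origin, "status": c.status,
                        "length": c.length, "cpg_per_bp": c.cpg_per_bp}
                       for c in classes])
    if df.empty:
        return pd.DataFrame(columns=["tissue", "status", "n", "metric",
                                     *[f"q{int(q * 100)}" for q in quantiles]])
    for (tissue, status), grp in df.groupby(["tissue", "status"]):
        for metric in ("length", "cpg_per_bp"):
            qs = grp[metric].quantile(quantiles).to_list()
            rows.append([tissue, status, len(grp), metric, *qs])
    return pd.DataFrame(rows, columns=["tissue", "status", "n", "metric",
                                       *[f"q{int(q * 100)}" for q in quantiles]])


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

@dataclass
class DeResult:
    gene_id: str
    mean_expr_A: float     # log2 mean normalized expression (pseudocount 1)
    log_ratio_M: float     # log2(tissue_b / tissue_a), pseudocount 1
    p_value: float
    q_value: float
    de_flag: bool
    direction: str         # <tissue>_up | none


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors: per sample, the median ratio to the
    per-gene geometric mean over genes expressed in every sample."""
    log_counts = np.log(counts.where(counts > 0))
    log_geomean = log_counts.mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        return pd.Series(1.0, index=counts.columns)
    ratios = log_counts.loc[usable].sub(log_geomean[usable], axis=0)
    return np.exp(ratios.median(axis=0))


def differential_expression(cm: CountMatrix,
                            tissue_a: Optional[str] = None,
                            tissue_b: Optional[str] = None,
                            alpha: float = 0.05,
                            min_fold: float = 2.0) -> List[DeResult]:
    """Two-tissue DE by an exact binomial rate test on pooled normalized
    counts, BH-corrected; a gene is flagged when q < ``alpha`` and the
    pseudocounted normalized-mean ratio exceeds ``min_fold`` either way."""
    labels = cm.tissue_labels()
    if tissue_a is None or tissue_b is None:
        if len(labels) != 2:
            raise ValueError("specify tissue_a/tissue_b for >2 tissues")
        tissue_a, tissue_b = labels
    samples_a = cm.samples_for(tissue_a)
    samples_b = cm.samples_for(tissue_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need >= 2 replicates per tissue")
    sf = median_of_ratios_size_factors(cm.counts)
    norm = cm.counts / sf
    mean_a = norm[samples_a].mean(axis=1)
    mean_b = norm[samples_b].mean(axis=1)
    sum_a = norm[samples_a].sum(axis=1).round().astype(int)
    sum_b = norm[samples_b].sum(axis=1).round().astype(int)
    k = sum_b.to_numpy()
    ntot = (sum_a + sum_b).to_numpy()
    w = len(samples_b) / (len(samples_a) + len(samples_b))
    lower = stats.binom.cdf(k, ntot, w)
    upper = stats.binom.sf(k - 1, ntot, w)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    p[ntot == 0] = 1.0
    q = _bh_step_up(p)
    M = np.log2((mean_b + 1.0) / (mean_a + 1.0)).to_numpy()
    A = 0.5 * (np.log2(mean_a + 1.0) + np.log2(mean_b + 1.0)).to_numpy()
    out: List[DeResult] = []
    log_fold = np.log2(min_fold)
    for i, gid in enumerate(cm.counts.index):
        flag = bool(q[i] < alpha and abs(M[i]) > log_fold)
        direction = "none"
        if flag:
            direction = f"{tissue_b}_up" if M[i] > 0 else f"{tissue_a}_up"
        out.append(DeResult(str(gid), float(A[i]), float(M[i]),
                            float(p[i]), float(q[i]), flag, direction))
    return out


def de_results_from_table(df: pd.DataFrame, tissue_a: str, tissue_b: str,
                          alpha: float = 0.05, min_fold: float = 2.0
                          ) -> List[DeResult]:
    """Adapt an external DE table (columns gene_id, log2fc, p or q) into
    :class:`DeResult` records using the same thresholds."""
    q = df["q"] if "q" in df.columns else _bh_step_up(df["p"].to_numpy())
    out = []
    log_fold = np.log2(min_fold)
    for gid, m, qv in zip(df["gene_id"], df["log2fc"], q):
        flag = bool(qv < alpha and abs(m) > log_fold)
        direction = "none"
        if flag:
            direction = f"{tissue_b}_up" if m > 0 else f"{tissue_a}_up"
        out.append(DeResult(str(gid), float("nan"), float(m),
                            float(qv), float(qv), flag, direction))
    return out


# ---------------------------------------------------------------------------
# NMI / differential-expression association
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    odds_ratio: float
    p_value: float
    n_universe: int


def sample_odds_ratio(table) -> float:
    """(a*d)/(b*c) with Haldane 0.5 correction applied when any cell is 0."""
    (a, b), (c, d) = table
    if min(a, b, c, d) == 0:
        a, b, c, d = (v + 0.5 for v in (a, b, c, d))
    return (a * d) / (b * c)


def fisher_one_sided(table) -> float:
    """One-sided (enrichment) Fisher exact p for a 2x2 table."""
    return float(stats.fisher_exact(np.asarray(table),
                                    alternative="greater")[1])


def nmi_de_association(classes: Sequence[TissueNmiClass],
                       de: Sequence[DeResult],
                       genes: Sequence[GeneModel],
                       tss_window: int = 1000
                       ) -> Dict[str, AssociationResult]:
    """Per tissue: 2x2 association between owning a unique-in-tissue
    promoter NMI and being overexpressed in that tissue.

    The gene universe is restricted to genes with a TSS-associated NMI in
    at least one tissue.
    """
    tissues = sorted({c.tissue_of_origin for c in classes})
    per_tissue: Dict[str, IntervalSet] = {
        t: IntervalSet([c.interval for c in classes
                        if c.tissue_of_origin == t]) for t in tissues}
    unique_sets: Dict[str, IntervalSet] = {
        t: IntervalSet([c.interval for c in classes
                        if c.tissue_of_origin == t and c.status == "unique"])
        for t in tissues}
    de_by_gene = {d.gene_id: d for d in de}
    universe: List[GeneModel] = []
    for g in genes:
        if g.biotype != "protein_coding" or g.gene_id not in de_by_gene:
            continue
        w0, w1 = tss_window_interval(g.chrom, g.tss, tss_window)
        if any(per_tissue[t].overlaps_interval(g.chrom, w0, w1)
               for t in tissues):
            universe.append(g)
    if not universe:
        raise ValueError("empty gene universe: no TSS-associated NMIs")
    out: Dict[str, AssociationResult] = {}
    for t in tissues:
        a = b = c = d = 0
        for g in universe:
            w0, w1 = tss_window_interval(g.chrom, g.tss, tss_window)
            has_unique = unique_sets[t].overlaps_interval(g.chrom, w0, w1)
            over = de_by_gene[g.gene_id].direction == f"{t}_up"
            if has_unique and over:
                a += 1
            elif has_unique:
                b += 1
            elif over:
                c += 1
            else:
                d += 1
        table = ((a, b), (c, d))
        out[t] = AssociationResult(table, sample_odds_ratio(table),
                                   fisher_one_sided(table), len(universe))
    return out
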