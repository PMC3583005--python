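"""Synthetic multi-species, multi-tissue Bio-CAP datasets with ground truth.

The generator emulates the statistical structure that methylation leaves in
vertebrate genomes: densely methylated background DNA is CpG-eroded
(low CpG observed/expected), while non-methylated islands retain CpGs.
Sequences are drawn from first-order Markov chains whose transition
matrices are solved in closed form so that the stationary base composition
hits a target GC content and the expected CpG rate hits a target CpG O/E.
Into this background the simulator plants three island classes:

* ``canonical`` — centred on a gene TSS, long and CpG-dense, non-methylated
  in every tissue (a configurable fraction is made tissue-specific to
  emulate methylation-plastic promoters);
* ``broad`` — spanning the entire gene body (>90 % coverage by
  construction), the polycomb-associated class;
* ``plastic`` — short, CpG-sparser, intergenic (>= 5 kb from any gene) and
  non-methylated in exactly one tissue.

Bio-CAP enrichment sequencing is emulated by placing reads at a rate
``input_depth + capture_efficiency x (non-methylated CpGs near the
fragment)`` with negative-binomial noise; the matched input is
CpG-independent.  Expression counts, H3K4me3 tracks, H3K4me1/H3K27me3
intervals and a GO mapping with one term planted among broad-island genes
complete the dataset.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cgi_nucleotide import count_bases
from .io_formats import (CountMatrix, CoverageTrack, GeneModel,
                         GenomicInterval, IntervalSet)

BASES = "ACGT"
NON_METHYLATED = "non_methylated"
METHYLATED = "methylated"


def derive_seed(base_seed: int, *labels: object) -> int:
    """Deterministic per-stage sub-seed (< 2**31) from a global seed."""
    h = hashlib.sha256(("|".join([str(base_seed), *map(str, labels)]))
                      .encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Knobs of the synthetic genome; defaults give a 1-Mb two-species,
    two-tissue dataset with 50 planted islands (40 promoter, 10 plastic)."""

    seed: int = 0
    n_species: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 40
    background_gc: float = 0.41
    background_cpg_oe: float = 0.20
    island_gc: float = 0.60
    island_cpg_oe: float = 0.90
    island_length_range: Tuple[int, int] = (800, 2000)
    plastic_length_range: Tuple[int, int] = (300, 600)
    plastic_cpg_oe: float = 0.65
    gene_length_range: Tuple[int, int] = (2000, 6000)
    broad_fraction: float = 0.10
    plastic_count: int = 10
    tissue_specific_promoter_fraction: float = 0.15
    island_presence_rate: float = 1.0
    conservation_rate: float = 0.90
    capture_efficiency: float = 10.0
    input_depth: float = 1.0
    noise_overdispersion: float = 0.05
    read_length: int = 51
    fragment_window: int = 300
    de_fraction: float = 0.20
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    n_replicates: int = 4
    tissues: Tuple[str, ...] = ("testes", "liver")
    h3k27me3_broad_prob: float = 0.90
    h3k27me3_canonical_prob: float = 0.05
    h3k4me1_plastic_prob: float = 0.70

    def __post_init__(self) -> None:
        for name in ("background_gc", "island_gc", "broad_fraction",
                     "island_presence_rate", "conservation_rate",
                     "de_fraction", "tissue_specific_promoter_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.island_cpg_oe <= self.background_cpg_oe:
            raise ValueError("island_cpg_oe must exceed background_cpg_oe")
        if len(self.tissues) < 2:
            raise ValueError("need >= 2 tissues")

    @classmethod
    def zebrafish_mode(cls, **overrides) -> "SimulationConfig":
        """Islands keep their CpG O/E contrast but GC matches background —
        the fish-like regime where composition-based CGI prediction fails."""
        kw = dict(background_gc=0.37, island_gc=0.37,
                  background_cpg_oe=0.20, island_cpg_oe=0.90)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def chicken_mode(cls, **overrides) -> "SimulationConfig":
        """Maximal GC and CpG O/E contrast between islands and background."""
        kw = dict(background_gc=0.40, island_gc=0.65,
                  background_cpg_oe=0.20, island_cpg_oe=0.95)
        kw.update(overrides)
        return cls(**kw)


# ---------------------------------------------------------------------------
# truth ledger
# ---------------------------------------------------------------------------

@dataclass
class PlantedIsland:
    interval: GenomicInterval
    island_class: str                      # canonical | plastic | broad
    gene_id: Optional[str]
    methylation: Dict[str, str]            # tissue -> methylation state

    def non_methylated_in(self, tissue: str) -> bool:
        return self.methylation[tissue] == NON_METHYLATED


@dataclass
class SpeciesTruth:
    species_id: str
    chrom_sizes: Dict[str, int]
    genes: List[GeneModel]
    islands: List[PlantedIsland]

    def islands_of_class(self, cls: str) -> List[PlantedIsland]:
        return [i for i in self.islands if i.island_class == cls]

    def island_intervals(self, tissue: Optional[str] = None) -> IntervalSet:
        """Planted islands, optionally only those non-methylated in ``tissue``."""
        ivs = [i.interval for i in self.islands
               if tissue is None or i.non_methylated_in(tissue)]
        return IntervalSet(ivs, self.species_id)

    def promoter_island_genes(self) -> Dict[str, PlantedIsland]:
        return {i.gene_id: i for i in self.islands if i.gene_id is not None}


@dataclass
class TruthSet:
    species: Dict[str, SpeciesTruth]
    orthologues: pd.DataFrame              # one column per species, gene ids
    tissues: Tuple[str, ...]
    de_truth: Optional[pd.DataFrame] = None   # gene_id, log2fc, direction


@dataclass
class SimulatedGenome:
    sequences: Dict[str, Dict[str, str]]   # species -> chrom -> sequence
    genes: Dict[str, List[GeneModel]]
    truth: TruthSet
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Markov sequence model
# ---------------------------------------------------------------------------

def transition_matrix(gc: float, cpg_oe: float) -> np.ndarray:
    """First-order transition matrix with stationary GC ``gc`` and expected
    CpG O/E ``cpg_oe``.

    Rows/columns are A, C, G, T.  The C row fixes ``P(G|C) = oe * pi_G`` and
    spreads the remainder over A/C/T proportionally to their stationary
    probabilities; the common A/G/T row is then solved exactly from the
    stationarity equations, so the chain's stationary distribution equals
    the target composition and the expected CpG rate is ``oe*pi_C*pi_G``.
    """
    pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    pi_c, pi_g = pi[1], pi[2]
    row_c = np.empty(4)
    row_c[2] = cpg_oe * pi_g
    rest = 1.0 - row_c[2]
    for j in (0, 1, 3):
        row_c[j] = pi[j] * rest / (1.0 - pi_g)
    # common row q for states A, G, T from pi = pi P
    q = (pi - pi_c * row_c) / (1.0 - pi_c)
    if (q < 0).any() or (row_c < 0).any():
        raise ValueError(f"infeasible composition gc={gc}, cpg_oe={cpg_oe}")
    M = np.vstack([q, row_c, q, q])
    return M


def markov_sequence(n: int, gc: float, cpg_oe: float,
                    rng: np.random.Generator) -> str:
    """Draw ``n`` bases from the tuned first-order chain."""
    M = transition_matrix(gc, cpg_oe)
    cum = np.cumsum(M, axis=1)
    pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    u = rng.random(n)
    states = np.empty(n, dtype=np.int8)
    state = int(np.searchsorted(np.cumsum(pi), u[0]))
    states[0] = state
    cum_rows = [cum[i] for i in range(4)]
    for t in range(1, n):
        row = cum_rows[state]
        ut = u[t]
        # manual 4-way branch beats searchsorted in the scalar loop
        if ut < row[0]:
            state = 0
        elif ut < row[1]:
            state = 1
        elif ut < row[2]:
            state = 2
        else:
            state = 3
        states[t] = state
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    return lut[states].tobytes().decode()


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

_JITTER = 2000
_BROAD_PAD = 200


def _layout_slots(config: SimulationConfig, rng: np.random.Generator
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Assign genes and plastic islands to evenly spaced chromosome slots."""
    n_slots = config.n_genes + config.plastic_count
    slot_w = config.chrom_length // n_slots
    needed = config.gene_length_range[1] + 2 * (_JITTER + 1000)
    if slot_w < needed:
        raise ValueError(
            f"infeasible packing: {n_slots} elements on "
            f"{config.chrom_length} bp need slots >= {needed} bp, "
            f"have {slot_w}")
    centers = slot_w // 2 + slot_w * np.arange(n_slots) \
        + rng.integers(-_JITTER, _JITTER + 1, n_slots)
    kinds = np.array(["gene"] * config.n_genes
                     + ["plastic"] * config.plastic_count)
    rng.shuffle(kinds)
    return centers, kinds


def _plant_species(species_id: str, config: SimulationConfig,
                   presence: np.ndarray, rng: np.random.Generator
                   ) -> Tuple[Dict[str, str], SpeciesTruth]:
    chrom = "chr1"
    L = config.chrom_length
    centers, kinds = _layout_slots(config, rng)
    genes: List[GeneModel] = []
    islands: List[PlantedIsland] = []
    segments: List[Tuple[int, int, float, float]] = []  # start,end,gc,oe

    gene_idx = 0
    plastic_idx = 0
    all_nm = {t: NON_METHYLATED for t in config.tissues}
    for center, kind in zip(centers, kinds):
        if kind == "gene":
            glen = int(rng.integers(*config.gene_length_range))
            strand = "+" if rng.random() < 0.5 else "-"
            start = int(center - glen // 2)
            gene = GeneModel(f"{species_id}_g{gene_idx:04d}", chrom,
                             start, start + glen, strand)
            genes.append(gene)
            has_island = bool(presence[gene_idx])
            is_broad = has_island and rng.random() < config.broad_fraction
            is_ts = (has_island and not is_broad
                     and rng.random()
                     < config.tissue_specific_promoter_fraction)
            nm_tissue = config.tissues[int(rng.integers(len(config.tissues)))]
            if has_island:
                if is_broad:
                    iv = GenomicInterval(chrom, gene.start - _BROAD_PAD,
                                         gene.end + _BROAD_PAD, ".",
                                         f"{gene.gene_id}_broad")
                    islands.append(PlantedIsland(iv, "broad", gene.gene_id,
                                                 dict(all_nm)))
                    segments.append((iv.start, iv.end, config.island_gc,
                                     config.island_cpg_oe))
                else:
                    ilen = int(rng.integers(*config.island_length_range))
                    s = gene.tss - ilen // 2
                    iv = GenomicInterval(chrom, s, s + ilen, ".",
                                         f"{gene.gene_id}_canonical")
                    meth = dict(all_nm)
                    if is_ts:
                        meth = {t: (NON_METHYLATED if t == nm_tissue
                                    else METHYLATED) for t in config.tissues}
                    islands.append(PlantedIsland(iv, "canonical",
                                                 gene.gene_id, meth))
                    segments.append((iv.start, iv.end, config.island_gc,
                                     config.island_cpg_oe))
            gene_idx += 1
        else:
            ilen = int(rng.integers(*config.plastic_length_range))
            s = int(center - ilen // 2)
            iv = GenomicInterval(chrom, s, s + ilen, ".",
                                 f"{species_id}_plastic{plastic_idx:03d}")
            nm_tissue = config.tissues[int(rng.integers(len(config.tissues)))]
            meth = {t: (NON_METHYLATED if t == nm_tissue else METHYLATED)
                    for t in config.tissues}
            islands.append(PlantedIsland(iv, "plastic", None, meth))
            segments.append((iv.start, iv.end, config.island_gc,
                             config.plastic_cpg_oe))
            plastic_idx += 1

    # background sequence, then overwrite island segments
    seq = list(markov_sequence(L, config.background_gc,
                               config.background_cpg_oe, rng))
    for s, e, gc, oe in segments:
        seq[s:e] = markov_sequence(e - s, gc, oe, rng)
    truth = SpeciesTruth(species_id, {chrom: L}, genes, islands)
    return {chrom: "".join(seq)}, truth


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Generate sequences, gene models and the truth ledger for all species.

    Orthologue groups map gene ``i`` of every species to one another;
    island presence in species > 0 copies species 0's state with
    probability ``conservation_rate`` and is otherwise redrawn from
    ``island_presence_rate``.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "genome"))
    species_ids = [f"sp{i + 1}" for i in range(config.n_species)]
    presence0 = rng.random(config.n_genes) < config.island_presence_rate
    sequences: Dict[str, Dict[str, str]] = {}
    truths: Dict[str, SpeciesTruth] = {}
    orth_cols: Dict[str, List[str]] = {}
    for si, sp in enumerate(species_ids):
        if si == 0:
            presence = presence0
        else:
            keep = rng.random(config.n_genes) < config.conservation_rate
            fresh = rng.random(config.n_genes) < config.island_presence_rate
            presence = np.where(keep, presence0, fresh)
        sp_rng = np.random.default_rng(derive_seed(config.seed, "species", sp))
        seqs, truth = _plant_species(sp, config, presence, sp_rng)
        sequences[sp] = seqs
        truths[sp] = truth
        orth_cols[sp] = [g.gene_id for g in truth.genes]
    orth = pd.DataFrame(orth_cols)
    truth_set = TruthSet(truths, orth, config.tissues)
    return SimulatedGenome(sequences, {sp: truths[sp].genes
                                       for sp in species_ids},
                           truth_set, config)


# ---------------------------------------------------------------------------
# Bio-CAP read simulation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean, dispersion: float, size=None
             ) -> np.ndarray:
    """Negative binomial with var = mu + dispersion*mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean, size)
    lam = rng.gamma(shape=1.0 / dispersion,
                    scale=mean * dispersion, size=size)
    return rng.poisson(lam)


def _cpg_positions(seq: str) -> np.ndarray:
    s = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return np.flatnonzero((s[:-1] == ord("C")) & (s[1:] == ord("G")))


def _coverage_from_starts(starts: np.ndarray, read_length: int,
                          chrom_length: int) -> np.ndarray:
    d = np.zeros(chrom_length + 1)
    np.add.at(d, starts, 1.0)
    np.add.at(d, starts + read_length, -1.0)
    return np.cumsum(d)[:chrom_length]


def simulate_biocap(sequences: Dict[str, str], truth: SpeciesTruth,
                    tissue: str, config: SimulationConfig,
                    seed: Optional[int] = None
                    ) -> Tuple[CoverageTrack, CoverageTrack]:
    """Simulate one tissue's Bio-CAP sample track and its matched input.

    Sample reads arise from (a) a CpG-independent background at
    ``input_depth`` mean coverage and (b) ``capture_efficiency`` expected
    reads per CpG that is non-methylated in this tissue, each read placed
    within a ``fragment_window`` around its CpG.  The input track carries
    the background process only.
    """
    if tissue not in config.tissues:
        raise ValueError(f"unknown tissue {tissue!r} (have {config.tissues})")
    if seed is None:
        seed = derive_seed(config.seed, "biocap", truth.species_id, tissue)
    rng = np.random.default_rng(seed)
    rl = config.read_length
    half = config.fragment_window // 2

    nm_islands = [i for i in truth.islands if i.non_methylated_in(tissue)]
    sample = CoverageTrack(truth.chrom_sizes)
    control = CoverageTrack(truth.chrom_sizes)
    for chrom, L in truth.chrom_sizes.items():
        seq = sequences[chrom]
        cpgs = _cpg_positions(seq)
        nm_mask = np.zeros(len(seq), dtype=bool)
        for isl in nm_islands:
            if isl.interval.chrom == chrom:
                nm_mask[isl.interval.start:isl.interval.end] = True
        nm_cpgs = cpgs[nm_mask[cpgs]]

        # background process (both tracks, independent draws)
        n_bg_mean = config.input_depth * L / rl
        for track in (sample, control):
            n_bg = int(_nb_draw(rng, n_bg_mean, config.noise_overdispersion))
            starts = rng.integers(0, L - rl, n_bg)
            track.data[chrom] += _coverage_from_starts(starts, rl, L)
            track.total_reads += n_bg

        # capture reads around non-methylated CpGs
        if config.capture_efficiency > 0 and len(nm_cpgs):
            reads_per_cpg = _nb_draw(rng, np.full(len(nm_cpgs),
                                                  config.capture_efficiency),
                                     config.noise_overdispersion)
            centres = np.repeat(nm_cpgs, reads_per_cpg)
            if len(centres):
                offs = rng.integers(-half, half - rl + 1, len(centres))
                starts = np.clip(centres + offs, 0, L - rl)
                sample.data[chrom] += _coverage_from_starts(starts, rl, L)
                sample.total_reads += len(centres)
    return sample, control


# ---------------------------------------------------------------------------
# expression, chromatin and GO simulation
# ---------------------------------------------------------------------------

@dataclass
class ExpressionChromatin:
    counts: CountMatrix
    de_truth: pd.DataFrame
    h3k4me3: Dict[str, CoverageTrack]
    h3k4me1: IntervalSet
    h3k27me3: IntervalSet
    go_mapping: pd.DataFrame


def _assign_de(truth: SpeciesTruth, config: SimulationConfig,
               rng: np.random.Generator) -> pd.DataFrame:
    """Choose true DE genes, preferentially those with tissue-specific
    promoter islands, with the direction of the non-methylated tissue."""
    t_a, t_b = config.tissues[0], config.tissues[1]
    gene_ids = [g.gene_id for g in truth.genes]
    lfc = pd.Series(0.0, index=gene_ids)
    promoter = truth.promoter_island_genes()
    n_de_target = int(round(config.de_fraction * len(gene_ids)))
    ts_genes = [gid for gid, isl in promoter.items()
                if isl.island_class == "canonical"
                and not all(isl.non_methylated_in(t) for t in config.tissues)]
    chosen: List[str] = []
    for gid in ts_genes:
        if rng.random() < 0.8:
            chosen.append(gid)
            # positive lfc = up in tissue B (liver) by convention
            up_b = promoter[gid].non_methylated_in(t_b)
            lfc[gid] = config.de_log2fc if up_b else -config.de_log2fc
    others = [g for g in gene_ids if g not in set(chosen)]
    n_more = max(0, n_de_target - len(chosen))
    extra = rng.choice(others, size=min(n_more, len(others)), replace=False)
    for gid in extra:
        lfc[gid] = config.de_log2fc * (1 if rng.random() < 0.5 else -1)
    direction = np.where(lfc > 0, f"{t_b}_up",
                         np.where(lfc < 0, f"{t_a}_up", "none"))
    return pd.DataFrame({"gene_id": gene_ids, "log2fc": lfc.values,
                         "direction": direction})


def _make_counts(de_truth: pd.DataFrame, config: SimulationConfig,
                 rng: np.random.Generator) -> CountMatrix:
    t_a, t_b = config.tissues[0], config.tissues[1]
    n = len(de_truth)
    base = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=n)
    lfc = de_truth["log2fc"].to_numpy()
    mean_a = base * 2.0 ** (-lfc / 2.0)
    mean_b = base * 2.0 ** (lfc / 2.0)
    samples: Dict[str, np.ndarray] = {}
    tissues: Dict[str, str] = {}
    for tissue, means in ((t_a, mean_a), (t_b, mean_b)):
        for r in range(config.n_replicates):
            size_factor = rng.uniform(0.7, 1.3)
            name = f"{tissue}_{r + 1}"
            samples[name] = _nb_draw(rng, means * size_factor,
                                     config.nb_dispersion)
            tissues[name] = tissue
    counts = pd.DataFrame(samples, index=de_truth["gene_id"].to_numpy())
    counts.index.name = "gene_id"
    return CountMatrix(counts, tissues)


def simulate_de_counts(n_genes: int, config: SimulationConfig,
                       seed: Optional[int] = None
                       ) -> Tuple[CountMatrix, pd.DataFrame]:
    """Standalone count-matrix simulation (for scale tests of the DE path):
    ``de_fraction`` of ``n_genes`` genes DE at ``+-de_log2fc``."""
    if seed is None:
        seed = derive_seed(config.seed, "de_counts")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    lfc = np.zeros(n_genes)
    n_de = int(round(config.de_fraction * n_genes))
    idx = rng.choice(n_genes, size=n_de, replace=False)
    signs = np.where(rng.random(n_de) < 0.5, 1.0, -1.0)
    lfc[idx] = config.de_log2fc * signs
    t_a, t_b = config.tissues[0], config.tissues[1]
    direction = np.where(lfc > 0, f"{t_b}_up",
                         np.where(lfc < 0, f"{t_a}_up", "none"))
    de_truth = pd.DataFrame({"gene_id": gene_ids, "log2fc": lfc,
                             "direction": direction})
    return _make_counts(de_truth, config, rng), de_truth


def simulate_go_mapping(gene_ids: Sequence[str],
                        enriched_genes: Sequence[str],
                        rng: np.random.Generator,
                        n_terms: int = 20, base_prob: float = 0.15,
                        enrichment: float = 5.0) -> pd.DataFrame:
    """Random GO annotations with one term planted among ``enriched_genes``
    at ``enrichment`` x the base annotation probability."""
    enriched = set(enriched_genes)
    rows = []
    planted = "GO:9000001"
    for gid in gene_ids:
        for t in range(n_terms):
            term = f"GO:{t + 1:07d}"
            if rng.random() < base_prob:
                rows.append((gid, term, f"term_{t + 1}", "BP"))
        p = base_prob * (enrichment if gid in enriched else 1.0)
        if rng.random() < min(1.0, p):
            rows.append((gid, planted, "sequence_specific_DNA_binding", "MF"))
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name",
                                       "ontology"])


def simulate_expression_and_chromatin(truth: TruthSet,
                                      config: SimulationConfig,
                                      species: Optional[str] = None,
                                      seed: Optional[int] = None
                                      ) -> ExpressionChromatin:
    """Counts, H3K4me3 tracks per tissue, H3K4me1/H3K27me3 intervals and a
    GO mapping, all coupled to the planted islands of one species."""
    if species is None:
        species = next(iter(truth.species))
    sp = truth.species[species]
    if seed is None:
        seed = derive_seed(config.seed, "expr", species)
    rng = np.random.default_rng(seed)

    de_truth = _assign_de(sp, config, rng)
    counts = _make_counts(de_truth, config, rng)
    truth.de_truth = de_truth

    # H3K4me3: promoter-mark coverage only where the island is non-methylated
    background_level = 0.2
    island_height = 5.0
    h3k4me3: Dict[str, CoverageTrack] = {}
    for tissue in config.tissues:
        track = CoverageTrack(sp.chrom_sizes)
        for chrom in sp.chrom_sizes:
            track.data[chrom] += background_level
        for isl in sp.islands:
            if isl.non_methylated_in(tissue):
                h = rng.gamma(shape=10.0, scale=island_height / 10.0)
                iv = isl.interval
                track.add_interval(iv.chrom, max(0, iv.start - 500),
                                   min(sp.chrom_sizes[iv.chrom], iv.end + 500),
                                   h)
        h3k4me3[tissue] = track

    k27: List[GenomicInterval] = []
    k4me1: List[GenomicInterval] = []
    for isl in sp.islands:
        iv = isl.interval
        if isl.island_class == "broad":
            p27 = config.h3k27me3_broad_prob
        elif isl.island_class == "canonical":
            p27 = config.h3k27me3_canonical_prob
        else:
            p27 = 0.0
        if rng.random() < p27:
            k27.append(GenomicInterval(iv.chrom, max(0, iv.start - 1000),
                                       iv.end + 1000, ".", "H3K27me3"))
        if isl.island_class == "plastic" \
                and rng.random() < config.h3k4me1_plastic_prob:
            k4me1.append(GenomicInterval(iv.chrom, iv.start, iv.end, ".",
                                         "H3K4me1"))

    broad_genes = [i.gene_id for i in sp.islands_of_class("broad")]
    go = simulate_go_mapping([g.gene_id for g in sp.genes], broad_genes, rng)
    return ExpressionChromatin(counts, de_truth, h3k4me3,
                               IntervalSet(k4me1, species),
                               IntervalSet(k27, species), go)


# ---------------------------------------------------------------------------
# lightweight orthologue-status simulation (for scale tests)
# ---------------------------------------------------------------------------

def simulate_orthologue_statuses(n_groups: int, presence_rate: float,
                                 conservation_rate: float, seed: int,
                                 n_species: int = 2
                                 ) -> Tuple[pd.DataFrame,
                                            List[Dict[str, bool]]]:
    """1:1(:1) orthologue groups with coupled island presence.

    Species 0 presence ~ Bernoulli(``presence_rate``); each other species
    copies species 0 with probability ``conservation_rate`` and otherwise
    redraws independently.  The expected pairwise conservation score is
    ``r + (1 - r) * p``.
    """
    rng = np.random.default_rng(seed)
    cols = {f"sp{i + 1}": [f"sp{i + 1}_g{j:06d}" for j in range(n_groups)]
            for i in range(n_species)}
    orth = pd.DataFrame(cols)
    base = rng.random(n_groups) < presence_rate
    statuses: List[Dict[str, bool]] = []
    for i in range(n_species):
        if i == 0:
            pres = base
        else:
            keep = rng.random(n_groups) < conservation_rate
            fresh = rng.random(n_groups) < presence_rate
            pres = np.where(keep, base, fresh)
        statuses.append(dict(zip(cols[f"sp{i + 1}"], map(bool, pres))))
    return orth, statuses


# ---------------------------------------------------------------------------
# realized-statistics report and dataset export
# ---------------------------------------------------------------------------

def realized_island_stats(sim: SimulatedGenome, species: str
                          ) -> pd.DataFrame:
    """Per planted island: realized GC and CpG O/E (counting oracle input)."""
    sp = sim.truth.species[species]
    rows = []
    for isl in sp.islands:
        iv = isl.interval
        bc = count_bases(sim.sequences[species][iv.chrom][iv.start:iv.end])
        rows.append((iv.chrom, iv.start, iv.end, isl.island_class,
                     bc.gc_content, bc.cpg_oe))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "class",
                                       "gc", "cpg_oe"])


def write_dataset(sim: SimulatedGenome, outdir: str) -> Dict[str, str]:
    """Write the full dataset as standard text files; returns a manifest
    of the paths written."""
    import os

    from . import io_formats as iof
    os.makedirs(outdir, exist_ok=True)
    manifest: Dict[str, str] = {}
    cfg = sim.config
    for sp, seqs in sim.sequences.items():
        base = os.path.join(outdir, sp)
        os.makedirs(base, exist_ok=True)
        iof.write_fasta(seqs, os.path.join(base, "genome.fa"))
        iof.write_chrom_sizes(sim.truth.species[sp].chrom_sizes,
                              os.path.join(base, "chrom.sizes"))
        iof.write_gene_models_gtf(sim.genes[sp],
                                  os.path.join(base, "genes.gtf"))
        iof.write_bed(sim.truth.species[sp].island_intervals(),
                      os.path.join(base, "true_islands.bed"))
        manifest[sp] = base
        for tissue in cfg.tissues:
            sample, control = simulate_biocap(seqs, sim.truth.species[sp],
                                              tissue, cfg)
            iof.write_bedgraph(sample,
                               os.path.join(base, f"{tissue}_biocap.bedgraph"))
            iof.write_bedgraph(control,
                               os.path.join(base, f"{tissue}_input.bedgraph"))
    sim.truth.orthologues.to_csv(os.path.join(outdir, "orthologues.tsv"),
                                 sep="\t", index=False)
    sp0 = next(iter(sim.sequences))
    expr = simulate_expression_and_chromatin(sim.truth, cfg, sp0)
    iof.write_counts(expr.counts, os.path.join(outdir, "counts.tsv"))
    expr.go_mapping.to_csv(os.path.join(outdir, "go_mapping.tsv"),
                           sep="\t", index=False)
    iof.write_bed(expr.h3k4me1, os.path.join(outdir, "h3k4me1.bed"))
    iof.write_bed(expr.h3k27me3, os.path.join(outdir, "h3k27me3.bed"))
    ledger = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "species": {
            sp: {
                "chrom_sizes": t.chrom_sizes,
                "islands": [
                    {"chrom": i.interval.chrom, "start": i.interval.start,
                     "end": i.interval.end, "class": i.island_class,
                     "gene_id": i.gene_id, "methylation": i.methylation}
                    for i in t.islands],
                "genes": [
                    {"gene_id": g.gene_id, "chrom": g.chrom,
                     "start": g.start, "end": g.end, "strand": g.strand,
                     "biotype": g.biotype} for g in t.genes],
            } for sp, t in sim.truth.species.items()},
        "de_truth": (sim.truth.de_truth.to_dict(orient="records")
                     if sim.truth.de_truth is not None else None),
    }
    ledger_path = os.path.join(outdir, "truth_ledger.json")
    with open(ledger_path, "w") as fh:
        json.dump(ledger, fh, indent=1)
    manifest["truth_ledger"] = ledger_path
    return manifest
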