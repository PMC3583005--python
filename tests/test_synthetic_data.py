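"""Generator contracts: determinism, realized composition, enrichment
geometry and ledger/file consistency."""

import numpy as np
import pytest

import nmiscape as nm
from nmiscape.synthetic_data import NON_METHYLATED

from oracles import scan_gc_oe

SMALL = dict(chrom_length=250_000, n_genes=10, plastic_count=3)


def test_same_seed_is_byte_identical():
    a = nm.simulate_genome(nm.SimulationConfig(seed=5, **SMALL))
    b = nm.simulate_genome(nm.SimulationConfig(seed=5, **SMALL))
    assert a.sequences == b.sequences
    assert a.genes == b.genes
    for sp in a.truth.species:
        ia = [(i.interval, i.island_class, i.gene_id, i.methylation)
              for i in a.truth.species[sp].islands]
        ib = [(i.interval, i.island_class, i.gene_id, i.methylation)
              for i in b.truth.species[sp].islands]
        assert ia == ib


def test_different_seed_differs():
    a = nm.simulate_genome(nm.SimulationConfig(seed=5, **SMALL))
    b = nm.simulate_genome(nm.SimulationConfig(seed=6, **SMALL))
    assert a.sequences != b.sequences


def test_island_background_cpg_oe_separation():
    """Mean realized island CpG O/E exceeds background by >= 0.5 when the
    configured targets are 0.9 vs 0.2 (counting-oracle check, 5 seeds)."""
    gaps = []
    for seed in range(5):
        cfg = nm.SimulationConfig(seed=seed, **SMALL)
        sim = nm.simulate_genome(cfg)
        sp = sim.truth.species["sp1"]
        seq = sim.sequences["sp1"]["chr1"]
        island_oes = [scan_gc_oe(seq[i.interval.start:i.interval.end])[1]
                      for i in sp.islands if i.island_class != "plastic"]
        # background: gaps at least 3 kb from any island
        mask = np.zeros(len(seq), dtype=bool)
        for i in sp.islands:
            mask[max(0, i.interval.start - 3000):i.interval.end + 3000] = True
        bg_runs = []
        pos = 0
        while pos + 5000 < len(seq):
            if not mask[pos:pos + 5000].any():
                bg_runs.append(scan_gc_oe(seq[pos:pos + 5000])[1])
            pos += 5000
        gaps.append(np.mean(island_oes) - np.mean(bg_runs))
    assert np.mean(gaps) >= 0.5


def test_realized_statistics_near_targets():
    cfg = nm.SimulationConfig(seed=2)
    sim = nm.simulate_genome(cfg)
    seq = sim.sequences["sp1"]["chr1"]
    gc, oe = scan_gc_oe(seq)  # whole chromosome is background-dominated
    assert gc == pytest.approx(cfg.background_gc, abs=0.05)
    sp = sim.truth.species["sp1"]
    stats = [scan_gc_oe(seq[i.interval.start:i.interval.end])
             for i in sp.islands if i.island_class != "plastic"]
    assert np.mean([s[0] for s in stats]) == pytest.approx(cfg.island_gc,
                                                           abs=0.05)
    assert np.mean([s[1] for s in stats]) == pytest.approx(cfg.island_cpg_oe,
                                                           abs=0.05)


def test_zebrafish_mode_gc_indistinguishable():
    """Fish-like regime: island GC within 0.02 of background while the
    CpG O/E separation is retained."""
    island_gc, bg_gc, island_oe, bg_oe = [], [], [], []
    for seed in range(5):
        cfg = nm.SimulationConfig.zebrafish_mode(seed=seed, **SMALL)
        sim = nm.simulate_genome(cfg)
        sp = sim.truth.species["sp1"]
        seq = sim.sequences["sp1"]["chr1"]
        for i in sp.islands:
            if i.island_class == "plastic":
                continue
            gc, oe = scan_gc_oe(seq[i.interval.start:i.interval.end])
            island_gc.append(gc)
            island_oe.append(oe)
        gc, oe = scan_gc_oe(seq[:50_000])
        bg_gc.append(gc)
        bg_oe.append(oe)
    assert abs(np.mean(island_gc) - np.mean(bg_gc)) <= 0.02
    assert np.mean(island_oe) - np.mean(bg_oe) >= 0.5


def test_infeasible_packing_raises_before_sequences():
    cfg = nm.SimulationConfig(seed=0, chrom_length=100_000, n_genes=50)
    with pytest.raises(ValueError, match="packing"):
        nm.simulate_genome(cfg)


def test_truth_ledger_consistency(default_sim):
    """Planted intervals in bounds; broad islands cover > 90% of their
    gene per-base; plastic islands >= 5 kb from every gene; promoter
    islands overlap their gene's TSS window."""
    sp = default_sim["sp"]
    L = sp.chrom_sizes["chr1"]
    genes = {g.gene_id: g for g in sp.genes}
    for isl in sp.islands:
        iv = isl.interval
        assert 0 <= iv.start < iv.end <= L
        if isl.island_class == "broad":
            g = genes[isl.gene_id]
            covered = min(iv.end, g.end) - max(iv.start, g.start)
            assert covered / g.length > 0.9
        elif isl.island_class == "plastic":
            for g in genes.values():
                assert iv.end + 5000 <= g.start or g.end + 5000 <= iv.start
            assert sum(isl.non_methylated_in(t)
                       for t in default_sim["cfg"].tissues) == 1
        else:
            g = genes[isl.gene_id]
            assert iv.start <= g.tss + 1000 and g.tss - 1000 <= iv.end


class TestBiocap:
    def test_null_enrichment_limit(self):
        # Poisson noise isolates the rate structure; the NB depth draw
        # would otherwise dominate a single genome's realized mean
        cfg = nm.SimulationConfig(seed=3, capture_efficiency=0.0,
                                  noise_overdispersion=0.0, **SMALL)
        sim = nm.simulate_genome(cfg)
        sp = sim.truth.species["sp1"]
        s, c = nm.simulate_biocap(sim.sequences["sp1"], sp, "testes", cfg)
        ms, mc = s.total_area() / cfg.chrom_length, \
            c.total_area() / cfg.chrom_length
        assert ms == pytest.approx(cfg.input_depth, rel=0.1)
        assert mc == pytest.approx(cfg.input_depth, rel=0.1)

    def test_total_reads_equal_area_over_read_length(self, default_sim):
        s, c = default_sim["tracks"]["testes"]
        for tr in (s, c):
            assert tr.total_area() / default_sim["cfg"].read_length == \
                pytest.approx(tr.total_reads, rel=1e-9)

    def test_tissue_differential_coverage(self):
        """Coverage over a plastic island is higher in its non-methylated
        tissue in >= 95% of planted islands (Monte-Carlo)."""
        wins = total = 0
        for seed in range(8):
            cfg = nm.SimulationConfig(seed=seed, chrom_length=300_000,
                                      n_genes=2, plastic_count=13)
            sim = nm.simulate_genome(cfg)
            sp = sim.truth.species["sp1"]
            tracks = {t: nm.simulate_biocap(sim.sequences["sp1"], sp, t,
                                            cfg)[0] for t in cfg.tissues}
            for isl in sp.islands_of_class("plastic"):
                iv = isl.interval
                own = next(t for t in cfg.tissues
                           if isl.non_methylated_in(t))
                other = next(t for t in cfg.tissues
                             if not isl.non_methylated_in(t))
                total += 1
                wins += tracks[own].mean(iv.chrom, iv.start, iv.end) > \
                    tracks[other].mean(iv.chrom, iv.start, iv.end)
        assert total >= 100
        assert wins / total >= 0.95

    def test_unknown_tissue_raises(self, default_sim):
        with pytest.raises(ValueError, match="tissue"):
            nm.simulate_biocap(default_sim["sim"].sequences["sp1"],
                               default_sim["sp"], "kidney",
                               default_sim["cfg"])


class TestExpressionChromatin:
    def test_de_fraction_zero_means_no_true_de(self):
        cfg = nm.SimulationConfig(seed=4, de_fraction=0.0,
                                  tissue_specific_promoter_fraction=0.0,
                                  **SMALL)
        sim = nm.simulate_genome(cfg)
        expr = nm.simulate_expression_and_chromatin(sim.truth, cfg, "sp1")
        assert (expr.de_truth["log2fc"] == 0).all()

    def test_h3k27me3_broad_rate_matches_generative_probability(self):
        hits = total = 0
        for seed in range(5):
            cfg = nm.SimulationConfig(seed=seed, chrom_length=600_000,
                                      n_genes=24, plastic_count=2,
                                      broad_fraction=1.0)
            sim = nm.simulate_genome(cfg)
            expr = nm.simulate_expression_and_chromatin(sim.truth, cfg,
                                                        "sp1")
            sp = sim.truth.species["sp1"]
            for isl in sp.islands_of_class("broad"):
                iv = isl.interval
                total += 1
                hits += expr.h3k27me3.overlaps_interval(iv.chrom, iv.start,
                                                        iv.end)
        assert total >= 100
        assert hits / total == pytest.approx(0.9, abs=0.05)

    def test_h3k4me3_absent_at_methylated_islands(self, default_sim):
        """H3K4me3 over an island methylated in a tissue stays near the
        background level in that tissue's track."""
        expr = default_sim["expr"]
        sp = default_sim["sp"]
        cfg = default_sim["cfg"]
        checks = []
        for isl in sp.islands:
            for t in cfg.tissues:
                if isl.non_methylated_in(t):
                    continue
                iv = isl.interval
                bg = expr.h3k4me3[t].mean(iv.chrom, 0, 2000)
                checks.append(expr.h3k4me3[t].mean(iv.chrom, iv.start,
                                                   iv.end) <= bg * 1.5)
        assert checks and np.mean(checks) >= 0.95


def test_orthologue_status_coupling_expectation():
    orth, (sa, sb) = nm.simulate_orthologue_statuses(5000, 0.9, 0.9, seed=11)
    res = nm.pairwise_conservation(orth, sa, sb)
    assert res.score == pytest.approx(0.9 + 0.1 * 0.9, abs=0.02)


def test_write_dataset_round_trips(default_sim, tmp_path):
    manifest = nm.write_dataset(default_sim["sim"], str(tmp_path))
    sizes = nm.read_chrom_sizes(str(tmp_path / "sp1" / "chrom.sizes"))
    assert sizes == default_sim["sp"].chrom_sizes
    genes = nm.read_gene_models(str(tmp_path / "sp1" / "genes.gtf"), "gtf")
    assert genes == default_sim["sp"].genes
    truth_bed = nm.read_bed(str(tmp_path / "sp1" / "true_islands.bed"))
    assert len(truth_bed) == len(default_sim["sp"].islands)
    assert (tmp_path / "truth_ledger.json").exists()
    assert "truth_ledger" in manifest
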