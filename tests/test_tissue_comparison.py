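"""Shared/unique classification, the simplified DE test and the
tissue-specific-NMI / differential-expression association."""

import numpy as np
import pandas as pd
import pytest

import nmiscape as nm
from nmiscape.tissue_comparison import (median_of_ratios_size_factors,
                                        sample_odds_ratio)

from oracles import fisher_greater


def iset(*spans, chrom="chr1"):
    return nm.IntervalSet([nm.GenomicInterval(chrom, s, e)
                           for s, e in spans])


class TestClassification:
    def test_overlapping_intervals_are_shared_in_both(self):
        classes = nm.classify_tissue_nmis(iset((0, 100)), iset((50, 150)),
                                          [])
        assert [(c.tissue_of_origin, c.status) for c in classes] == \
            [("testes", "shared"), ("liver", "shared")]

    def test_empty_other_tissue_makes_unique(self):
        classes = nm.classify_tissue_nmis(iset((0, 100)), iset(), [])
        assert [(c.tissue_of_origin, c.status) for c in classes] == \
            [("testes", "unique")]

    def test_per_tissue_partition(self, default_sim):
        peaks = default_sim["peaks"]
        classes = nm.classify_tissue_nmis(
            nm.peaks_to_intervals(peaks["testes"]),
            nm.peaks_to_intervals(peaks["liver"]),
            default_sim["sp"].genes)
        for tissue, pk in peaks.items():
            ours = [c for c in classes if c.tissue_of_origin == tissue]
            assert len(ours) == len(pk)

    def test_plastic_islands_recovered_as_unique_in_their_tissue(
            self, default_sim):
        """Planted plastic islands come back as unique NMIs of exactly
        their non-methylated tissue (recall >= 0.9)."""
        sp = default_sim["sp"]
        peaks = default_sim["peaks"]
        classes = nm.classify_tissue_nmis(
            nm.peaks_to_intervals(peaks["testes"]),
            nm.peaks_to_intervals(peaks["liver"]), sp.genes)
        unique = {t: nm.IntervalSet([c.interval for c in classes
                                     if c.tissue_of_origin == t
                                     and c.status == "unique"])
                  for t in ("testes", "liver")}
        plastics = sp.islands_of_class("plastic")
        hits = 0
        for isl in plastics:
            own = next(t for t in ("testes", "liver")
                       if isl.non_methylated_in(t))
            other = "liver" if own == "testes" else "testes"
            iv = isl.interval
            if unique[own].overlaps_interval(iv.chrom, iv.start, iv.end) \
                    and not unique[other].overlaps_interval(iv.chrom,
                                                            iv.start,
                                                            iv.end):
                hits += 1
        assert hits / len(plastics) >= 0.9

    def test_shared_longer_and_denser_than_unique(self, default_sim):
        """The planted contrast (plastic islands shorter and CpG-sparser)
        is recovered in the shared/unique strata medians."""
        sp = default_sim["sp"]
        classes = nm.classify_tissue_nmis(
            nm.peaks_to_intervals(default_sim["peaks"]["testes"]),
            nm.peaks_to_intervals(default_sim["peaks"]["liver"]),
            sp.genes, sequences=default_sim["sim"].sequences["sp1"])
        df = pd.DataFrame([(c.status, c.length, c.cpg_per_bp)
                           for c in classes],
                          columns=["status", "length", "dens"])
        med = df.groupby("status").median()
        assert med.loc["shared", "length"] > med.loc["unique", "length"]
        assert med.loc["shared", "dens"] > med.loc["unique", "dens"]


def make_cm(rows, n_rep=2, tissues=("testes", "liver")):
    """rows: gene_id -> (counts_a per rep, counts_b per rep)."""
    data, labels = {}, {}
    for t_idx, t in enumerate(tissues):
        for r in range(n_rep):
            name = f"{t}_{r + 1}"
            data[name] = [rows[g][t_idx][r] for g in rows]
            labels[name] = t
    return nm.CountMatrix(pd.DataFrame(data, index=list(rows)), labels)


class TestDifferentialExpression:
    def test_identical_counts_flag_nothing(self):
        rows = {f"g{i}": ((i + 1, i + 2), (i + 1, i + 2))
                for i in range(50)}
        res = nm.differential_expression(make_cm(rows))
        assert not any(d.de_flag for d in res)
        assert all(d.direction == "none" for d in res)

    def test_exact_binomial_oracle_example(self):
        """Summed normalized counts 100 vs 12 at equal library sizes give
        the doubled exact binomial tail of 100/112 at rate 1/2."""
        # equal library sizes: all other genes identical across samples,
        # target gene 50+50 vs 6+6 (and a balancing gene keeps sums equal)
        rows = {f"bg{i}": ((30, 30), (30, 30)) for i in range(200)}
        rows["target"] = ((50, 50), (6, 6))
        rows["balance"] = ((6, 6), (50, 50))
        cm = make_cm(rows)
        sf = median_of_ratios_size_factors(cm.counts)
        assert np.allclose(sf, 1.0)
        res = {d.gene_id: d for d in nm.differential_expression(cm)}
        from math import comb
        tail = sum(comb(112, k) for k in range(13)) / 2 ** 112
        expected = min(1.0, 2 * tail)
        assert res["target"].p_value == pytest.approx(expected, rel=1e-10)
        assert res["target"].direction == "testes_up"
        assert res["balance"].direction == "liver_up"

    def test_all_zero_gene_never_flagged(self):
        rows = {f"g{i}": ((10, 10), (10, 10)) for i in range(20)}
        rows["zero"] = ((0, 0), (0, 0))
        res = {d.gene_id: d for d in nm.differential_expression(make_cm(rows))}
        z = res["zero"]
        assert (z.log_ratio_M, z.de_flag) == (0.0, False)

    def test_size_factor_normalization_recovers_library_scaling(self, rng):
        base = rng.integers(10, 1000, size=100) * 4  # keeps scaling integral
        scale = {"testes_1": 1.0, "testes_2": 2.0,
                 "liver_1": 0.5, "liver_2": 1.5}
        counts = pd.DataFrame({s: (base * f).astype(int)
                               for s, f in scale.items()},
                              index=[f"g{i}" for i in range(100)])
        sf = median_of_ratios_size_factors(counts)
        norm_totals = (counts / sf).sum(axis=0)
        assert np.allclose(norm_totals, norm_totals.iloc[0], rtol=1e-6)

    def test_fewer_than_two_replicates_rejected(self):
        rows = {"g": ((5,), (9,))}
        with pytest.raises(ValueError, match="replicates"):
            nm.differential_expression(make_cm(rows, n_rep=1))

    def test_recovery_and_fdr_on_simulated_counts(self):
        """At the configured effect size the DE path recovers >= 70% of
        true DE genes with empirical FDR <= 0.15."""
        cfg = nm.SimulationConfig(seed=0, de_fraction=0.2, de_log2fc=2.0,
                                  nb_dispersion=0.05, n_replicates=4)
        cm, de_truth = nm.simulate_de_counts(2000, cfg, seed=17)
        res = nm.differential_expression(cm)
        flags = pd.Series({d.gene_id: d.de_flag for d in res})
        truth = de_truth.set_index("gene_id")["log2fc"] != 0
        tp = int((flags & truth).sum())
        fp = int((flags & ~truth).sum())
        assert tp / int(truth.sum()) >= 0.7
        assert fp / max(1, int(flags.sum())) <= 0.15


class TestAssociation:
    def test_odds_ratio_formula(self):
        assert sample_odds_ratio(((20, 5), (10, 65))) == pytest.approx(26.0)

    def test_haldane_correction_on_zero_cell(self):
        assert sample_odds_ratio(((5, 0), (3, 7))) == \
            pytest.approx((5.5 * 7.5) / (0.5 * 3.5))

    def test_fisher_matches_enumeration_for_small_tables(self):
        for a in range(5):
            for b in range(5):
                for c in range(5):
                    for d in range(5):
                        if a + b + c + d == 0:
                            continue
                        table = ((a, b), (c, d))
                        assert nm.tissue_comparison.fisher_one_sided(table) \
                            == pytest.approx(fisher_greater(table),
                                             rel=1e-9, abs=1e-12)

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError, match="universe"):
            nm.nmi_de_association([], [], [])

    def test_planted_coupling_detected(self, default_sim):
        """Genes with tissue-specific promoter NMIs are enriched among
        genes overexpressed in the non-methylated tissue."""
        sp = default_sim["sp"]
        classes = nm.classify_tissue_nmis(
            nm.peaks_to_intervals(default_sim["peaks"]["testes"]),
            nm.peaks_to_intervals(default_sim["peaks"]["liver"]), sp.genes)
        de = nm.differential_expression(default_sim["expr"].counts)
        assoc = nm.nmi_de_association(classes, de, sp.genes)
        assert set(assoc) == {"testes", "liver"}
        # at least one tissue shows the planted enrichment clearly
        assert min(r.p_value for r in assoc.values()) <= 0.05
        for r in assoc.values():
            assert r.odds_ratio > 1.0

    def test_independence_null_is_calibrated(self, rng):
        """Fisher one-sided p under independent memberships is
        super-uniform: P(p <= 0.05) stays near or below 0.05."""
        hits = 0
        n_iter = 400
        for _ in range(n_iter):
            u = rng.random(60) < 0.3
            v = rng.random(60) < 0.3
            a = int((u & v).sum())
            b = int((u & ~v).sum())
            c = int((~u & v).sum())
            d = int((~u & ~v).sum())
            if nm.tissue_comparison.fisher_one_sided(((a, b), (c, d))) \
                    <= 0.05:
                hits += 1
        assert hits / n_iter <= 0.08
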