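"""k-mer counting and enrichment statistics, checked against exact oracles."""

import math

import numpy as np
import pytest

from immad.kmer_enrichment import (
    count_kmers,
    enrichment_screen,
    gene_frequency_test,
    heptamer_to_hexamers,
    kmer_universe_size,
    list_overlap_enrichment,
    per_motif_comparison,
    pooled_motif_comparison,
)
from immad.motif_tools import MotifGroup, scramble_motifs
from immad.synthetic_data import plant_motif_in_seqs, random_introns


def brute_force_counts(seqs, k):
    """Oracle: naive substring scan with N-window skipping."""
    counts = {}
    total = 0
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k].upper()
            if set(window) <= set("ACGT"):
                total += 1
                counts[window] = counts.get(window, 0) + 1
    return counts, total


def hypergeom_fisher_two_sided(a, b, c, d):
    """Oracle: exact two-sided Fisher p by full hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def pmf(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    observed = pmf(a)
    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    return sum(
        pmf(x) for x in range(lo, hi + 1) if pmf(x) <= observed * (1 + 1e-9)
    )


class TestCountKmers:
    def test_short_example(self):
        table = count_kmers(["ACGTACGT"], 5)
        assert table.counts == {"ACGTA": 1, "CGTAC": 1, "GTACG": 1, "TACGT": 1}
        assert table.total_windows == 4

    def test_sequence_shorter_than_k(self):
        table = count_kmers(["AAAA"], 5)
        assert table.counts == {} and table.total_windows == 0

    def test_n_windows_are_skipped(self):
        table = count_kmers(["ACGTNACGT"], 4)
        # windows touching the N are excluded from counts and the total
        assert table.total_windows == 2
        assert table.counts == {"ACGT": 2}

    @pytest.mark.parametrize("k", [5, 6, 7])
    def test_matches_brute_force_on_random_sequences(self, k):
        rng = np.random.default_rng(42)
        seqs = random_introns(50, 200, 0.4, rng)
        table = count_kmers(seqs, k)
        oracle_counts, oracle_total = brute_force_counts(seqs, k)
        assert table.counts == oracle_counts
        assert table.total_windows == oracle_total

    def test_counts_sum_to_total_windows_without_n(self):
        rng = np.random.default_rng(3)
        seqs = random_introns(20, 120, 0.5, rng)
        for k in (5, 6, 7):
            table = count_kmers(seqs, k)
            assert sum(table.counts.values()) == table.total_windows


class TestEnrichmentScreen:
    def test_identical_groups_never_significant(self):
        rng = np.random.default_rng(1)
        seqs = random_introns(30, 150, 0.4, rng)
        records = enrichment_screen(seqs, list(seqs), 5, alpha_corrected=1.0)
        assert all(not r.significant for r in records)
        assert all(r.p_raw == pytest.approx(1.0) for r in records)

    def test_planted_hexamer_detected(self):
        rng = np.random.default_rng(7)
        motif = MotifGroup.from_consensus("GATGAC")
        a, _ = plant_motif_in_seqs(
            random_introns(300, 200, 0.32, rng), motif, 0.015, rng
        )
        b, _ = plant_motif_in_seqs(
            random_introns(600, 200, 0.32, rng), motif, 0.005, rng
        )
        records = enrichment_screen(a, b, 6, alpha_corrected=1e-5)
        significant = {r.oligomer for r in records if r.significant}
        assert "GATGAC" in significant

    def test_p_matches_hypergeometric_oracle(self):
        records = enrichment_screen(
            ["ACGTACGTAC" * 3], ["TTTTTTTTTTACGT"], 5, alpha_corrected=1.0
        )
        for r in records:
            oracle = hypergeom_fisher_two_sided(
                r.count_a,
                r.windows_a - r.count_a,
                r.count_b,
                r.windows_b - r.count_b,
            )
            assert r.p_raw == pytest.approx(oracle, rel=1e-6)

    def test_ratio_and_bonferroni_arithmetic(self):
        # counts a=30/10000 vs b=10/10000 -> per-window frequency ratio 3.0
        a = ["GATGAC" + "T" * 4] * 30 + ["T" * 10] * 1994
        # each 10-mer contributes 5 hexamer windows -> 10120? keep it simple:
        records = enrichment_screen(a, a, 6, alpha_corrected=1.0)
        for r in records:
            assert r.p_corrected == pytest.approx(
                min(1.0, r.p_raw * kmer_universe_size(6))
            )
            assert r.ratio == pytest.approx(1.0)

    def test_swapping_groups_inverts_ratios_keeps_p(self):
        rng = np.random.default_rng(9)
        a = random_introns(40, 150, 0.3, rng)
        b = random_introns(40, 150, 0.5, rng)
        fwd = {r.oligomer: r for r in enrichment_screen(a, b, 5, 1e-5)}
        rev = {r.oligomer: r for r in enrichment_screen(b, a, 5, 1e-5)}
        for oligo, r in fwd.items():
            s = rev[oligo]
            assert r.p_raw == pytest.approx(s.p_raw, rel=1e-9)
            if r.count_a and r.count_b:
                assert r.ratio == pytest.approx(1.0 / s.ratio, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            enrichment_screen([], ["ACGTACGT"], 5)
        with pytest.raises(ValueError):
            enrichment_screen(["AAA"], ["ACGTACGT"], 5)  # zero windows in A


class TestGeneFrequency:
    @staticmethod
    def _gene_with(seqs):
        from immad.annotation_io import GenomicInterval
        from immad.splice_classifier import ClassifiedGene
        from .conftest import make_gene

        g = make_gene("g", [[(0, 100), (200, 300)], [(0, 100), (250, 300)]])
        flanking = tuple(
            (GenomicInterval("chr1", 100 + i * 500, 200 + i * 500), s)
            for i, s in enumerate(seqs)
        )
        from immad.splice_classifier import cluster_decision_sites, find_alternative_introns

        sites = tuple(cluster_decision_sites(find_alternative_introns(g)))
        return ClassifiedGene(g, sites, "SASS", flanking)

    def test_absent_motif_gives_p_one(self):
        motif = MotifGroup.from_consensus("GGGGGG")
        genes_a = [self._gene_with(["A" * 50]) for _ in range(5)]
        genes_b = [self._gene_with(["T" * 50]) for _ in range(5)]
        (rec,) = gene_frequency_test(genes_a, genes_b, [motif])
        assert rec.p_corrected == pytest.approx(1.0)

    def test_total_separation_matches_enumeration_oracle(self):
        # motif in all 10 of A, none of 10 in B: two-sided p = 2/C(20,10)
        motif = MotifGroup.from_consensus("GATGAC")
        genes_a = [self._gene_with(["TTGATGACTT"]) for _ in range(10)]
        genes_b = [self._gene_with(["T" * 10]) for _ in range(10)]
        (rec,) = gene_frequency_test(genes_a, genes_b, [motif])
        assert rec.genes_with_a == 10 and rec.genes_with_b == 0
        assert rec.p_raw == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_planted_difference_significant(self):
        rng = np.random.default_rng(21)
        motif = MotifGroup.from_consensus("GATGAC")
        genes_a = [
            self._gene_with(["TTGATGACTT" if rng.random() < 0.5 else "T" * 10])
            for _ in range(100)
        ]
        genes_b = [
            self._gene_with(["TTGATGACTT" if rng.random() < 0.1 else "T" * 10])
            for _ in range(100)
        ]
        (rec,) = gene_frequency_test(genes_a, genes_b, [motif])
        assert rec.p_corrected < 0.01


class TestPooledComparison:
    def test_identical_groups_ratio_one(self):
        motifs = [MotifGroup.from_consensus("GATGAC")]
        seqs = ["TTGATGACTTTT"] * 5
        res = pooled_motif_comparison(motifs, seqs, list(seqs))
        assert res.ratio == pytest.approx(1.0)

    def test_scrambled_motifs_not_enriched_on_planted_data(self):
        rng = np.random.default_rng(13)
        motif = MotifGroup.from_consensus("GATGAC")
        a, _ = plant_motif_in_seqs(
            random_introns(150, 200, 0.32, rng), motif, 0.015, rng
        )
        b, _ = plant_motif_in_seqs(
            random_introns(300, 200, 0.32, rng), motif, 0.005, rng
        )
        real = pooled_motif_comparison([motif], a, b)
        assert real.ratio > 2 and real.p < 1e-5
        ctrl = pooled_motif_comparison(scramble_motifs([motif], 99), a, b)
        assert 0.5 < ctrl.ratio < 2.0
        assert ctrl.p > 1e-3

    def test_per_motif_mode_consistent_with_pooled_singletons(self):
        rng = np.random.default_rng(17)
        motifs = [
            MotifGroup.from_consensus("GATGAC"),
            MotifGroup.from_consensus("RAGAAG"),
        ]
        a = random_introns(40, 150, 0.4, rng)
        b = random_introns(40, 150, 0.4, rng)
        singles = per_motif_comparison(motifs, a, b)
        for m, res in zip(motifs, singles):
            alone = pooled_motif_comparison([m], a, b)
            assert res.ratio == pytest.approx(alone.ratio, nan_ok=True)
            assert res.p == pytest.approx(alone.p)


class TestHeptamerConversion:
    @pytest.mark.parametrize(
        "inp,expected",
        [
            (["AGCAGAC"], ["AGCAGA", "GCAGAC"]),
            (["CCACA"], ["CCACA"]),
            (["AGCAGA", "AGCAGAC"], ["AGCAGA", "GCAGAC"]),
        ],
    )
    def test_conversion_and_dedup(self, inp, expected):
        assert heptamer_to_hexamers(inp) == expected

    def test_rejects_out_of_range_lengths(self):
        with pytest.raises(ValueError):
            heptamer_to_hexamers(["ACGT"])


class TestListOverlap:
    def test_identical_lists_fold_is_universe_over_reference(self):
        res = list_overlap_enrichment(["AAAAA", "CCCCC"], ["AAAAA", "CCCCC"], 1024)
        assert res.fold == pytest.approx(1024 / 2)
        assert res.p < 1e-4

    def test_disjoint_lists_fold_zero(self):
        res = list_overlap_enrichment(["AAAAA"], ["CCCCC"], 1024)
        assert res.fold == 0.0

    def test_published_style_counts_emit_both_fold_variants(self):
        query = [f"Q{i}" for i in range(79)]
        reference = query[:17] + [f"R{i}" for i in range(383)]
        res = list_overlap_enrichment(query, reference, 5120)
        assert res.overlap == 17
        assert res.expected == pytest.approx(79 * 400 / 5120)
        assert res.fold == pytest.approx(17 / (79 * 400 / 5120), rel=1e-6)
        assert res.odds_ratio == pytest.approx(
            (17 * (5120 - 79 - 400 + 17)) / ((79 - 17) * (400 - 17)), rel=1e-6
        )
        assert res.p < 1e-3

    def test_universe_smaller_than_lists_rejected(self):
        with pytest.raises(ValueError):
            list_overlap_enrichment(["A"] , ["B", "C"], 2)


class TestFamilyWiseError:
    def test_null_data_rarely_yields_any_corrected_hit(self):
        """Bonferroni keeps the family-wise error under control on null data."""
        runs_with_hit = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            a = random_introns(100, 200, 0.32, rng)
            b = random_introns(200, 200, 0.32, rng)
            records = enrichment_screen(a, b, 5, alpha_corrected=1e-2)
            if any(r.p_corrected < 1e-2 for r in records):
                runs_with_hit += 1
        assert runs_with_hit <= 3
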