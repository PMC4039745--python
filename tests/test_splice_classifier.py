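"""MASS/SASS classification: alternative introns, decision sites, flanking introns."""

import numpy as np
import pytest

from immad.annotation_io import Genome
from immad.splice_classifier import (
    classify,
    classify_genes,
    cluster_decision_sites,
    event_type,
    extract_flanking_introns,
    find_alternative_introns,
    remove_alt_start_introns,
)
from immad.synthetic_data import SimConfig, generate_dataset
from .conftest import make_gene


def brute_force_components(intervals):
    """Oracle: connected components by repeated pairwise merging."""
    comps = [{iv} for iv in intervals]
    merged = True
    while merged:
        merged = False
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                if any(
                    a[0] < b[1] and b[0] < a[1]
                    for a in comps[i]
                    for b in comps[j]
                ):
                    comps[i] |= comps.pop(j)
                    merged = True
                    break
            if merged:
                break
    return sorted(frozenset(c) for c in comps)


class TestAlternativeIntrons:
    def test_identical_intron_sets_yield_none(self):
        g = make_gene(
            "same",
            [
                [(0, 100), (200, 300)],
                [(0, 100), (200, 300)],
            ],
        )
        assert find_alternative_introns(g) == []

    def test_cassette_exon_yields_three(self, ce_gene):
        alts = find_alternative_introns(ce_gene)
        assert {a.interval.coords() for a in alts} == {
            (100, 200),
            (300, 400),
            (100, 400),
        }

    def test_mxe_yields_four(self, mxe_gene):
        alts = find_alternative_introns(mxe_gene)
        assert {a.interval.coords() for a in alts} == {
            (100, 200),
            (300, 600),
            (100, 400),
            (500, 600),
        }

    def test_supporting_isoforms_are_proper_subsets(self, ce_gene):
        for a in find_alternative_introns(ce_gene):
            assert 0 < len(a.supporting_isoforms) < len(ce_gene.transcripts)


class TestTSSFilter:
    def test_pure_tss_variants_all_removed(self, tss_gene):
        alts = find_alternative_introns(tss_gene)
        assert len(alts) == 2
        assert remove_alt_start_introns(tss_gene, alts) == []

    def test_internal_cassette_untouched(self, ce_gene):
        alts = find_alternative_introns(ce_gene)
        assert remove_alt_start_introns(ce_gene, alts) == alts

    def test_mixed_gene_keeps_only_cassette(self, tss_plus_cassette_gene):
        g = tss_plus_cassette_gene
        kept = remove_alt_start_introns(g, find_alternative_introns(g))
        assert {a.interval.coords() for a in kept} == {
            (300, 400),
            (500, 600),
            (300, 600),
        }

    def test_first_intron_a5ss_is_not_mistaken_for_tss(self):
        # both isoforms share the transcription start; only the donor differs
        g = make_gene(
            "fa5",
            [
                [(0, 100), (200, 300)],
                [(0, 150), (200, 300)],
            ],
        )
        alts = find_alternative_introns(g)
        assert remove_alt_start_introns(g, alts) == alts


class TestDecisionSites:
    def test_cassette_triple_forms_one_site(self, ce_gene):
        sites = cluster_decision_sites(find_alternative_introns(ce_gene))
        assert len(sites) == 1
        assert sites[0].span.coords() == (100, 400)

    def test_two_cassettes_form_two_sites(self, mass_gene):
        sites = cluster_decision_sites(find_alternative_introns(mass_gene))
        assert [s.span.coords() for s in sites] == [(100, 400), (500, 800)]

    def test_single_alternative_intron_is_its_own_site(self, a5ss_gene):
        sites = cluster_decision_sites(find_alternative_introns(a5ss_gene))
        assert len(sites) == 1
        assert sites[0].span.coords() == (100, 200)

    def test_site_spans_are_pairwise_disjoint(self, mass_gene):
        sites = cluster_decision_sites(find_alternative_introns(mass_gene))
        for i, a in enumerate(sites):
            for b in sites[i + 1 :]:
                assert not a.span.overlaps(b.span)

    def test_matches_brute_force_merging_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(1, 9))
            ivs = []
            for _ in range(n):
                s = int(rng.integers(0, 500))
                ivs.append((s, s + int(rng.integers(10, 200))))
            ivs = sorted(set(ivs))
            from immad.annotation_io import GenomicInterval
            from immad.splice_classifier import AlternativeIntron

            alts = [
                AlternativeIntron(GenomicInterval("chr1", s, e), frozenset({"t1"}))
                for s, e in ivs
            ]
            got = sorted(
                frozenset(m.interval.coords() for m in site.members)
                for site in cluster_decision_sites(alts)
            )
            assert got == brute_force_components(ivs)


class TestEventTypes:
    def test_cassette(self, ce_gene):
        site = cluster_decision_sites(find_alternative_introns(ce_gene))[0]
        assert event_type(site, ce_gene) == "CE"

    def test_mutually_exclusive(self, mxe_gene):
        site = cluster_decision_sites(find_alternative_introns(mxe_gene))[0]
        assert event_type(site, mxe_gene) == "MXE"

    def test_alternative_donor_and_acceptor(self, a5ss_gene, a3ss_gene):
        s5 = cluster_decision_sites(find_alternative_introns(a5ss_gene))[0]
        s3 = cluster_decision_sites(find_alternative_introns(a3ss_gene))[0]
        assert event_type(s5, a5ss_gene) == "A5SS"
        assert event_type(s3, a3ss_gene) == "A3SS"

    def test_minus_strand_swaps_donor_acceptor_call(self):
        g = make_gene(
            "m5",
            [
                [(0, 100), (200, 300)],
                [(0, 150), (200, 300)],
            ],
            strand="-",
        )
        site = cluster_decision_sites(find_alternative_introns(g))[0]
        # shared genomic end = shared 5' splice site on the minus strand
        assert event_type(site, g) == "A3SS"


class TestClassify:
    def test_cassette_gene_is_sass(self, ce_gene, toy_genome):
        cg = classify(ce_gene, toy_genome)
        assert cg.label == "SASS" and cg.n_sites == 1

    def test_two_site_gene_is_mass(self, mass_gene, toy_genome):
        cg = classify(mass_gene, toy_genome)
        assert cg.label == "MASS" and cg.n_sites == 2

    def test_pure_tss_gene_excluded(self, tss_gene, toy_genome):
        assert classify(tss_gene, toy_genome) is None

    def test_duplicate_isoform_never_changes_classification(
        self, ce_gene, mass_gene, toy_genome
    ):
        from immad.annotation_io import GeneModel, Transcript

        for g in (ce_gene, mass_gene):
            dup = Transcript("dup.t", g.transcripts[0].exons)
            g2 = GeneModel(g.id, g.transcripts + (dup,))
            a, b = classify(g, toy_genome), classify(g2, toy_genome)
            assert a.label == b.label
            assert [s.span.coords() for s in a.sites] == [
                s.span.coords() for s in b.sites
            ]


class TestFlankingIntrons:
    def test_cassette_site_contributes_its_three_introns(self, ce_gene, toy_genome):
        cg = classify(ce_gene, toy_genome)
        coords = {iv.coords() for iv, _ in cg.flanking_introns}
        assert coords == {(100, 200), (300, 400), (100, 400)}

    def test_shared_intron_coordinates_deduplicated(self, mass_gene, toy_genome):
        cg = classify(mass_gene, toy_genome)
        coords = [iv.coords() for iv, _ in cg.flanking_introns]
        assert len(coords) == len(set(coords))

    def test_sequences_are_sense_oriented(self, toy_genome):
        g_plus = make_gene("p", [[(0, 100), (200, 300)], [(0, 100), (250, 300)]])
        g_minus = make_gene(
            "m", [[(0, 100), (200, 300)], [(0, 100), (250, 300)]], strand="-"
        )
        from immad.annotation_io import fetch_sequence

        for g in (g_plus, g_minus):
            cg = classify(g, toy_genome)
            for iv, seq in cg.flanking_introns:
                assert seq == fetch_sequence(iv, toy_genome)

    def test_constitutive_regions_contribute_nothing(self, ce_gene, toy_genome):
        # the gene has 2 constitutive flanks; only site introns are returned
        cg = classify(ce_gene, toy_genome)
        assert len(cg.flanking_introns) == 3


class TestRandomGeneInvariants:
    def test_synthetic_population_obeys_site_count_rule(self):
        ds = generate_dataset(SimConfig(n_genes=150, seed=5))
        classified, excluded = classify_genes(ds.genes, Genome(ds.genome))
        assert not excluded
        for cg in classified:
            assert (cg.label == "MASS") == (cg.n_sites >= 2)
            assert cg.label == ds.labels[cg.id]
            for i, a in enumerate(cg.sites):
                for b in cg.sites[i + 1 :]:
                    assert not a.span.overlaps(b.span)
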