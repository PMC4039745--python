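"""Shared fixtures: hand-built event genes and a deterministic toy genome."""

from __future__ import annotations

import numpy as np
import pytest

from immad.annotation_io import GeneModel, Genome, GenomicInterval, Transcript


def make_gene(
    gene_id: str,
    isoform_exons: list[list[tuple[int, int]]],
    chrom: str = "chr1",
    strand: str = "+",
) -> GeneModel:
    transcripts = []
    for i, exons in enumerate(isoform_exons, 1):
        transcripts.append(
            Transcript(
                f"{gene_id}.t{i}",
                tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
            )
        )
    return GeneModel(gene_id, tuple(transcripts))


def random_genome(chroms: dict[str, int], seed: int = 7) -> Genome:
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return Genome(
        {
            name: "".join(bases[rng.integers(0, 4, size=length)])
            for name, length in chroms.items()
        }
    )


@pytest.fixture(scope="session")
def toy_genome() -> Genome:
    return random_genome({"chr1": 1200, "chr2": 1200})


@pytest.fixture
def ce_gene() -> GeneModel:
    """Single cassette exon (200,300): one decision site, SASS."""
    return make_gene(
        "ce1",
        [
            [(0, 100), (200, 300), (400, 500)],
            [(0, 100), (400, 500)],
        ],
    )


@pytest.fixture
def mxe_gene() -> GeneModel:
    """Two mutually exclusive middle exons: one site, four alternative introns."""
    return make_gene(
        "mxe1",
        [
            [(0, 100), (200, 300), (600, 700)],
            [(0, 100), (400, 500), (600, 700)],
        ],
    )


@pytest.fixture
def a5ss_gene() -> GeneModel:
    """Alternative donor: introns (100,200) and (150,200) share their 3' end."""
    return make_gene(
        "a5ss1",
        [
            [(0, 100), (200, 300)],
            [(0, 150), (200, 300)],
        ],
    )


@pytest.fixture
def a3ss_gene() -> GeneModel:
    """Alternative acceptor: introns (100,200) and (100,250) share their 5' end."""
    return make_gene(
        "a3ss1",
        [
            [(0, 100), (200, 300)],
            [(0, 100), (250, 300)],
        ],
    )


@pytest.fixture
def mass_gene() -> GeneModel:
    """Two independent cassette exons: two disjoint decision sites, MASS."""
    return make_gene(
        "mass1",
        [
            [(0, 100), (200, 300), (400, 500), (600, 700), (800, 900)],
            [(0, 100), (400, 500), (800, 900)],
        ],
    )


@pytest.fixture
def tss_gene() -> GeneModel:
    """Isoforms differing only in the first exon: excluded after TSS filtering."""
    return make_gene(
        "tss1",
        [
            [(0, 50), (200, 300)],
            [(100, 150), (200, 300)],
        ],
    )


@pytest.fixture
def tss_plus_cassette_gene() -> GeneModel:
    """A TSS-variant first intron plus an internal cassette exon."""
    return make_gene(
        "mix1",
        [
            [(0, 50), (200, 300), (400, 500), (600, 700)],
            [(100, 150), (200, 300), (600, 700)],
        ],
    )
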