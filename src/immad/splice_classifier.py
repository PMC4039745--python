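"""Alternative-intron detection and MASS/SASS gene classification.

An *alternative intron* is an intron (exact coordinate pair) present in some
but not all isoforms of a gene. Transitively overlapping alternative introns
are clustered into *decision sites* — the unit of one independent splicing
decision (a cassette exon, mutually exclusive exon pair, or alternative 5'/3'
splice site each produce one such overlapping cluster). Genes with a single
decision site are labelled SASS, genes with two or more non-overlapping sites
are labelled MASS. Alternative introns explained purely by alternative
transcription starts are removed before clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .annotation_io import (
    GeneModel,
    GenomicInterval,
    Transcript,
    derive_introns,
    fetch_sequence,
)

__all__ = [
    "AlternativeIntron",
    "DecisionSite",
    "ClassifiedGene",
    "find_alternative_introns",
    "remove_alt_start_introns",
    "cluster_decision_sites",
    "classify",
    "classify_genes",
    "extract_flanking_introns",
    "event_type",
]

MASS = "MASS"
SASS = "SASS"


@dataclass(frozen=True)
class AlternativeIntron:
    """An intron absent from at least one isoform, with its supporting isoforms."""

    interval: GenomicInterval
    supporting_isoforms: frozenset[str]


@dataclass(frozen=True)
class DecisionSite:
    """A maximal cluster of transitively overlapping alternative introns."""

    members: tuple[AlternativeIntron, ...]
    span: GenomicInterval

    @classmethod
    def from_members(cls, members: Sequence[AlternativeIntron]) -> "DecisionSite":
        ivs = [m.interval for m in members]
        span = GenomicInterval(
            ivs[0].chrom,
            min(iv.start for iv in ivs),
            max(iv.end for iv in ivs),
            ivs[0].strand,
        )
        ordered = tuple(sorted(members, key=lambda m: m.interval.coords()))
        return cls(ordered, span)

    @property
    def member_coords(self) -> set[tuple[int, int]]:
        return {m.interval.coords() for m in self.members}


@dataclass(frozen=True)
class ClassifiedGene:
    """A gene with its decision sites, MASS/SASS label and flanking introns."""

    gene: GeneModel
    sites: tuple[DecisionSite, ...]
    label: str
    flanking_introns: tuple[tuple[GenomicInterval, str], ...]

    @property
    def id(self) -> str:
        return self.gene.id

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def flanking_sequences(self) -> list[str]:
        return [seq for _, seq in self.flanking_introns]


def _intron_sets(g: GeneModel) -> dict[str, list[GenomicInterval]]:
    return {t.id: derive_introns(t) for t in g.transcripts}


def find_alternative_introns(g: GeneModel) -> list[AlternativeIntron]:
    """Introns whose exact (start, end) pair is absent from >= 1 isoform."""
    per_iso = _intron_sets(g)
    coord_sets = {tid: {iv.coords() for iv in ivs} for tid, ivs in per_iso.items()}
    seen: dict[tuple[int, int], GenomicInterval] = {}
    for ivs in per_iso.values():
        for iv in ivs:
            seen.setdefault(iv.coords(), iv)
    alts = []
    for coords, iv in sorted(seen.items()):
        supporters = frozenset(
            tid for tid, cs in coord_sets.items() if coords in cs
        )
        if len(supporters) < len(g.transcripts):
            alts.append(AlternativeIntron(iv, supporters))
    return alts


def _overlap_components(
    alts: Sequence[AlternativeIntron],
) -> list[list[AlternativeIntron]]:
    """Connected components under >= 1 base interval overlap (transitive)."""
    ordered = sorted(alts, key=lambda a: a.interval.coords())
    components: list[list[AlternativeIntron]] = []
    current: list[AlternativeIntron] = []
    current_end = -1
    for alt in ordered:
        if current and alt.interval.start < current_end:
            current.append(alt)
            current_end = max(current_end, alt.interval.end)
        else:
            if current:
                components.append(current)
            current = [alt]
            current_end = alt.interval.end
    if current:
        components.append(current)
    return components


def _three_prime_ss(iv: GenomicInterval) -> int:
    """3' splice-site coordinate in transcript orientation."""
    return iv.end if iv.strand == "+" else iv.start


def remove_alt_start_introns(
    g: GeneModel, alts: Sequence[AlternativeIntron]
) -> list[AlternativeIntron]:
    """Drop alternative introns explained by alternative transcription starts.

    An overlap cluster of alternative introns is considered TSS-derived — and
    all its members removed — when (a) each member is the 5'-most intron of
    every isoform supporting it, (b) all members (and the first intron of every
    other intron-bearing isoform) share the same 3' splice site in transcript
    orientation, and (c) the supporting isoforms genuinely start at different
    positions (distinct first-exon 5' ends), i.e. the isoforms differ only in
    which first exon splices onto a common downstream exon. Condition (c)
    distinguishes a true alternative start from an alternative 5' splice site
    in the first intron, where the isoforms share one transcription start.
    Clusters mixing in any internal intron fail the test and pass through
    unchanged.
    """
    per_iso = _intron_sets(g)
    first_intron = {
        tid: ivs[0].coords() if ivs else None for tid, ivs in per_iso.items()
    }

    def _tss_coord(t: Transcript) -> int:
        return t.exons[0].start if t.strand == "+" else t.exons[-1].end

    tss_by_iso = {t.id: _tss_coord(t) for t in g.transcripts}
    kept: list[AlternativeIntron] = []
    for comp in _overlap_components(alts):
        tss_like = all(
            all(first_intron[tid] == m.interval.coords() for tid in m.supporting_isoforms)
            for m in comp
        )
        supporters_tss = {
            tss_by_iso[tid] for m in comp for tid in m.supporting_isoforms
        }
        three_prime = {_three_prime_ss(m.interval) for m in comp}
        if tss_like and len(three_prime) == 1 and len(supporters_tss) > 1:
            ss = next(iter(three_prime))
            member_supporters = set().union(
                *(m.supporting_isoforms for m in comp)
            )
            others_ok = True
            for t in g.transcripts:
                if t.id in member_supporters:
                    continue
                ivs = per_iso[t.id]
                if ivs and _three_prime_ss(ivs[0]) != ss:
                    others_ok = False
                    break
            if others_ok:
                continue  # whole cluster removed
        kept.extend(comp)
    return sorted(kept, key=lambda a: a.interval.coords())


def cluster_decision_sites(
    alts: Sequence[AlternativeIntron],
) -> list[DecisionSite]:
    """Cluster alternative introns into decision sites, ordered 5'->3'.

    Sites are the connected components of the >= 1-base-overlap relation,
    transitively closed; their spans are pairwise disjoint by construction.
    """
    sites = [DecisionSite.from_members(comp) for comp in _overlap_components(alts)]
    if sites and sites[0].span.strand == "-":
        sites.reverse()
    return sites


def classify(g: GeneModel, genome: Mapping[str, str] | None = None) -> ClassifiedGene | None:
    """Classify a multi-isoform gene as MASS or SASS.

    Returns ``None`` (the gene is excluded, not an error) when no alternative
    intron survives the alternative-transcription-start filter. With a genome
    the flanking-intron sequences are attached; without one they are empty
    strings.
    """
    alts = find_alternative_introns(g)
    alts = remove_alt_start_introns(g, alts)
    if not alts:
        return None
    sites = cluster_decision_sites(alts)
    label = MASS if len(sites) >= 2 else SASS
    flanking = extract_flanking_introns(g, sites, genome)
    return ClassifiedGene(g, tuple(sites), label, tuple(flanking))


def classify_genes(
    genes: Iterable[GeneModel], genome: Mapping[str, str] | None = None
) -> tuple[list[ClassifiedGene], list[str]]:
    """Classify many genes; returns (classified, excluded_gene_ids)."""
    classified, excluded = [], []
    for g in genes:
        cg = classify(g, genome)
        if cg is None:
            excluded.append(g.id)
        else:
            classified.append(cg)
    return classified, excluded


def _constitutive_exon_coords(g: GeneModel) -> set[tuple[int, int]]:
    exon_sets = [{e.coords() for e in t.exons} for t in g.transcripts]
    return set.intersection(*exon_sets)


def extract_flanking_introns(
    g: GeneModel,
    sites: Sequence[DecisionSite],
    genome: Mapping[str, str] | None = None,
) -> list[tuple[GenomicInterval, str]]:
    """Introns flanking alternate exons, deduplicated by coordinates.

    An intron (from any isoform) qualifies when it belongs to a decision site
    or shares a boundary with an exon that is not present with identical
    boundaries in all isoforms. Introns discarded by the transcription-start
    filter never qualify. Sequences are returned in sense orientation.
    """
    site_coords = set().union(*(s.member_coords for s in sites)) if sites else set()
    all_alt_coords = {a.interval.coords() for a in find_alternative_introns(g)}
    tss_removed = all_alt_coords - {
        a.interval.coords()
        for a in remove_alt_start_introns(g, find_alternative_introns(g))
    }
    constitutive = _constitutive_exon_coords(g)
    alternate_exons = []
    for t in g.transcripts:
        for e in t.exons:
            if e.coords() not in constitutive:
                alternate_exons.append(e.coords())
    alt_boundaries = set()
    for s, e in alternate_exons:
        alt_boundaries.add(s)
        alt_boundaries.add(e)

    chosen: dict[tuple[int, int], GenomicInterval] = {}
    for t in g.transcripts:
        for iv in derive_introns(t):
            c = iv.coords()
            if c in tss_removed:
                continue
            if c in site_coords or iv.end in alt_boundaries or iv.start in alt_boundaries:
                chosen.setdefault(c, iv)
    result = []
    for c in sorted(chosen):
        iv = chosen[c]
        seq = fetch_sequence(iv, genome) if genome is not None else ""
        result.append((iv, seq))
    return result


def event_type(site: DecisionSite, g: GeneModel) -> str:
    """Classify a decision site as CE, MXE, A5SS, A3SS or complex.

    The classification is in transcript orientation: members sharing only
    their 3' splice site are A5SS (the donor varies), members sharing only
    their 5' splice site are A3SS (the acceptor varies).
    """
    coords = sorted(site.member_coords)
    strand = site.span.strand
    exon_coords = {e.coords() for t in g.transcripts for e in t.exons}

    # Cassette exon: two chained introns bridged by an exon, plus one member
    # spanning both (the skipping intron).
    for a0, a1 in coords:
        for b0, b1 in coords:
            if a1 < b0 and (a1, b0) in exon_coords and (a0, b1) in site.member_coords:
                return "CE"

    if len(coords) == 2:
        (a0, a1), (b0, b1) = coords
        shares_start = a0 == b0 and a1 != b1
        shares_end = a1 == b1 and a0 != b0
        if shares_start:
            return "A3SS" if strand == "+" else "A5SS"
        if shares_end:
            return "A5SS" if strand == "+" else "A3SS"

    # Mutually exclusive exons: two disjoint internal exons, never in the same
    # isoform, each flanked on both sides by member introns.
    internal = []
    for s, e in sorted(exon_coords):
        if site.span.start <= s and e <= site.span.end:
            flanked_left = any(i1 == s for _, i1 in coords)
            flanked_right = any(i0 == e for i0, _ in coords)
            if flanked_left and flanked_right:
                internal.append((s, e))
    if len(internal) == 2:
        (x0, x1), (y0, y1) = internal
        disjoint = x1 <= y0 or y1 <= x0
        never_together = not any(
            (x0, x1) in {e.coords() for e in t.exons}
            and (y0, y1) in {e.coords() for e in t.exons}
            for t in g.transcripts
        )
        if disjoint and never_together:
            return "MXE"
    return "complex"
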