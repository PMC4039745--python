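"""Gene-model and genome sequence I/O.

Internal coordinates are 0-based half-open throughout the package; GFF3 files
are read and written with the standard 1-based inclusive convention. All
sequence extraction is in *transcript sense orientation*: intervals on the
minus strand are reverse-complemented, so downstream motif scanning always
sees the pre-mRNA sense strand.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AnnotationError",
    "GFF3ParseError",
    "StructuralError",
    "GenomicInterval",
    "Transcript",
    "GeneModel",
    "Genome",
    "read_gene_models",
    "derive_introns",
    "fetch_sequence",
    "write_gene_models_gff3",
    "write_bed6",
    "write_fasta",
]


class AnnotationError(ValueError):
    """Base class for annotation problems."""


class GFF3ParseError(AnnotationError):
    """Raised when a GFF3 file cannot be parsed."""


class StructuralError(AnnotationError):
    """Raised when the gene/mRNA/exon hierarchy is inconsistent."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on one strand of a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Overlap by at least one base (strand-blind, same chromosome)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def coords(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class Transcript:
    """One isoform: an ordered, disjoint list of exons on a single strand."""

    id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise StructuralError(f"transcript {self.id} has no exons")
        object.__setattr__(self, "exons", tuple(sorted(self.exons, key=lambda e: e.start)))
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise StructuralError(
                f"transcript {self.id} mixes chromosomes/strands: {chroms}, {strands}"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise StructuralError(
                    f"transcript {self.id} has overlapping exons "
                    f"{a.coords()} and {b.coords()}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more transcript isoforms on one chromosome/strand."""

    id: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise StructuralError(f"gene {self.id} has no transcripts")
        object.__setattr__(self, "transcripts", tuple(self.transcripts))
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise StructuralError(
                f"gene {self.id} mixes chromosomes/strands across isoforms"
            )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def length(self) -> int:
        return self.span.length


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Genome(Mapping[str, str]):
    """A genome as an uppercase chromosome-id -> sequence mapping."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: str(seq).upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "Genome":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __iter__(self):
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)


def derive_introns(t: Transcript) -> list[GenomicInterval]:
    """Gaps between consecutive exons, ordered 5'->3' in transcript orientation.

    A single-exon transcript yields an empty list. On the minus strand the
    genomically last gap is the transcript's first intron, so the list is
    reversed relative to genomic order.
    """
    introns = [
        GenomicInterval(t.chrom, a.end, b.start, t.strand)
        for a, b in zip(t.exons, t.exons[1:])
    ]
    if t.strand == "-":
        introns.reverse()
    return introns


def fetch_sequence(iv: GenomicInterval, genome: Mapping[str, str]) -> str:
    """Extract the sense-orientation sequence of an interval.

    Minus-strand intervals are reverse-complemented. Raises ``KeyError`` for an
    unknown chromosome and ``IndexError`` for out-of-bounds coordinates.
    """
    if iv.chrom not in genome:
        raise KeyError(f"unknown chromosome {iv.chrom!r}")
    chrom_seq = genome[iv.chrom]
    if iv.end > len(chrom_seq):
        raise IndexError(
            f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds contig length "
            f"{len(chrom_seq)}"
        )
    seq = chrom_seq[iv.start : iv.end].upper()
    return _revcomp(seq) if iv.strand == "-" else seq


def read_gene_models(
    gff3_path: str | os.PathLike, min_isoforms: int = 2
) -> list[GeneModel]:
    """Read gene models from GFF3, keeping genes with >= min_isoforms transcripts.

    Expects the conventional gene -> mRNA -> exon hierarchy with ID/Parent
    attributes. Coordinates are converted to 0-based half-open and exons sorted
    by start. Malformed GFF3 raises :class:`GFF3ParseError`; an exon whose
    Parent is not an mRNA of a gene raises :class:`StructuralError`.
    """
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFF3ParseError(
                    f"{gff3_path}: line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise GFF3ParseError(
                    f"{gff3_path}: line {lineno}: non-integer coordinates"
                ) from None
            if start < 1 or end < start:
                raise GFF3ParseError(
                    f"{gff3_path}: line {lineno}: invalid coordinate range "
                    f"{start}..{end}"
                )
    try:
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted exception types
        raise GFF3ParseError(f"cannot parse GFF3 {gff3_path}: {exc}") from exc

    transcript_ids = {
        f.id for f in db.all_features() if f.featuretype in ("mRNA", "transcript")
    }
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        if not parents or not any(p in transcript_ids for p in parents):
            raise StructuralError(
                f"exon at {exon.seqid}:{exon.start}-{exon.end} has no mRNA parent"
            )

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        transcripts = []
        for mrna in db.children(gene, featuretype=("mRNA", "transcript"), level=1):
            exons = [
                GenomicInterval(ex.seqid, ex.start - 1, ex.end, ex.strand)
                for ex in db.children(mrna, featuretype="exon", level=1)
            ]
            if exons:
                transcripts.append(Transcript(mrna.id, tuple(exons)))
        if len(transcripts) >= min_isoforms:
            genes.append(GeneModel(gene.id, tuple(transcripts)))
    return genes


def write_gene_models_gff3(
    genes: Iterable[GeneModel], path: str | os.PathLike
) -> None:
    """Write gene models as GFF3 (1-based inclusive, gene/mRNA/exon)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            span = g.span
            fh.write(
                f"{g.chrom}\timmad\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{g.strand}\t.\tID={g.id}\n"
            )
            for t in g.transcripts:
                ts = t.span
                fh.write(
                    f"{g.chrom}\timmad\tmRNA\t{ts.start + 1}\t{ts.end}\t.\t"
                    f"{g.strand}\t.\tID={t.id};Parent={g.id}\n"
                )
                for i, ex in enumerate(t.exons, 1):
                    fh.write(
                        f"{g.chrom}\timmad\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                        f"{g.strand}\t.\tID={t.id}.exon{i};Parent={t.id}\n"
                    )


def write_bed6(
    intervals: Sequence[GenomicInterval],
    path: str | os.PathLike,
    names: Sequence[str] | None = None,
) -> None:
    """Write intervals as BED6 (0-based half-open, as BED requires)."""
    if names is not None and len(names) != len(intervals):
        raise ValueError("names must align with intervals")
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region{i + 1}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | os.PathLike
) -> None:
    """Write (id, sequence) pairs as wrapped FASTA."""
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")
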