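"""Synthetic gene models with planted intronic motifs and tandem repeats.

Generates multi-isoform gene models (cassette exons, mutually exclusive
exons, alternative 5'/3' splice sites), a matching genome sequence, and a
truth table of every planted motif occurrence, so the whole discovery
pipeline can be exercised end to end without external annotation downloads.

Genes are built exon by exon in transcript sense space, then mirrored onto
the minus strand for roughly half of them. MASS genes receive two or three
non-overlapping alternative regions, SASS genes exactly one. Intron sequences
are drawn i.i.d. at a configurable GC content; planted motifs are written
over background bases at Poisson rates scaled by a fold factor in the target
group's flanking introns; repeats are inserted as exact tandem arrays.
Everything is driven by a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation_io import (
    GeneModel,
    GenomicInterval,
    Transcript,
    write_fasta,
    write_gene_models_gff3,
)
from .distance_analysis import EmpiricalDistribution
from .motif_tools import MotifGroup
from .splice_classifier import ClassifiedGene

__all__ = [
    "PlantedMotif",
    "RepeatSpec",
    "SimConfig",
    "SimulatedDataset",
    "generate_dataset",
    "random_introns",
    "plant_motif_in_seqs",
    "empirical_length_laws",
]

_EVENTS = ("CE", "MXE", "A5SS", "A3SS")


@dataclass(frozen=True)
class PlantedMotif:
    """A motif to enrich in one gene group's flanking introns.

    ``rate`` is the Poisson insertion rate per k-mer window in the non-target
    group; the target group receives ``fold`` times that rate. With
    ``target_group="both"`` both groups get the base rate.
    """

    consensus: str
    target_group: str = "MASS"  # MASS | SASS | both
    fold: float = 3.0
    rate: float = 0.005

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold must be positive")
        if self.target_group not in ("MASS", "SASS", "both"):
            raise ValueError(f"bad target_group {self.target_group!r}")


@dataclass(frozen=True)
class RepeatSpec:
    """An exact tandem array to insert into one flanking intron."""

    unit: str
    n_copies: int
    target_group: str = "MASS"


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic genome.

    Defaults reflect the nematode data the pipeline targets: about a third of
    alternatively spliced genes carry multiple decision sites, cassette exons
    dominate the event mix, introns follow a short log-normal law (median 65
    bases) and are AT-rich (GC ~ 0.32).
    """

    n_genes: int = 200
    p_mass: float = 0.32
    event_mix: dict[str, float] = field(
        default_factory=lambda: {"CE": 0.6, "MXE": 0.1, "A5SS": 0.15, "A3SS": 0.15}
    )
    intron_length_law: tuple[str, dict] = (
        "lognormal",
        {"median": 65.0, "sigma": 0.7},
    )
    gc_content: float = 0.32
    planted: tuple[PlantedMotif, ...] = ()
    repeats: tuple[RepeatSpec, ...] = ()
    seed: int = 0
    min_intron: int = 30
    exon_length_median: float = 120.0
    exon_length_sigma: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_mass <= 1.0):
            raise ValueError("p_mass must be in [0, 1]")
        if not math.isclose(sum(self.event_mix.values()), 1.0, abs_tol=1e-9):
            raise ValueError("event_mix proportions must sum to 1")
        if set(self.event_mix) - set(_EVENTS):
            raise ValueError(f"unknown event types in mix: {self.event_mix}")
        self.planted = tuple(self.planted)
        self.repeats = tuple(self.repeats)


@dataclass
class SimulatedDataset:
    """In-memory result of a simulation, plus file paths when written."""

    genes: list[GeneModel]
    genome: dict[str, str]
    truth: pd.DataFrame
    labels: dict[str, str]
    flanking: dict[str, list[GenomicInterval]]  # sense-space genomic introns
    gff3_path: str | None = None
    fasta_path: str | None = None
    truth_path: str | None = None


def _draw_length(rng: np.random.Generator, median: float, sigma: float, lo: int) -> int:
    return max(lo, int(round(rng.lognormal(math.log(median), sigma))))


def _intron_len(rng: np.random.Generator, cfg: SimConfig) -> int:
    law, params = cfg.intron_length_law
    if law == "lognormal":
        return _draw_length(rng, params["median"], params["sigma"], cfg.min_intron)
    if law == "fixed":
        return int(params["length"])
    raise ValueError(f"unknown intron length law {law!r}")


def _exon_len(rng: np.random.Generator, cfg: SimConfig) -> int:
    return _draw_length(rng, cfg.exon_length_median, cfg.exon_length_sigma, 20)


@dataclass
class _SiteLayout:
    """One alternative region in sense space, between two constitutive exons."""

    event: str
    start: int
    end: int
    # per variant: (left exon end shift, right exon start shift, internal exons)
    variants: list[tuple[int, int, list[tuple[int, int]]]]
    intron_intervals: list[tuple[int, int]]  # union across variants


def _build_site(
    rng: np.random.Generator, cfg: SimConfig, event: str, start: int
) -> _SiteLayout:
    if event == "CE":
        l1, l2 = _intron_len(rng, cfg), _intron_len(rng, cfg)
        e = _exon_len(rng, cfg)
        end = start + l1 + e + l2
        variants = [
            (0, 0, [(start + l1, start + l1 + e)]),  # inclusion
            (0, 0, []),  # skipping
        ]
        introns = [
            (start, start + l1),
            (start + l1 + e, end),
            (start, end),
        ]
    elif event == "MXE":
        l1, lm, l2 = (_intron_len(rng, cfg) for _ in range(3))
        ex, ey = _exon_len(rng, cfg), _exon_len(rng, cfg)
        x = (start + l1, start + l1 + ex)
        y = (x[1] + lm, x[1] + lm + ey)
        end = y[1] + l2
        variants = [
            (0, 0, [x]),  # include X
            (0, 0, [y]),  # include Y
        ]
        introns = [
            (start, x[0]),
            (x[1], end),
            (start, y[0]),
            (y[1], end),
        ]
    elif event == "A5SS":
        d = max(6, _exon_len(rng, cfg) // 4)
        li = _intron_len(rng, cfg)
        end = start + d + li
        # variant 0: left exon extended by d; variant 1: plain boundary
        variants = [(d, 0, []), (0, 0, [])]
        introns = [(start + d, end), (start, end)]
    elif event == "A3SS":
        d = max(6, _exon_len(rng, cfg) // 4)
        li = _intron_len(rng, cfg)
        end = start + li + d
        # variant 0: right exon starts early (pulled into the block)
        variants = [(0, -d, []), (0, 0, [])]
        introns = [(start, end - d), (start, end)]
    else:
        raise ValueError(f"unknown event {event!r}")
    return _SiteLayout(event, start, end, variants, introns)


def _assemble_isoform(
    const_exons: list[tuple[int, int]],
    sites: list[_SiteLayout],
    variant_choice: Sequence[int],
) -> list[tuple[int, int]]:
    """Build one isoform's exon list from backbone exons and variant picks."""
    exons = [list(const_exons[0])]
    for i, (site, choice) in enumerate(zip(sites, variant_choice)):
        left_shift, right_shift, internal = site.variants[choice]
        exons[-1][1] += left_shift
        for s, e in internal:
            exons.append([s, e])
        nxt = list(const_exons[i + 1])
        nxt[0] += right_shift
        exons.append(nxt)
    return [(s, e) for s, e in exons]


def _gene_structure(
    rng: np.random.Generator, cfg: SimConfig, gene_id: str, is_mass: bool
) -> tuple[list[list[tuple[int, int]]], list[_SiteLayout], int]:
    """Sense-space exon lists per isoform, site layouts, total gene length."""
    n_sites = 1 if not is_mass else int(rng.choice([2, 3], p=[0.7, 0.3]))
    events = [
        str(rng.choice(list(cfg.event_mix), p=list(cfg.event_mix.values())))
        for _ in range(n_sites)
    ]
    const_exons: list[tuple[int, int]] = []
    sites: list[_SiteLayout] = []
    cursor = 0
    first = _exon_len(rng, cfg)
    const_exons.append((cursor, cursor + first))
    cursor += first
    for event in events:
        site = _build_site(rng, cfg, event, cursor)
        sites.append(site)
        cursor = site.end
        e = _exon_len(rng, cfg)
        const_exons.append((cursor, cursor + e))
        cursor += e

    n_iso = int(rng.integers(2, 5))
    combos: list[tuple[int, ...]] = [
        tuple([0] * n_sites),
        tuple([1] * n_sites),
    ]
    attempts = 0
    while len(combos) < n_iso and attempts < 20:
        cand = tuple(int(rng.integers(0, 2)) for _ in range(n_sites))
        if cand not in combos:
            combos.append(cand)
        attempts += 1
    isoforms = [_assemble_isoform(const_exons, sites, combo) for combo in combos]
    return isoforms, sites, cursor


def random_introns(
    n: int, length: int, gc: float, rng: np.random.Generator
) -> list[str]:
    """Draw n i.i.d. background sequences of a given length and GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    return [
        "".join(bases[rng.choice(4, size=length, p=p)]) for _ in range(n)
    ]


def plant_motif_in_seqs(
    seqs: Sequence[str],
    motif: MotifGroup,
    rate: float,
    rng: np.random.Generator,
) -> tuple[list[str], list[tuple[int, int, str]]]:
    """Overwrite background bases with motif copies at a Poisson rate per window.

    Returns the modified sequences and (seq_index, offset, realization) truth
    records. Plants avoid overlapping one another (up to 50 placement tries
    per copy).
    """
    members = sorted(motif.members)
    out = []
    truth = []
    for si, seq in enumerate(seqs):
        chars = list(seq)
        width_min = min(len(m) for m in members)
        windows = max(0, len(seq) - width_min + 1)
        n_plants = int(rng.poisson(rate * windows))
        occupied: list[tuple[int, int]] = []
        for _ in range(n_plants):
            member = members[int(rng.integers(0, len(members)))]
            if len(seq) < len(member):
                continue
            for _try in range(50):
                pos = int(rng.integers(0, len(seq) - len(member) + 1))
                if all(
                    pos + len(member) <= s or e <= pos for s, e in occupied
                ):
                    chars[pos : pos + len(member)] = list(member)
                    occupied.append((pos, pos + len(member)))
                    truth.append((si, pos, member))
                    break
        out.append("".join(chars))
    return out, truth


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _mirror(iv: tuple[int, int], total: int) -> tuple[int, int]:
    return (total - iv[1], total - iv[0])


def generate_dataset(
    cfg: SimConfig, out_prefix: str | None = None
) -> SimulatedDataset:
    """Generate gene models, genome and truth table from a simulation config.

    With ``out_prefix`` the dataset is also written as ``<prefix>.gff3``,
    ``<prefix>.fa`` and ``<prefix>.truth.tsv``.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.planted:
        targets = {p.target_group for p in cfg.planted}
        if "MASS" in targets and cfg.p_mass == 0:
            raise ValueError("motif targets MASS but p_mass is 0")
        if "SASS" in targets and cfg.p_mass == 1:
            raise ValueError("motif targets SASS but p_mass is 1")

    pad = 50
    genes: list[GeneModel] = []
    genome: dict[str, str] = {}
    labels: dict[str, str] = {}
    flanking: dict[str, list[GenomicInterval]] = {}
    # per gene: sense-space intron list, sense sequence (mutable), chrom meta
    sense_seqs: dict[str, list[str]] = {}
    sense_introns: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, int, str]] = {}  # chrom, total_len, strand

    for gi in range(cfg.n_genes):
        gene_id = f"g{gi + 1:04d}"
        is_mass = bool(rng.random() < cfg.p_mass)
        isoforms, sites, gene_len = _gene_structure(rng, cfg, gene_id, is_mass)
        strand = "+" if rng.random() < 0.5 else "-"
        total = gene_len + 2 * pad
        chrom = f"chr_{gene_id}"

        # flanking introns = union of site intron intervals, deduplicated
        intron_ivs = sorted(
            {iv for site in sites for iv in site.intron_intervals}
        )
        sense_introns[gene_id] = intron_ivs
        labels[gene_id] = "MASS" if is_mass else "SASS"
        meta[gene_id] = (chrom, total, strand)

        # build transcripts in genomic coordinates
        transcripts = []
        for ti, exons in enumerate(isoforms):
            g_exons = []
            for s, e in exons:
                gs, ge = s + pad, e + pad
                if strand == "-":
                    gs, ge = _mirror((gs, ge), total)
                g_exons.append(GenomicInterval(chrom, gs, ge, strand))
            transcripts.append(Transcript(f"{gene_id}.t{ti + 1}", tuple(g_exons)))
        genes.append(GeneModel(gene_id, tuple(transcripts)))
        flanking[gene_id] = [
            GenomicInterval(
                chrom,
                *( _mirror((s + pad, e + pad), total) if strand == "-" else (s + pad, e + pad)),
                strand,
            )
            for s, e in intron_ivs
        ]

        # background sense-space sequence for the whole padded region
        sense_seqs[gene_id] = [random_introns(1, total, cfg.gc_content, rng)[0]]

    # --- tandem repeats -----------------------------------------------------
    truth_rows: list[dict] = []
    occupied: dict[str, list[tuple[int, int]]] = {g: [] for g in labels}

    def _genomic(gene_id: str, a: int, b: int) -> tuple[str, int, int, str]:
        """Sense-space padded coords -> genomic (chrom, start, end, strand)."""
        chrom, total, strand = meta[gene_id]
        if strand == "-":
            a, b = _mirror((a, b), total)
        return chrom, a, b, strand
    for spec in cfg.repeats:
        array = spec.unit * spec.n_copies
        candidates = [
            (gene_id, iv)
            for gene_id, ivs in sense_introns.items()
            if labels[gene_id] == spec.target_group
            for iv in ivs
            if iv[1] - iv[0] >= len(array)
        ]
        if not candidates:
            raise ValueError(
                f"no {spec.target_group} flanking intron can hold the "
                f"{len(array)}-base repeat array; increase intron lengths"
            )
        gene_id, iv = candidates[int(rng.integers(0, len(candidates)))]
        offset = int(rng.integers(0, iv[1] - iv[0] - len(array) + 1))
        pos = iv[0] + pad + offset
        seq = sense_seqs[gene_id][0]
        sense_seqs[gene_id][0] = seq[:pos] + array + seq[pos + len(array) :]
        occupied[gene_id].append((pos, pos + len(array)))
        chrom, gs, ge, strand = _genomic(gene_id, iv[0] + pad, iv[1] + pad)
        truth_rows.append(
            {
                "gene_id": gene_id,
                "chrom": chrom,
                "strand": strand,
                "kind": "repeat",
                "intron_start": gs,
                "intron_end": ge,
                "offset": offset,
                "sequence": array,
                "motif": spec.unit,
            }
        )

    # --- planted motifs -----------------------------------------------------
    pad_off = pad
    for planted in cfg.planted:
        motif = MotifGroup.from_consensus(planted.consensus)
        members = sorted(motif.members)
        w = min(len(m) for m in members)
        for gene_id, ivs in sense_introns.items():
            group = labels[gene_id]
            if planted.target_group != "both" and group == planted.target_group:
                rate = planted.rate * planted.fold
            else:
                rate = planted.rate
            seq = sense_seqs[gene_id][0]
            chars = list(seq)
            for s, e in ivs:
                a, b = s + pad_off, e + pad_off
                windows = max(0, (b - a) - w + 1)
                n_plants = int(rng.poisson(rate * windows))
                for _ in range(n_plants):
                    member = members[int(rng.integers(0, len(members)))]
                    if b - a < len(member):
                        continue
                    for _try in range(50):
                        pos = int(rng.integers(a, b - len(member) + 1))
                        if all(
                            pos + len(member) <= os or oe <= pos
                            for os, oe in occupied[gene_id]
                        ):
                            chars[pos : pos + len(member)] = list(member)
                            occupied[gene_id].append((pos, pos + len(member)))
                            chrom, gs, ge, strand = _genomic(gene_id, a, b)
                            truth_rows.append(
                                {
                                    "gene_id": gene_id,
                                    "chrom": chrom,
                                    "strand": strand,
                                    "kind": "motif",
                                    "intron_start": gs,
                                    "intron_end": ge,
                                    "offset": pos - a,
                                    "sequence": member,
                                    "motif": planted.consensus,
                                }
                            )
                            break
            sense_seqs[gene_id][0] = "".join(chars)

    # --- finalize genome ----------------------------------------------------
    for gene_id, (chrom, total, strand) in meta.items():
        seq = sense_seqs[gene_id][0]
        genome[chrom] = (
            seq if strand == "+" else seq.translate(_COMPLEMENT)[::-1]
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene_id",
            "chrom",
            "strand",
            "kind",
            "intron_start",
            "intron_end",
            "offset",
            "sequence",
            "motif",
        ],
    )
    ds = SimulatedDataset(genes, genome, truth, labels, flanking)
    if out_prefix is not None:
        ds.gff3_path = f"{out_prefix}.gff3"
        ds.fasta_path = f"{out_prefix}.fa"
        ds.truth_path = f"{out_prefix}.truth.tsv"
        write_gene_models_gff3(genes, ds.gff3_path)
        write_fasta(sorted(genome.items()), ds.fasta_path)
        truth.to_csv(ds.truth_path, sep="\t", index=False)
    return ds


def empirical_length_laws(
    genes: Sequence[ClassifiedGene],
) -> tuple[EmpiricalDistribution, EmpiricalDistribution]:
    """Empirical gene-length and flanking-intron-length distributions.

    Feeds the random inter-site null model so that simulated transcripts match
    the observed pool in total length and intron size.
    """
    if not genes:
        raise ValueError("need at least one gene")
    gene_lengths = [g.gene.length for g in genes]
    intron_lengths = [iv.length for g in genes for iv, _ in g.flanking_introns]
    if not intron_lengths:
        intron_lengths = gene_lengths
    return EmpiricalDistribution(gene_lengths), EmpiricalDistribution(intron_lengths)
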