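"""Gene-level co-occurrence analysis for heterologous motif pairs.

A gene "contains" a motif when at least one of its flanking introns carries
the motif at a frequency higher than expected from the motif's pooled
background density and the intron's length. This per-intron filter prevents
very large introns — which accumulate motif occurrences by chance — from
dominating the gene-level counts. Each unordered pair of distinct motifs is
then tested on a 2x2 gene-count table with a two-sided Fisher exact test,
Bonferroni-corrected over the number of pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from scipy import stats

from .motif_tools import MotifGroup, match_positions
from .splice_classifier import ClassifiedGene

__all__ = [
    "CoOccurrenceRecord",
    "motif_background_density",
    "overrepresented_in_intron",
    "cooccurrence_screen",
    "write_cooccurrence_tsv",
]


@dataclass
class CoOccurrenceRecord:
    """2x2 gene counts, odds ratio and corrected p for one motif pair."""

    pair: tuple[MotifGroup, MotifGroup]
    n_both: int
    n_only_a: int
    n_only_b: int
    n_neither: int
    odds_ratio: float
    p_raw: float
    p_corrected: float
    haldane_corrected: bool = False
    significant: bool = False

    @property
    def n_genes(self) -> int:
        return self.n_both + self.n_only_a + self.n_only_b + self.n_neither


def motif_background_density(
    introns: Sequence[str], m: MotifGroup
) -> float:
    """Pooled matches of a motif per window across a set of introns."""
    k_min = m.k_range[0]
    matches = sum(len(match_positions(seq, m)) for seq in introns)
    windows = sum(max(0, len(seq) - k_min + 1) for seq in introns)
    return matches / windows if windows else 0.0


def overrepresented_in_intron(
    intron: str, m: MotifGroup, background_density: float
) -> bool:
    """True iff the intron carries more copies than its length predicts."""
    k_min = m.k_range[0]
    observed = len(match_positions(intron, m))
    expected = max(0, len(intron) - k_min + 1) * background_density
    return observed > expected


def _odds_ratio(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    if b == 0 or c == 0:
        # ad/bc undefined; Haldane-Anscombe 0.5 continuity correction, flagged
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)), True
    return (a * d) / (b * c), False


def cooccurrence_screen(
    genes: Sequence[ClassifiedGene],
    motifs: Sequence[MotifGroup],
    alpha: float = 0.01,
    exclude_genes: Sequence[str] = (),
) -> list[CoOccurrenceRecord]:
    """Test every unordered heterologous motif pair for gene-level co-occurrence.

    ``exclude_genes`` supports robustness re-tests that drop individual genes
    (e.g. one gene carrying a private tandem repeat). Records are sorted by
    descending odds ratio among significant ones first, mirroring a results
    table ordering.
    """
    if len(motifs) < 2:
        raise ValueError("need at least two motifs")
    excluded = set(exclude_genes)
    analyzed = [g for g in genes if g.id not in excluded]
    pooled_introns = [seq for g in analyzed for seq in g.flanking_sequences]
    density = {m.consensus: motif_background_density(pooled_introns, m) for m in motifs}

    presence: dict[str, set[str]] = {m.consensus: set() for m in motifs}
    for g in analyzed:
        for m in motifs:
            if any(
                overrepresented_in_intron(seq, m, density[m.consensus])
                for seq in g.flanking_sequences
            ):
                presence[m.consensus].add(g.id)

    n_pairs = len(motifs) * (len(motifs) - 1) // 2
    n_genes = len(analyzed)
    records = []
    for ma, mb in combinations(motifs, 2):
        in_a = presence[ma.consensus]
        in_b = presence[mb.consensus]
        both = len(in_a & in_b)
        only_a = len(in_a - in_b)
        only_b = len(in_b - in_a)
        neither = n_genes - both - only_a - only_b
        odds, haldane = _odds_ratio(both, only_a, only_b, neither)
        p_raw = float(
            stats.fisher_exact([[both, only_a], [only_b, neither]])[1]
        )
        p_corr = min(1.0, p_raw * n_pairs)
        records.append(
            CoOccurrenceRecord(
                (ma, mb),
                both,
                only_a,
                only_b,
                neither,
                odds,
                p_raw,
                p_corr,
                haldane_corrected=haldane,
                significant=(p_corr < alpha and odds > 1),
            )
        )
    records.sort(key=lambda r: (not r.significant, -r.odds_ratio))
    return records


def write_cooccurrence_tsv(records: Sequence[CoOccurrenceRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "motif_a\tmotif_b\tn_both\tn_only_a\tn_only_b\tn_neither\t"
            "odds_ratio\tp_corrected\tsignificant\n"
        )
        for r in records:
            fh.write(
                f"{r.pair[0].consensus}\t{r.pair[1].consensus}\t{r.n_both}\t"
                f"{r.n_only_a}\t{r.n_only_b}\t{r.n_neither}\t"
                f"{r.odds_ratio:.4g}\t{r.p_corrected:.4g}\t{int(r.significant)}\n"
            )
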