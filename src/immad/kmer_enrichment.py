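"""Oligomer counting and enrichment statistics between two intron groups.

The screen counts every possible pentamer, hexamer and heptamer in overlapping
windows (step 1, sense strand) and compares per-window frequencies between two
groups of sequences with two-sided Fisher exact tests on the window counts
(occurrences vs other windows). Multiple testing is controlled with a
Bonferroni multiplier equal to the oligomer universe size 4^k (1024 for
pentamers, 4096 for hexamers, 16384 for heptamers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats
from scipy.special import gammaln

from .motif_tools import MotifGroup, match_positions
from .splice_classifier import ClassifiedGene

__all__ = [
    "KmerCountTable",
    "EnrichmentRecord",
    "GeneFrequencyRecord",
    "PooledComparison",
    "ListOverlapResult",
    "kmer_universe_size",
    "count_kmers",
    "enrichment_screen",
    "gene_frequency_test",
    "pooled_motif_comparison",
    "per_motif_comparison",
    "heptamer_to_hexamers",
    "list_overlap_enrichment",
    "write_enrichment_tsv",
]


def kmer_universe_size(k: int) -> int:
    """Number of possible DNA oligomers of length k (the Bonferroni multiplier)."""
    return 4**k


@dataclass
class KmerCountTable:
    """Occurrence counts of all observed k-mers plus the valid-window total."""

    k: int
    counts: dict[str, int]
    total_windows: int


_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(index: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[index % 4])
        index //= 4
    return "".join(reversed(out))


def count_kmers(seqs: Iterable[str], k: int) -> KmerCountTable:
    """Count overlapping k-mer windows across sequences on the sense strand.

    Windows containing any non-ACGT character (N and friends) are skipped and
    excluded from ``total_windows``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = np.zeros(4**k, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    total = 0
    for seq in seqs:
        if len(seq) < k:
            continue
        codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        windows = sliding_window_view(codes, k)
        valid = (windows >= 0).all(axis=1)
        total += int(valid.sum())
        if valid.any():
            idx = (windows[valid].astype(np.int64) * powers).sum(axis=1)
            np.add.at(counts, idx, 1)
    nonzero = np.nonzero(counts)[0]
    return KmerCountTable(
        k, {_decode(int(i), k): int(counts[i]) for i in nonzero}, total
    )


@dataclass
class EnrichmentRecord:
    """Per-oligomer window counts, frequency ratio and Fisher test result."""

    oligomer: str
    count_a: int
    windows_a: int
    count_b: int
    windows_b: int
    ratio: float
    p_raw: float
    p_corrected: float
    significant: bool = False


def _fisher_two_sided(ca: int, wa: int, cb: int, wb: int) -> float:
    """Exact two-sided Fisher p, summing the hypergeometric pmf over its support.

    Identical to the conditional-exact test on [[ca, wa-ca], [cb, wb-cb]]:
    all tables with the same margins whose probability does not exceed that of
    the observed one (up to a small relative tolerance for float ties).
    """
    total_hits = ca + cb
    lo = max(0, total_hits - wb)
    hi = min(total_hits, wa)
    x = np.arange(lo, hi + 1)
    n, k, m = wa + wb, total_hits, wa
    log_pmf = (
        gammaln(k + 1)
        - gammaln(x + 1)
        - gammaln(k - x + 1)
        + gammaln(n - k + 1)
        - gammaln(m - x + 1)
        - gammaln(n - k - m + x + 1)
        - (gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1))
    )
    pmf = np.exp(log_pmf)
    p_obs = pmf[ca - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def _frequency_ratio(ca: int, wa: int, cb: int, wb: int) -> float:
    fa = ca / wa
    fb = cb / wb
    if fb == 0:
        return float("inf") if fa > 0 else float("nan")
    return fa / fb


def enrichment_screen(
    group_a: Sequence[str],
    group_b: Sequence[str],
    k: int,
    alpha_corrected: float = 1e-5,
) -> list[EnrichmentRecord]:
    """Screen all observed k-mers for enrichment in group A over group B.

    For each oligomer a two-sided Fisher exact test is computed on the 2x2
    table [[count_a, windows_a - count_a], [count_b, windows_b - count_b]];
    p-values are Bonferroni-corrected by the universe size 4^k. Records with
    corrected p below ``alpha_corrected`` and frequency ratio > 1 are flagged
    significant. Oligomers absent from both groups are omitted (their p is 1).
    Results are sorted by corrected p-value, then oligomer.
    """
    if not group_a or not group_b:
        raise ValueError("both sequence groups must be non-empty")
    ta = count_kmers(group_a, k)
    tb = count_kmers(group_b, k)
    if ta.total_windows == 0 or tb.total_windows == 0:
        raise ValueError("a group contributes zero k-mer windows (degenerate input)")
    multiplier = kmer_universe_size(k)
    records = []
    for oligo in sorted(set(ta.counts) | set(tb.counts)):
        ca = ta.counts.get(oligo, 0)
        cb = tb.counts.get(oligo, 0)
        p_raw = _fisher_two_sided(ca, ta.total_windows, cb, tb.total_windows)
        p_corr = min(1.0, p_raw * multiplier)
        ratio = _frequency_ratio(ca, ta.total_windows, cb, tb.total_windows)
        records.append(
            EnrichmentRecord(
                oligo,
                ca,
                ta.total_windows,
                cb,
                tb.total_windows,
                ratio,
                p_raw,
                p_corr,
                significant=(p_corr < alpha_corrected and ratio > 1),
            )
        )
    records.sort(key=lambda r: (r.p_corrected, r.oligomer))
    return records


@dataclass
class GeneFrequencyRecord:
    """Gene-level presence/absence comparison for one motif group."""

    motif: MotifGroup
    genes_with_a: int
    genes_total_a: int
    genes_with_b: int
    genes_total_b: int
    p_raw: float
    p_corrected: float


def _gene_has_motif(gene: ClassifiedGene, motif: MotifGroup) -> bool:
    return any(match_positions(seq, motif) for seq in gene.flanking_sequences)


def gene_frequency_test(
    genes_a: Sequence[ClassifiedGene],
    genes_b: Sequence[ClassifiedGene],
    motifs: Sequence[MotifGroup],
) -> list[GeneFrequencyRecord]:
    """Compare, per motif, the fraction of genes harboring >= 1 copy.

    This control is insensitive to the number of motif repeats within a gene.
    Fisher exact test on gene presence/absence, Bonferroni over the number of
    motifs tested.
    """
    na, nb = len(genes_a), len(genes_b)
    n_tests = max(1, len(motifs))
    records = []
    for motif in motifs:
        wa = sum(_gene_has_motif(g, motif) for g in genes_a)
        wb = sum(_gene_has_motif(g, motif) for g in genes_b)
        p_raw = float(
            stats.fisher_exact([[wa, na - wa], [wb, nb - wb]])[1]
        )
        records.append(
            GeneFrequencyRecord(
                motif, wa, na, wb, nb, p_raw, min(1.0, p_raw * n_tests)
            )
        )
    return records


@dataclass
class PooledComparison:
    """Pooled motif-frequency comparison between two intron groups."""

    ratio: float
    p: float
    count_a: int
    windows_a: int
    count_b: int
    windows_b: int


def _pooled_counts(
    motifs: Sequence[MotifGroup], introns: Sequence[str]
) -> tuple[int, int]:
    count = 0
    windows = 0
    for m in motifs:
        width = len(m.consensus)
        for seq in introns:
            count += len(match_positions(seq, m))
            windows += max(0, len(seq) - width + 1)
    return count, windows


def pooled_motif_comparison(
    motifs: Sequence[MotifGroup],
    introns_a: Sequence[str],
    introns_b: Sequence[str],
) -> PooledComparison:
    """Overall motif-pool frequency ratio between groups plus Fisher p.

    Match counts of all motifs are pooled over all windows per group; used for
    the conservation comparison on ortholog intron sets and for the
    scrambled-motif control.
    """
    if not motifs or not introns_a or not introns_b:
        raise ValueError("motifs and both intron groups must be non-empty")
    ca, wa = _pooled_counts(motifs, introns_a)
    cb, wb = _pooled_counts(motifs, introns_b)
    if wa == 0 or wb == 0:
        raise ValueError("a group contributes zero windows")
    p = _fisher_two_sided(ca, wa, cb, wb)
    return PooledComparison(_frequency_ratio(ca, wa, cb, wb), p, ca, wa, cb, wb)


def per_motif_comparison(
    motifs: Sequence[MotifGroup],
    introns_a: Sequence[str],
    introns_b: Sequence[str],
) -> list[PooledComparison]:
    """Per-motif frequency ratios and Fisher p-values (one pool per motif)."""
    return [pooled_motif_comparison([m], introns_a, introns_b) for m in motifs]


def heptamer_to_hexamers(motif_list: Sequence[str]) -> list[str]:
    """Convert heptamers to their two constituent hexamers, passing 5/6-mers through.

    Used to compare a mixed-length motif list against published hexamer/pentamer
    splicing-regulatory-element lists; the result is deduplicated preserving
    first-seen order.
    """
    out: list[str] = []
    seen = set()
    for oligo in motif_list:
        oligo = oligo.upper()
        if len(oligo) == 7:
            derived = [oligo[:6], oligo[1:]]
        elif len(oligo) in (5, 6):
            derived = [oligo]
        else:
            raise ValueError(f"oligomer {oligo!r} outside length range 5-7")
        for d in derived:
            if d not in seen:
                seen.add(d)
                out.append(d)
    return out


@dataclass
class ListOverlapResult:
    """Overlap of two oligomer lists within a common universe.

    ``fold`` is observed overlap over the expected overlap
    |query|*|reference|/universe; ``odds_ratio`` is the sample odds ratio of
    the same 2x2 table. Both are reported because the two summaries differ
    whenever the lists are a non-trivial fraction of the universe.
    """

    overlap: int
    expected: float
    fold: float
    odds_ratio: float
    p: float


def list_overlap_enrichment(
    query: Sequence[str], reference: Sequence[str], universe_size: int
) -> ListOverlapResult:
    """Enrichment of a reference oligomer list within a query list."""
    q = set(o.upper() for o in query)
    r = set(o.upper() for o in reference)
    if universe_size < len(q | r):
        raise ValueError("universe smaller than the union of the lists")
    overlap = len(q & r)
    expected = len(q) * len(r) / universe_size
    fold = overlap / expected if expected > 0 else float("nan")
    a = overlap
    b = len(q) - overlap
    c = len(r) - overlap
    d = universe_size - len(q) - len(r) + overlap
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    p = float(stats.fisher_exact([[a, b], [c, d]])[1])
    return ListOverlapResult(overlap, expected, fold, odds, p)


def write_enrichment_tsv(records: Sequence[EnrichmentRecord], path) -> None:
    """Serialize enrichment records as TSV."""
    with open(path, "w") as fh:
        fh.write(
            "oligomer\tk\tcount_a\twindows_a\tcount_b\twindows_b\t"
            "ratio\tp_raw\tp_corrected\tsignificant\n"
        )
        for r in records:
            fh.write(
                f"{r.oligomer}\t{len(r.oligomer)}\t{r.count_a}\t{r.windows_a}\t"
                f"{r.count_b}\t{r.windows_b}\t{r.ratio:.6g}\t{r.p_raw:.6g}\t"
                f"{r.p_corrected:.6g}\t{int(r.significant)}\n"
            )
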