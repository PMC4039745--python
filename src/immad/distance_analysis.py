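"""Distance analyses: inter-site gaps, a simulated null, and inter-motif distances.

Three kinds of distances are measured. (1) The inter-site distance Δ between
consecutive splicing decision sites of a MASS gene, taken as the inner gap
between their spans. (2) A simulated null for Δ: transcripts are drawn from
empirical gene-length and intron-length distributions, two intron spans are
placed uniformly at random without overlap, and their inner gap recorded.
(3) Distances between consecutive motif occurrences within individual introns
(homologous: same motif; heterologous: consecutive occurrences of two
different motifs), whose histogram peaks expose tandem repeats and composite
octamers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .motif_tools import MotifGroup, match_positions
from .splice_classifier import MASS, ClassifiedGene

__all__ = [
    "DistanceDistribution",
    "RandomPoolConfig",
    "Peak",
    "inter_site_distances",
    "simulate_random_intersite",
    "compare_distance_sets",
    "kruskal_across",
    "motif_distance_distribution",
    "detect_peaks",
    "write_histogram_tsv",
]


@dataclass
class DistanceDistribution:
    """A multiset of non-negative integer distances with a context label."""

    distances: np.ndarray
    context: str = ""

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=np.int64)
        if self.distances.size and self.distances.min() < 0:
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return int(self.distances.size)

    def histogram(self) -> Counter:
        return Counter(self.distances.tolist())


def inter_site_distances(cg: ClassifiedGene) -> DistanceDistribution:
    """Inner gaps between consecutive decision-site spans of a MASS gene."""
    if cg.label != MASS:
        raise ValueError(f"gene {cg.id} is not MASS; inter-site distances undefined")
    spans = sorted((s.span.start, s.span.end) for s in cg.sites)
    gaps = [b0 - a1 for (_, a1), (b0, _) in zip(spans, spans[1:])]
    return DistanceDistribution(np.array(gaps, dtype=np.int64), "inter-site")


class EmpiricalDistribution:
    """Resampling-ready empirical distribution of integer values."""

    def __init__(self, values: Sequence[int]):
        self.values = np.asarray(values, dtype=np.int64)
        if self.values.size == 0:
            raise ValueError("empirical distribution needs at least one value")

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        return rng.choice(self.values, size=n, replace=True)

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass
class RandomPoolConfig:
    """Configuration of the simulated transcript pool for the inter-site null."""

    gene_length_sample: EmpiricalDistribution
    intron_length_sample: EmpiricalDistribution
    n_transcripts: int = 6510
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be >= 1")


def simulate_random_intersite(cfg: RandomPoolConfig) -> DistanceDistribution:
    """Null inter-site distances from random placement of two intron spans.

    Per simulated transcript: draw a total length L and two intron lengths,
    place both spans uniformly at random without overlap inside [0, L]
    (rejection sampling, up to 1000 attempts before redrawing L), and record
    the inner gap. Fully determined by ``cfg.seed``.
    """
    max_l = int(cfg.gene_length_sample.values.max())
    min_introns = int(np.partition(cfg.intron_length_sample.values, 0)[0]) * 2
    if min_introns > max_l:
        raise ValueError("intron lengths exceed every possible transcript length")
    rng = np.random.default_rng(cfg.seed)
    gaps = np.empty(cfg.n_transcripts, dtype=np.int64)
    for i in range(cfg.n_transcripts):
        while True:
            L = int(cfg.gene_length_sample.sample(rng)[0])
            l1 = int(cfg.intron_length_sample.sample(rng)[0])
            l2 = int(cfg.intron_length_sample.sample(rng)[0])
            if l1 + l2 > L:
                continue
            placed = False
            for _ in range(1000):
                s1 = int(rng.integers(0, L - l1 + 1))
                s2 = int(rng.integers(0, L - l2 + 1))
                if s1 + l1 <= s2 or s2 + l2 <= s1:
                    placed = True
                    break
            if placed:
                break
        first_end, second_start = (
            (s1 + l1, s2) if s1 <= s2 else (s2 + l2, s1)
        )
        gaps[i] = second_start - first_end
    return DistanceDistribution(gaps, "inter-site null")


def compare_distance_sets(
    observed: DistanceDistribution,
    null: DistanceDistribution,
    n_comparisons: int = 1,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U between two distance sets.

    The returned p-value is Bonferroni-multiplied by ``n_comparisons`` when the
    comparison is one of several follow-ups after an omnibus test.
    """
    if len(observed) < 2 or len(null) < 2:
        raise ValueError("need at least two distances per set")
    u, p = stats.mannwhitneyu(
        observed.distances, null.distances, alternative="two-sided"
    )
    return float(u), min(1.0, float(p) * n_comparisons)


def kruskal_across(groups: Sequence[DistanceDistribution]) -> tuple[float, float]:
    """Kruskal-Wallis H test across several distance sets."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    h, p = stats.kruskal(*[g.distances for g in groups])
    return float(h), float(p)


def motif_distance_distribution(
    introns: Sequence[tuple[str, str]],
    m1: MotifGroup,
    m2: MotifGroup | None = None,
) -> DistanceDistribution:
    """Distances between consecutive motif occurrences within single introns.

    Homologous mode (``m2`` None or identical to ``m1``): differences between
    consecutive start positions of the motif within each intron. Heterologous
    mode: occurrences of both motifs are merged in ascending start order and
    the absolute start differences between consecutive occurrences of
    *different* motifs are recorded. A distance never spans two introns.
    """
    homologous = m2 is None or m2 is m1 or m2 == m1
    dists: list[int] = []
    for _, seq in introns:
        p1 = match_positions(seq, m1)
        if homologous:
            dists.extend(b - a for a, b in zip(p1, p1[1:]))
        else:
            assert m2 is not None
            p2 = match_positions(seq, m2)
            merged = sorted(
                [(pos, 0) for pos in p1] + [(pos, 1) for pos in p2]
            )
            for (pa, la), (pb, lb) in zip(merged, merged[1:]):
                if la != lb:
                    dists.append(abs(pb - pa))
    context = (
        f"homologous {m1.consensus}"
        if homologous
        else f"heterologous {m1.consensus}-{m2.consensus}"
    )
    return DistanceDistribution(np.array(dists, dtype=np.int64), context)


@dataclass
class Peak:
    """A prominent distance value in an inter-motif distance histogram."""

    distance: int
    count: int
    fraction: float


def detect_peaks(
    d: DistanceDistribution, min_fraction: float = 0.05
) -> list[Peak]:
    """Distance values that are local maxima carrying >= min_fraction of intervals.

    A distance qualifies when its fraction of all intervals is at least
    ``min_fraction``, its count is >= 2, and its count is not exceeded at the
    neighboring distances +/- 1 base. Sorted by fraction descending.
    """
    if not (0 < min_fraction < 1):
        raise ValueError("min_fraction must be in (0, 1)")
    total = len(d)
    if total == 0:
        return []
    hist = d.histogram()
    peaks = []
    for value, count in hist.items():
        fraction = count / total
        if (
            fraction >= min_fraction
            and count >= 2
            and count >= hist.get(value - 1, 0)
            and count >= hist.get(value + 1, 0)
        ):
            peaks.append(Peak(value, count, fraction))
    peaks.sort(key=lambda p: (-p.fraction, p.distance))
    return peaks


def write_histogram_tsv(d: DistanceDistribution, path) -> None:
    """Write a distance histogram as two-column TSV (distance, count)."""
    hist = d.histogram()
    with open(path, "w") as fh:
        fh.write("distance\tcount\n")
        for value in sorted(hist):
            fh.write(f"{value}\t{hist[value]}\n")
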