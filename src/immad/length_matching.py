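"""Stratified subsampling to match length distributions between gene groups.

Genes are binned by total length (default 1 kb bins). Within each bin the
group whose within-group proportion is higher is down-sampled, uniformly at
random, so that both groups end up with the bin fraction of the
under-represented group. Because the total fraction removed is the same on
both sides (the total-variation distance between the two binned
distributions), the post-subsampling per-bin proportions agree up to integer
rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .splice_classifier import ClassifiedGene

__all__ = ["SubsamplePlan", "stratified_subsample", "rank_test_lengths"]


@dataclass
class SubsamplePlan:
    """Record of which gene ids were removed from each group."""

    bin_width: int
    removed_a: frozenset[str]
    removed_b: frozenset[str]
    seed: int


def _gene_length(g: ClassifiedGene) -> int:
    return g.gene.length


def stratified_subsample(
    genes_a: Sequence[ClassifiedGene],
    genes_b: Sequence[ClassifiedGene],
    bin_width: int = 1000,
    seed: int = 0,
) -> tuple[list[ClassifiedGene], list[ClassifiedGene], SubsamplePlan]:
    """Down-sample each group per length bin to the smaller bin fraction.

    Input order is preserved in the outputs; removals are seeded and recorded
    in the returned plan.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not genes_a or not genes_b:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    na, nb = len(genes_a), len(genes_b)
    bins_a: dict[int, list[ClassifiedGene]] = {}
    bins_b: dict[int, list[ClassifiedGene]] = {}
    for g in genes_a:
        bins_a.setdefault(_gene_length(g) // bin_width, []).append(g)
    for g in genes_b:
        bins_b.setdefault(_gene_length(g) // bin_width, []).append(g)

    removed_a: set[str] = set()
    removed_b: set[str] = set()
    for b in sorted(set(bins_a) | set(bins_b)):
        in_a = bins_a.get(b, [])
        in_b = bins_b.get(b, [])
        fa = len(in_a) / na
        fb = len(in_b) / nb
        if fa > fb:
            keep = int(round(fb * na))
            n_remove = len(in_a) - keep
            if n_remove > 0:
                victims = rng.choice(len(in_a), size=n_remove, replace=False)
                removed_a.update(in_a[i].id for i in victims)
        elif fb > fa:
            keep = int(round(fa * nb))
            n_remove = len(in_b) - keep
            if n_remove > 0:
                victims = rng.choice(len(in_b), size=n_remove, replace=False)
                removed_b.update(in_b[i].id for i in victims)

    out_a = [g for g in genes_a if g.id not in removed_a]
    out_b = [g for g in genes_b if g.id not in removed_b]
    plan = SubsamplePlan(bin_width, frozenset(removed_a), frozenset(removed_b), seed)
    return out_a, out_b, plan


def rank_test_lengths(
    genes_a: Sequence[ClassifiedGene],
    genes_b: Sequence[ClassifiedGene],
    statistic: str = "gene_length",
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U on gene lengths or pooled flanking-intron lengths."""
    if statistic == "gene_length":
        va = [_gene_length(g) for g in genes_a]
        vb = [_gene_length(g) for g in genes_b]
    elif statistic == "flanking_intron_length":
        va = [iv.length for g in genes_a for iv, _ in g.flanking_introns]
        vb = [iv.length for g in genes_b for iv, _ in g.flanking_introns]
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    if len(va) < 2 or len(vb) < 2:
        raise ValueError("need at least two values per group")
    u, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
    return float(u), float(p)
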