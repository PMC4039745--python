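"""IUPAC motif groups: clustering, matching, scrambling, reverse-complement overlap.

Significant oligomers are clustered into motif groups when one is a substring
of the other or when two equal-length oligomers differ at a single position;
each group is summarized by a degenerate IUPAC consensus (minimal code per
column, e.g. {C,T} -> Y). Matching is sense-strand only and counts overlapping
occurrences.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "IUPAC_SETS",
    "MotifGroup",
    "MotifMatch",
    "expand_iupac",
    "cluster_oligomers",
    "match_motif",
    "scramble_motifs",
    "revcomp_overlap",
]

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
_SET_TO_CODE = {v: k for k, v in IUPAC_SETS.items()}


def _code_for(bases: frozenset[str]) -> str:
    try:
        return _SET_TO_CODE[bases]
    except KeyError:
        raise ValueError(f"no IUPAC code for base set {sorted(bases)}") from None


def expand_iupac(consensus: str) -> list[str]:
    """All concrete oligomers matching a degenerate IUPAC string."""
    pools = []
    for c in consensus.upper():
        if c not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC code {c!r} in {consensus!r}")
        pools.append(sorted(IUPAC_SETS[c]))
    return ["".join(p) for p in itertools.product(*pools)]


@dataclass(frozen=True)
class MotifGroup:
    """A set of concrete oligomers plus an IUPAC-degenerate consensus."""

    consensus: str
    members: frozenset[str]
    k_range: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("motif group needs at least one member")

    @classmethod
    def from_consensus(cls, consensus: str) -> "MotifGroup":
        members = frozenset(expand_iupac(consensus))
        lengths = {len(m) for m in members}
        return cls(consensus.upper(), members, (min(lengths), max(lengths)))

    @classmethod
    def from_members(cls, members: Iterable[str]) -> "MotifGroup":
        groups = cluster_oligomers(list(members))
        if len(groups) != 1:
            raise ValueError("members do not form a single cluster")
        return groups[0]

    @property
    def name(self) -> str:
        return self.consensus


@dataclass(frozen=True)
class MotifMatch:
    """One occurrence of a motif group on the sense strand of a sequence."""

    seq_id: str
    start: int
    motif: MotifGroup


def _iupac_regex(consensus: str) -> str:
    parts = []
    for c in consensus.upper():
        bases = IUPAC_SETS.get(c)
        if bases is None:
            raise ValueError(f"invalid IUPAC code {c!r}")
        parts.append(next(iter(bases)) if len(bases) == 1 else "[" + "".join(sorted(bases)) + "]")
    return "".join(parts)


@lru_cache(maxsize=4096)
def _compiled_pattern(consensus: str, members: frozenset[str]) -> re.Pattern:
    alternatives = [_iupac_regex(consensus)]
    # Members shorter than the consensus (mixed-length clusters) must also hit.
    alternatives.extend(m for m in sorted(members) if len(m) != len(consensus))
    body = "|".join(f"(?:{a})" for a in alternatives)
    return re.compile(f"(?=(?:{body}))")


def match_positions(seq: str, m: MotifGroup) -> list[int]:
    """Start offsets (0-based, overlapping) of all matches on the sense strand."""
    pattern = _compiled_pattern(m.consensus, m.members)
    return [hit.start() for hit in pattern.finditer(seq.upper())]


def match_motif(seq: str, m: MotifGroup, seq_id: str = "") -> list[MotifMatch]:
    """All overlapping sense-strand occurrences, ascending by start."""
    return [MotifMatch(seq_id, pos, m) for pos in match_positions(seq, m)]


def _cluster_edges(a: str, b: str) -> bool:
    if len(a) == len(b):
        return sum(x != y for x, y in zip(a, b)) <= 1
    short, long_ = (a, b) if len(a) < len(b) else (b, a)
    return short in long_


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def _best_offset(member: str, reference: str) -> int:
    """Offset of member relative to reference maximizing exact matches.

    Ties break to the leftmost offset. Requires at least three overlapping
    positions so unrelated dangles are not aligned.
    """
    best, best_score = 0, -1
    for off in range(-(len(member) - 1), len(reference)):
        score = 0
        overlap = 0
        for i, ch in enumerate(member):
            j = off + i
            if 0 <= j < len(reference):
                overlap += 1
                if ch == reference[j]:
                    score += 1
        if overlap >= min(3, len(member)) and score > best_score:
            best, best_score = off, score
    return best


def _build_consensus(members: Sequence[str]) -> str:
    """Align members on their shared core and emit minimal IUPAC per column."""
    reference = sorted(members, key=lambda m: (-len(m), m))[0]
    offsets = {m: _best_offset(m, reference) for m in members}
    left = min(offsets.values())
    columns: list[set[str]] = []
    width = max(offsets[m] + len(m) for m in members) - left
    for _ in range(width):
        columns.append(set())
    for m in members:
        for i, ch in enumerate(m):
            columns[offsets[m] - left + i].add(ch)
    return "".join(_code_for(frozenset(col)) for col in columns)


def cluster_oligomers(oligos: Sequence[str]) -> list[MotifGroup]:
    """Group oligomers by the substring-or-one-mismatch rule.

    Union-find over pairwise edges: one oligomer being a substring of the
    other, or equal lengths at Hamming distance <= 1. The one-mismatch rule is
    applied within equal lengths only. Output order is by consensus string, so
    clustering is invariant to input order.
    """
    uniq = sorted(set(o.upper() for o in oligos))
    for o in uniq:
        if not (5 <= len(o) <= 7):
            raise ValueError(f"oligomer {o!r} outside supported length range 5-7")
    uf = _UnionFind(len(uniq))
    for i, a in enumerate(uniq):
        for j in range(i + 1, len(uniq)):
            if _cluster_edges(a, uniq[j]):
                uf.union(i, j)
    clusters: dict[int, list[str]] = {}
    for i, o in enumerate(uniq):
        clusters.setdefault(uf.find(i), []).append(o)
    groups = []
    for members in clusters.values():
        lengths = {len(m) for m in members}
        groups.append(
            MotifGroup(
                _build_consensus(members),
                frozenset(members),
                (min(lengths), max(lengths)),
            )
        )
    return sorted(groups, key=lambda g: g.consensus)


def scramble_motifs(
    motifs: Sequence[MotifGroup], seed: int
) -> list[MotifGroup]:
    """Seeded letter-permutation controls preserving base composition.

    For each group, one random permutation of the consensus positions is drawn
    and applied to the consensus and every member, so each scrambled member
    keeps its exact base composition and the group stays internally consistent.
    A permutation whose scrambled members collide with any real member (or
    leave the consensus unchanged) is re-drawn, up to 100 attempts; a
    composition-forced identity (e.g. a homopolymer) is kept with a warning.
    """
    rng = np.random.default_rng(seed)
    real_members = set().union(*(m.members for m in motifs)) if motifs else set()
    scrambled = []
    for m in motifs:
        n = len(m.consensus)
        chosen = None
        for _ in range(100):
            perm = rng.permutation(n)
            new_consensus = "".join(m.consensus[i] for i in perm)
            new_members = frozenset(
                "".join(mem[i] for i in perm) for mem in m.members if len(mem) == n
            )
            short = frozenset(mem for mem in m.members if len(mem) != n)
            # mixed-length members are scrambled with their own permutation
            for mem in sorted(short):
                p = rng.permutation(len(mem))
                new_members |= {"".join(mem[i] for i in p)}
            if new_consensus != m.consensus and not (new_members & real_members):
                chosen = MotifGroup(new_consensus, new_members, m.k_range)
                break
        if chosen is None:
            warnings.warn(
                f"could not scramble motif {m.consensus} away from real members; "
                "keeping original composition-forced sequence",
                stacklevel=2,
            )
            chosen = MotifGroup(m.consensus, m.members, m.k_range)
        scrambled.append(chosen)
    return scrambled


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp_overlap(a: str, b: str) -> int:
    """Longest contiguous substring shared between reverse-complement(a) and b."""
    ra = a.upper().translate(_COMPLEMENT)[::-1]
    b = b.upper()
    best = 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(ra) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if ra[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best
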