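"""Core-genome construction by global-alignment identity.

Genes of every strain are matched against genes of every other strain
with an exact Needleman–Wunsch global alignment (match +1, mismatch -1,
gap -2); identity is the fraction of identical columns over all alignment
columns, gap columns included.  Candidate pairs per strain pair are
ranked by identity and accepted greedily (best first, one-to-one) at a
minimum identity threshold, 0.70 by default.  Accepted pairs across all
strain pairs are merged transitively into ortholog groups; only groups
with exactly one member in every strain form the core set, and groups
claiming two genes of one strain (paralogy conflicts) are dropped.

An exhaustive all-vs-all alignment is quadratic in gene count, so
candidate pairs are pre-screened by shared k-mer content before the exact
aligner runs; the screen only prunes pairs whose identity cannot
plausibly reach the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSequence",
    "OrthologGroup",
    "make_aligner",
    "global_alignment",
    "global_identity",
    "pair_genomes",
    "greedy_match",
    "build_core_set",
]

_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class GeneSequence:
    """One coding sequence of one strain."""

    gene_id: str
    strain_id: str
    biovar: str
    sequence: str
    category: str = "core-candidate"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty sequence")
        if set(self.sequence.upper()) - _ALPHABET:
            raise ValueError(
                f"invalid characters in sequence of {self.gene_id}"
            )


@dataclass
class OrthologGroup:
    """Per-strain members of one gene family across strains."""

    group_id: str
    members: dict[str, str]  # strain_id -> gene_id
    pairwise_identity: dict[tuple[str, str], float] = field(
        default_factory=dict
    )


def make_aligner(
    match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> Align.PairwiseAligner:
    """Global NW aligner with the package's default scoring scheme."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


_DEFAULT_ALIGNER = make_aligner()


def global_alignment(
    seq_a: str, seq_b: str, aligner: Align.PairwiseAligner | None = None
) -> tuple[str, str]:
    """Optimal global alignment of two sequences as two gapped rows."""
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aligner = aligner or _DEFAULT_ALIGNER
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    return str(aln[0]), str(aln[1])


def global_identity(
    seq_a: str, seq_b: str, aligner: Align.PairwiseAligner | None = None
) -> float:
    """Identity = identical columns / all columns of the optimal alignment.

    Symmetric in its arguments; 1.0 iff the sequences are identical.
    """
    if seq_a == seq_b:
        if not seq_a:
            raise ValueError("cannot align an empty sequence")
        return 1.0
    row_a, row_b = global_alignment(seq_a, seq_b, aligner)
    matches = sum(a == b for a, b in zip(row_a, row_b))
    return matches / len(row_a)


# -- k-mer pre-screen -------------------------------------------------------


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def _kmer_candidates(
    genes_a: list[GeneSequence],
    genes_b: list[GeneSequence],
    k: int,
    min_shared: int,
) -> list[tuple[int, int]]:
    """Index pairs sharing at least ``min_shared`` k-mers."""
    from collections import defaultdict

    index: dict[str, list[int]] = defaultdict(list)
    for j, g in enumerate(genes_b):
        for km in _kmer_set(g.sequence.upper(), k):
            index[km].append(j)
    hits: dict[tuple[int, int], int] = defaultdict(int)
    for i, g in enumerate(genes_a):
        for km in _kmer_set(g.sequence.upper(), k):
            for j in index.get(km, ()):
                hits[(i, j)] += 1
    return [pair for pair, n in hits.items() if n >= min_shared]


def pair_genomes(
    genes_a: list[GeneSequence],
    genes_b: list[GeneSequence],
    min_identity: float = 0.70,
    aligner: Align.PairwiseAligner | None = None,
    prescreen_k: int = 12,
    prescreen_min_shared: int = 3,
) -> list[tuple[str, str, float]]:
    """Greedy one-to-one gene pairing between two strains.

    All candidate pairs are sorted in descending order of identity; a
    pair is accepted when both genes are still unmatched and its identity
    is at least ``min_identity``.  Returns (gene_id_a, gene_id_b,
    identity) tuples.  Set ``prescreen_k`` to 0 to disable the k-mer
    pre-screen and align every pair exactly.
    """
    if not genes_a or not genes_b:
        return []
    if genes_a[0].strain_id == genes_b[0].strain_id:
        raise ValueError("pair_genomes needs two distinct strains")
    if prescreen_k:
        candidates = _kmer_candidates(
            genes_a, genes_b, prescreen_k, prescreen_min_shared
        )
    else:
        candidates = [
            (i, j) for i in range(len(genes_a)) for j in range(len(genes_b))
        ]
    scored = []
    for i, j in candidates:
        ident = global_identity(
            genes_a[i].sequence, genes_b[j].sequence, aligner
        )
        scored.append((ident, i, j))
    return [
        (genes_a[i].gene_id, genes_b[j].gene_id, ident)
        for ident, i, j in greedy_match(scored, min_identity)
    ]


def greedy_match(
    scored: list[tuple[float, int, int]], min_identity: float
) -> list[tuple[float, int, int]]:
    """Best-first one-to-one matching of scored index pairs.

    Pairs are taken in descending identity (deterministic index
    tie-break); a pair is accepted when both sides are still unmatched
    and its identity reaches ``min_identity``.
    """
    ranked = sorted(scored, key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    accepted = []
    for ident, i, j in ranked:
        if ident < min_identity or i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        accepted.append((ident, i, j))
    return accepted


def build_core_set(
    pairings: dict[tuple[str, str], list[tuple[str, str, float]]],
    strains: list[str],
) -> list[OrthologGroup]:
    """Merge per-strain-pair pairings into core ortholog groups.

    ``pairings`` maps (strain_a, strain_b) to the pair list from
    :func:`pair_genomes` for those strains.  Pairs are merged
    transitively (union-find over (strain, gene) nodes); a group enters
    the core set only when it has exactly one member in every strain.
    Groups in which two genes of one strain collide are paralogy
    conflicts: dropped and logged.
    """
    parent: dict[tuple[str, str], tuple[str, str]] = {}

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(x, y):
        for node in (x, y):
            parent.setdefault(node, node)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    identity_of: dict[tuple[str, str], dict[tuple[str, str], float]] = {}
    for (sa, sb), pairs in pairings.items():
        for ga, gb, ident in pairs:
            union((sa, ga), (sb, gb))
            identity_of.setdefault((sa, ga), {})
            identity_of[(sa, ga)][(sa, sb)] = ident

    components: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for node in parent:
        components.setdefault(find(node), []).append(node)

    strain_set = set(strains)
    groups: list[OrthologGroup] = []
    n_conflict = n_partial = 0
    for root, nodes in sorted(components.items()):
        members: dict[str, str] = {}
        conflict = False
        for strain, gene in nodes:
            if strain in members and members[strain] != gene:
                conflict = True
            members[strain] = gene
        if conflict:
            n_conflict += 1
            logger.info("dropping paralog-conflicted group at %s", root)
            continue
        if set(members) != strain_set:
            n_partial += 1
            continue
        ref_strain = strains[0]
        gid = members.get(ref_strain, root[1])
        pid = {}
        for (sa, sb), pairs in pairings.items():
            for ga, gb, ident in pairs:
                if members.get(sa) == ga and members.get(sb) == gb:
                    pid[(sa, sb)] = ident
        groups.append(OrthologGroup(gid, members, pid))
    if n_conflict or n_partial:
        logger.info(
            "core set: %d groups kept, %d paralog conflicts dropped, "
            "%d absent from >=1 strain",
            len(groups),
            n_conflict,
            n_partial,
        )
    groups.sort(key=lambda g: g.group_id)
    return groups
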