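"""Per-gene alignment and nucleotide polymorphism (p-distance).

The p-distance between two aligned rows counts only columns in which
both strains carry a determined base (A/C/G/T): gaps and Ns are excluded
pairwise, and the substitution count is divided by the number of
comparable columns.  A gene's polymorphism within a biovar is the mean of
the off-diagonal entries of its p-distance matrix restricted to that
biovar's strains; a gene is polymorphic in a biovar when this mean is
greater than zero.

Ortholog groups whose members share one length are taken as already
frame-aligned (the common case for intact orthologous CDSs); unequal
lengths trigger a centre-star progressive alignment built on the exact
pairwise global aligner, or optionally an external aligner such as mafft.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .orthologs import global_alignment, global_identity, make_aligner

__all__ = [
    "AlignedGene",
    "align_group",
    "p_distance_pair",
    "p_distance_matrix",
    "gene_mean_p",
]

_DETERMINED = frozenset(b"ACGT")


@dataclass
class AlignedGene:
    """Equal-length aligned rows of one gene, keyed by strain."""

    group_id: str
    rows: dict[str, str]

    def __post_init__(self):
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"rows of {self.group_id} differ in length")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def in_frame(self) -> bool:
        """True when the alignment length keeps a codon frame."""
        return self.n_columns % 3 == 0


def _merge_center_star(center: str, pairs: list[tuple[str, str]]):
    """Merge pairwise alignments against one centre into an MSA.

    ``pairs`` holds (gapped_center, gapped_other) rows.  Classic
    once-a-gap-always-a-gap merge: the master gap profile before each
    centre residue (and at the end) is the maximum over the pairwise
    alignments.
    """
    n = len(center)
    master = [0] * (n + 1)
    profiles = []
    for gc, _ in pairs:
        prof = [0] * (n + 1)
        pos = 0
        for ch in gc:
            if ch == "-":
                prof[pos] += 1
            else:
                pos += 1
        profiles.append(prof)
        for k in range(n + 1):
            master[k] = max(master[k], prof[k])

    def expand(row_other: str, prof):
        out = []
        i = 0  # index into the pairwise row
        for k in range(n + 1):
            out.append("-" * (master[k] - prof[k]))
            # copy the gap block and (if any) the centre residue column
            take = prof[k] + (1 if k < n else 0)
            out.append(row_other[i : i + take])
            i += take
        return "".join(out)

    center_row = expand(center, [0] * (n + 1))
    merged = [expand(go, prof) for (_, go), prof in zip(pairs, profiles)]
    return center_row, merged


def _external_align(seqs: dict[str, str], tool: str = "mafft") -> dict[str, str]:
    """Align with an external command-line MSA tool (optional hook)."""
    if shutil.which(tool) is None:
        raise RuntimeError(f"external aligner {tool!r} not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fasta"
        fin.write_text(
            "".join(f">{k}\n{v}\n" for k, v in seqs.items())
        )
        out = subprocess.run(
            [tool, "--auto", "--quiet", str(fin)]
            if tool == "mafft"
            else [tool, str(fin)],
            capture_output=True,
            text=True,
            check=True,
        ).stdout
    rows: dict[str, str] = {}
    key = None
    for line in out.splitlines():
        if line.startswith(">"):
            key = line[1:].split()[0]
            rows[key] = ""
        elif key is not None:
            rows[key] += line.strip().upper()
    return rows


def align_group(
    group_id: str,
    seqs: dict[str, str],
    external_tool: str | None = None,
) -> AlignedGene:
    """Align one ortholog group's sequences.

    Equal-length inputs pass through unchanged (frame preserved).
    Otherwise a centre-star progressive alignment is built: the centre is
    the sequence with the greatest summed identity to the others, every
    other sequence is aligned to it with the exact global aligner, and
    the pairwise alignments are merged under once-a-gap-always-a-gap.
    With ``external_tool`` set (e.g. ``"mafft"``), that tool is invoked
    instead.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences to align")
    seqs = {k: v.upper() for k, v in seqs.items()}
    if len({len(s) for s in seqs.values()}) == 1:
        return AlignedGene(group_id, dict(seqs))
    if external_tool:
        return AlignedGene(group_id, _external_align(seqs, external_tool))
    keys = sorted(seqs)
    totals = {
        k: sum(global_identity(seqs[k], seqs[j]) for j in keys if j != k)
        for k in keys
    }
    center_key = max(keys, key=lambda k: (totals[k], k))
    others = [k for k in keys if k != center_key]
    pairs = [global_alignment(seqs[center_key], seqs[k]) for k in others]
    center_row, merged = _merge_center_star(seqs[center_key], pairs)
    rows = {center_key: center_row}
    rows.update(dict(zip(others, merged)))
    return AlignedGene(group_id, rows)


def p_distance_pair(row_a: str, row_b: str) -> float:
    """Uncorrected p-distance over pairwise-comparable columns.

    Columns where either row has a gap or an undetermined base are
    ignored.  NaN when no column is comparable.
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows differ in length")
    a = np.frombuffer(row_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(row_b.upper().encode(), dtype=np.uint8)
    det = np.zeros(256, dtype=bool)
    det[list(_DETERMINED)] = True
    ok = det[a] & det[b]
    n = int(ok.sum())
    if n == 0:
        return math.nan
    return float((a[ok] != b[ok]).sum() / n)


def p_distance_matrix(aligned: AlignedGene) -> tuple[list[str], np.ndarray]:
    """Symmetric strain x strain p-distance matrix, zero diagonal."""
    order = sorted(aligned.rows)
    n = len(order)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = p_distance_pair(aligned.rows[order[i]], aligned.rows[order[j]])
            mat[i, j] = mat[j, i] = d
    return order, mat


def gene_mean_p(
    matrix: np.ndarray, order: list[str], strains: list[str]
) -> float:
    """Mean off-diagonal p-distance among the given strains.

    With a biovar's strains this is that biovar's per-gene polymorphism;
    the gene is polymorphic there iff the mean is > 0.  NaN entries
    (no comparable columns for a pair) are excluded from the mean.
    """
    idx = [order.index(s) for s in strains]
    if len(idx) < 2:
        raise ValueError("need at least two strains")
    sub = matrix[np.ix_(idx, idx)]
    vals = sub[np.triu_indices(len(idx), k=1)]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return math.nan
    return float(vals.mean())
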