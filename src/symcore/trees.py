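"""ANI matrices, neighbor-joining trees, and topological congruence.

The average nucleotide identity between two strains over a gene set is
one minus the length-weighted mean p-distance of the set's genes.  Trees
are built by neighbor joining on 1 - ANI and compared by the
Robinson-Foulds distance normalised by its maximum 2(n-3); 0 means
identical unrooted topologies.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

__all__ = ["ani_matrix", "build_tree", "congruence"]


def ani_matrix(
    gene_matrices: dict[str, tuple[list[str], np.ndarray, int]],
    gene_subset: list[str] | None = None,
) -> tuple[list[str], np.ndarray]:
    """Length-weighted ANI over a gene set.

    ``gene_matrices`` maps gene id to (strain order, p-distance matrix,
    gene length in columns).  ANI(i,j) = 1 - sum(len_g * p_g(i,j)) /
    sum(len_g); genes with an undefined p-distance for a pair are
    excluded from that pair's weighting.  Diagonal is 1.
    """
    genes = list(gene_matrices) if gene_subset is None else list(gene_subset)
    if not genes:
        raise ValueError("empty gene subset")
    order = gene_matrices[genes[0]][0]
    n = len(order)
    weighted = np.zeros((n, n))
    weights = np.zeros((n, n))
    for g in genes:
        g_order, mat, length = gene_matrices[g]
        if g_order != order:
            idx = [g_order.index(s) for s in order]
            mat = mat[np.ix_(idx, idx)]
        ok = ~np.isnan(mat)
        weighted[ok] += length * mat[ok]
        weights[ok] += length
    with np.errstate(invalid="ignore"):
        ani = 1.0 - weighted / weights
    np.fill_diagonal(ani, 1.0)
    return order, ani


def build_tree(order: list[str], ani: np.ndarray) -> str:
    """Neighbor-joining tree on 1 - ANI, as a Newick string.

    Negative branch lengths produced by NJ are clamped to zero.
    """
    if len(order) < 3:
        raise ValueError("need at least three strains")
    if not np.allclose(ani, ani.T, equal_nan=True):
        raise ValueError("ANI matrix must be symmetric")
    dist = 1.0 - ani
    np.fill_diagonal(dist, 0.0)
    dm = DistanceMatrix(dist, ids=order)
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def congruence(newick_a: str, newick_b: str) -> float:
    """Normalised Robinson-Foulds distance between two unrooted trees.

    RF divided by 2(n-3); 0 = topologically identical.  The leaf sets
    must match.
    """
    ns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(
        data=newick_a, schema="newick", taxon_namespace=ns,
        preserve_underscores=True,
    )
    tb = dendropy.Tree.get(
        data=newick_b, schema="newick", taxon_namespace=ns,
        preserve_underscores=True,
    )
    leaves_a = {t.taxon.label for t in ta.leaf_node_iter()}
    leaves_b = {t.taxon.label for t in tb.leaf_node_iter()}
    if leaves_a != leaves_b:
        raise ValueError("trees have different leaf sets")
    n = len(leaves_a)
    if n < 4:
        return 0.0
    for t in (ta, tb):
        t.is_rooted = False
        t.collapse_basal_bifurcation()
        t.encode_bipartitions()
    rf = dendropy.calculate.treecompare.symmetric_difference(ta, tb)
    return rf / (2.0 * (n - 3))
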