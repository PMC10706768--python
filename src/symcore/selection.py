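"""Per-codon dN/dS estimation and selection-regime classification.

The estimator works directly on codon alignments of two strains.  Each
codon is assigned a *theoretical synonymous fraction*: of its nine
single-nucleotide neighbours, the fraction that is synonymous among the
non-stop ones (alanine codons: 3 of 9, i.e. 1/3).  Synonymous (Sd) and
nonsynonymous (Nd) differences between two observed codons are counted by
averaging over all mutational pathways that avoid stop codons, in the
spirit of Nei–Gojobori counting.  Synonymous site totals come from the
per-codon synonymous fractions; proportions are corrected for multiple
hits with the one-parameter Jukes–Cantor formula before the dN/dS ratio
is formed.

A gene pair with no synonymous divergence (dS = 0) has an undefined
ratio, represented as NaN and excluded from gene means.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BASES",
    "STOP_CODONS",
    "SENSE_CODONS",
    "GENETIC_CODE",
    "CodonProfile",
    "codon_profile",
    "codon_pair_diffs",
    "gene_dnds_pair",
    "dnds_matrix",
    "gene_mean_dnds",
    "classify_selection",
]

BASES = "ACGT"

#: Standard (NCBI table 1) genetic code, codon -> one-letter amino acid,
#: stop codons included as "*".
from Bio.Data import CodonTable as _CodonTable

_STD = _CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_STD.forward_table)
GENETIC_CODE.update({c: "*" for c in _STD.stop_codons})

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))


@dataclass(frozen=True)
class CodonProfile:
    """Mutational neighbourhood of one sense codon.

    ``syn_fraction`` is the synonymous fraction among non-stop neighbours,
    i.e. ``syn / (syn + nonsyn)``.
    """

    codon: str
    syn_neighbors: int
    nonsyn_neighbors: int
    stop_neighbors: int

    @property
    def syn_fraction(self) -> float:
        return self.syn_neighbors / (self.syn_neighbors + self.nonsyn_neighbors)


def _neighbors(codon: str):
    for pos in range(3):
        for base in BASES:
            if base != codon[pos]:
                yield codon[:pos] + base + codon[pos + 1 :]


def codon_profile(codon: str) -> CodonProfile:
    """Classify the nine single-nucleotide neighbours of a sense codon.

    Raises ``ValueError`` for stop codons or invalid triplets.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"not a valid codon: {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon has no profile: {codon!r}")
    aa = GENETIC_CODE[codon]
    syn = nonsyn = stop = 0
    for nb in _neighbors(codon):
        if nb in STOP_CODONS:
            stop += 1
        elif GENETIC_CODE[nb] == aa:
            syn += 1
        else:
            nonsyn += 1
    return CodonProfile(codon, syn, nonsyn, stop)


def _step_class(src: str, dst: str) -> str:
    """Classify a single-nucleotide codon change as 's' or 'n'."""
    return "s" if GENETIC_CODE[src] == GENETIC_CODE[dst] else "n"


def codon_pair_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts between codons.

    Codons differing at k positions are connected by k! single-step
    pathways; pathways passing through a stop codon are excluded and the
    step counts averaged over the remainder.  If every pathway is blocked
    by a stop, each differing position is classified directly in the
    context of ``codon_a`` (a step landing on a stop counts as
    nonsynonymous).
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if len(c) != 3 or any(b not in BASES for b in c):
            raise ValueError(f"not a valid codon: {c!r}")
        if c in STOP_CODONS:
            raise ValueError(f"stop codon not allowed: {c!r}")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return (0.0, 0.0)
    syn_tot = nonsyn_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            steps.append(_step_class(cur, nxt))
            cur = nxt
        if ok:
            n_paths += 1
            syn_tot += steps.count("s")
            nonsyn_tot += steps.count("n")
    if n_paths == 0:
        # all pathways blocked: classify each position independently
        syn = nonsyn = 0
        for pos in diff_pos:
            nxt = codon_a[:pos] + codon_b[pos] + codon_a[pos + 1 :]
            if nxt in STOP_CODONS or _step_class(codon_a, nxt) == "n":
                nonsyn += 1
            else:
                syn += 1
        return (float(syn), float(nonsyn))
    return (syn_tot / n_paths, nonsyn_tot / n_paths)


# ---------------------------------------------------------------------------
# Precomputed lookup tables over the 61 sense codons: pairwise Sd/Nd and
# per-codon synonymous fractions, used to vectorise whole-gene computation.
# ---------------------------------------------------------------------------

_CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
_SYN_FRACTION = np.array(
    [codon_profile(c).syn_fraction for c in SENSE_CODONS]
)
_PAIR_SD = np.zeros((61, 61))
_PAIR_ND = np.zeros((61, 61))
for _a, _ca in enumerate(SENSE_CODONS):
    for _b, _cb in enumerate(SENSE_CODONS):
        if _b < _a:
            continue
        _s, _n = codon_pair_diffs(_ca, _cb)
        _PAIR_SD[_a, _b] = _PAIR_SD[_b, _a] = _s
        _PAIR_ND[_a, _b] = _PAIR_ND[_b, _a] = _n


def encode_codons(row: str) -> np.ndarray:
    """Encode an aligned nucleotide row as sense-codon indices.

    Codons containing gaps, Ns, anything non-ACGT, or stops map to -1 and
    are skipped by the pairwise estimator.  Row length must be a multiple
    of three.
    """
    if len(row) % 3:
        raise ValueError("row length not divisible by 3")
    row = row.upper()
    return np.array(
        [
            _CODON_INDEX.get(row[i : i + 3], -1)
            for i in range(0, len(row), 3)
        ],
        dtype=np.int64,
    )


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction d = -(3/4) ln(1 - (4/3)p).

    Saturated proportions (p >= 3/4) return NaN.
    """
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def gene_dnds_pair(
    row_a: str | np.ndarray,
    row_b: str | np.ndarray,
    *,
    jc_correction: bool = True,
    per_codon_average: bool = False,
) -> float:
    """dN/dS for one aligned pair of coding rows; NaN when undefined.

    Rows may be raw aligned strings (length divisible by three) or
    pre-encoded codon index arrays from :func:`encode_codons`.  Codons
    with a gap, N, or stop in either row are skipped whole.  With
    ``per_codon_average`` the raw Sd/Nd counts are averaged per comparable
    codon instead of being converted into site-normalised proportions
    (an alternative normalisation; site counting is the default).
    """
    a = encode_codons(row_a) if isinstance(row_a, str) else row_a
    b = encode_codons(row_b) if isinstance(row_b, str) else row_b
    if a.shape != b.shape:
        raise ValueError("aligned rows differ in codon length")
    ok = (a >= 0) & (b >= 0)
    n_codons = int(ok.sum())
    if n_codons == 0:
        return math.nan
    ai, bi = a[ok], b[ok]
    sd = float(_PAIR_SD[ai, bi].sum())
    nd = float(_PAIR_ND[ai, bi].sum())
    if per_codon_average:
        if sd == 0.0:
            return math.nan
        return (nd / n_codons) / (sd / n_codons)
    s_sites = float(3.0 * 0.5 * (_SYN_FRACTION[ai] + _SYN_FRACTION[bi]).sum())
    n_sites = 3.0 * n_codons - s_sites
    if s_sites <= 0 or n_sites <= 0:
        return math.nan
    ps, pn = sd / s_sites, nd / n_sites
    if jc_correction:
        ds, dn = jukes_cantor(ps), jukes_cantor(pn)
    else:
        ds, dn = ps, pn
    if not (ds > 0) or math.isnan(dn):
        return math.nan
    return dn / ds


def dnds_matrix(
    rows: dict[str, str],
    strain_order: list[str] | None = None,
    **kwargs,
) -> tuple[list[str], np.ndarray]:
    """Symmetric strain x strain matrix of pairwise dN/dS values.

    The diagonal is NaN (a strain has no divergence from itself), as are
    pairs with dS = 0.  Returns the strain order used and the matrix.
    """
    order = list(rows) if strain_order is None else list(strain_order)
    enc = {s: encode_codons(rows[s]) for s in order}
    n = len(order)
    mat = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            v = gene_dnds_pair(enc[order[i]], enc[order[j]], **kwargs)
            mat[i, j] = mat[j, i] = v
    return order, mat


def gene_mean_dnds(
    matrix: np.ndarray, order: list[str], strains: list[str]
) -> float:
    """Mean of the defined off-diagonal entries among the given strains.

    NaN when no entry is defined (the gene then carries no selection
    signal for this strain subset and is excluded from pooled summaries).
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


def classify_selection(mean: float, se: float, z: float = 1.96) -> str:
    """Classify a pooled dN/dS as driving (D), purifying (P) or neutral (N).

    D when the lower z-interval bound exceeds 1, P when the upper bound is
    below 1, N otherwise.
    """
    if se < 0:
        raise ValueError("standard error must be >= 0")
    if mean - z * se > 1.0:
        return "D"
    if mean + z * se < 1.0:
        return "P"
    return "N"
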