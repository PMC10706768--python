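"""Synthetic two-biovar genome collections with known evolutionary truth.

Emulates a collection of 14 rhizobium strains from two host-specific
biovars (6 bv. orientalis + 8 bv. officinalis): a shared pool of core
genes plus 39 symbiotic genes (16 nod, 8 nif, 15 fix), all evolved on a
single two-clade strain tree so core and sym genes are phylogenetically
congruent by construction (no horizontal transfer).

Sequences evolve by a proposal/acceptance scheme: single-nucleotide
changes arrive as a Poisson process, a proposed nonsynonymous change is
accepted with relative probability omega (synonymous changes always),
and changes creating stop codons are rejected.  Branch lengths are
calibrated so that the configured within-/between-biovar divergence is
the *expected pairwise p-distance*: the target is inverted through the
Jukes-Cantor formula and divided by the sequence- and omega-specific
proposal acceptance probability.

Defaults mirror the study conditions of the real strain collection:
within-biovar divergence 0.048 (orientalis) / 0.010 (officinalis),
between-biovar divergence 0.15, polymorphic gene fractions 74.6/75.9 %
(core) and 38.5/7.7 % (sym), and per-group dN/dS regimes 1.571/1.013
(core) and 1.009/0.272 (sym).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .selection import SENSE_CODONS, STOP_CODONS, GENETIC_CODE, codon_profile

__all__ = [
    "ORIENTALIS",
    "OFFICINALIS",
    "BIOVARS",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_codon_sequence",
    "evolve_gene",
    "acceptance_probability",
    "invert_p_distance",
    "generate_dataset",
]

ORIENTALIS = "orientalis"
OFFICINALIS = "officinalis"
BIOVARS = (ORIENTALIS, OFFICINALIS)

_SYM_CATEGORIES = ("nod", "nif", "fix")

# per-codon neighbour counts, aligned with SENSE_CODONS
_PROFILES = [codon_profile(c) for c in SENSE_CODONS]
_SYN_N = np.array([p.syn_neighbors for p in _PROFILES], dtype=float)
_NONSYN_N = np.array([p.nonsyn_neighbors for p in _PROFILES], dtype=float)
_CODON_IDX = {c: i for i, c in enumerate(SENSE_CODONS)}


def _default_omega() -> dict:
    # (group, biovar) -> list of (omega, fraction); study-condition means
    return {
        ("core", ORIENTALIS): [(1.571, 1.0)],
        ("core", OFFICINALIS): [(1.013, 1.0)],
        ("sym", ORIENTALIS): [(1.009, 1.0)],
        ("sym", OFFICINALIS): [(0.272, 1.0)],
    }


def _default_polymorphic() -> dict:
    # (group, biovar) -> fraction of genes receiving any within-biovar change
    return {
        ("core", ORIENTALIS): 0.746,
        ("core", OFFICINALIS): 0.759,
        ("sym", ORIENTALIS): 0.385,
        ("sym", OFFICINALIS): 0.077,
    }


@dataclass
class SimulationConfig:
    """Conditions of one synthetic strain collection.

    ``within_biovar_divergence`` / ``between_biovar_divergence`` are the
    expected pairwise p-distances among (resp. between) biovar members.
    ``omega_classes`` maps (gene group, biovar) to (omega, fraction)
    mixtures; ``polymorphic_fraction`` maps the same keys to the fraction
    of genes that receive any within-biovar substitution.
    ``omega_divergence_coupling`` scales a gene's within-biovar
    divergence by omega**coupling, letting simulations couple selection
    to polymorphism (0 = uncoupled).
    """

    seed: int = 0
    n_strains_per_biovar: tuple[int, int] = (6, 8)  # (orientalis, officinalis)
    n_core_genes: int = 200
    n_sym_genes: tuple[int, int, int] = (16, 8, 15)  # (nod, nif, fix)
    gene_length_codons: tuple[int, int] = (100, 400)
    within_biovar_divergence: dict = field(
        default_factory=lambda: {ORIENTALIS: 0.048, OFFICINALIS: 0.010}
    )
    between_biovar_divergence: float = 0.15
    omega_classes: dict = field(default_factory=_default_omega)
    polymorphic_fraction: dict = field(default_factory=_default_polymorphic)
    n_go_terms: int = 40
    go_mean_genes_per_term: float = 8.0
    omega_divergence_coupling: float = 0.0

    def validate(self) -> None:
        if any(n < 2 for n in self.n_strains_per_biovar):
            raise ValueError("need at least two strains per biovar")
        if self.n_core_genes < 1 or any(n < 0 for n in self.n_sym_genes):
            raise ValueError("invalid gene counts")
        lo, hi = self.gene_length_codons
        if not (1 <= lo <= hi):
            raise ValueError("invalid gene length range")
        for b, d in self.within_biovar_divergence.items():
            if d < 0:
                raise ValueError(f"negative divergence for {b}")
        if self.between_biovar_divergence < 0:
            raise ValueError("negative between-biovar divergence")
        for key, classes in self.omega_classes.items():
            total = sum(f for _, f in classes)
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"omega fractions for {key} must sum to 1")
            if any(w < 0 or f < 0 for w, f in classes):
                raise ValueError(f"negative omega or fraction for {key}")
        for key, frac in self.polymorphic_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"polymorphic fraction {key} outside [0,1]")
        if self.go_mean_genes_per_term < 1:
            raise ValueError("go_mean_genes_per_term must be >= 1")


def simulate_codon_sequence(length_codons: int, rng: np.random.Generator) -> str:
    """Random frame-aligned CDS with no internal stop codons."""
    if length_codons < 1:
        raise ValueError("length must be >= 1")
    idx = rng.integers(0, len(SENSE_CODONS), size=length_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def acceptance_probability(sequence: str, omega: float) -> float:
    """Probability that a uniform single-base proposal is accepted.

    Proposals are uniform over the 9L single-nucleotide neighbours of the
    codon sequence; stop-creating changes are never accepted and the
    synonymous:nonsynonymous acceptance odds are 1:omega (realised as
    probabilities min(1, 1/omega) and min(1, omega)).
    """
    idx = np.array(
        [_CODON_IDX[sequence[i : i + 3]] for i in range(0, len(sequence), 3)]
    )
    n_codons = len(idx)
    p_syn, p_nonsyn = _acceptance_probs(omega)
    return float(
        (p_syn * _SYN_N[idx].sum() + p_nonsyn * _NONSYN_N[idx].sum())
        / (9.0 * n_codons)
    )


def _acceptance_probs(omega: float) -> tuple[float, float]:
    """(synonymous, nonsynonymous) acceptance probabilities with 1:omega odds."""
    if omega <= 1.0:
        return 1.0, omega
    return 1.0 / omega, 1.0


def invert_p_distance(p: float) -> float:
    """Expected accepted substitutions/site giving pairwise p-distance p.

    Inverse of the Jukes-Cantor saturation curve p = (3/4)(1 - e^{-4t/3}).
    """
    if not 0.0 <= p < 0.75:
        raise ValueError("p-distance target must be in [0, 0.75)")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def evolve_gene(
    ancestor: str,
    branch_length: float,
    omega: float,
    rng: np.random.Generator,
) -> str:
    """Evolve a CDS along one branch of ``branch_length`` proposals/site.

    Single-nucleotide proposals arrive as a Poisson process (expected
    ``branch_length`` per site); each picks a uniform site and a uniform
    alternative base.  Stop-creating changes are rejected; synonymous and
    nonsynonymous changes are accepted with relative odds 1:omega
    (probabilities min(1, 1/omega) and min(1, omega)).
    """
    if branch_length < 0:
        raise ValueError("branch length must be >= 0")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    n_sites = len(ancestor)
    if n_sites % 3:
        raise ValueError("ancestor length not divisible by 3")
    if branch_length == 0.0:
        return ancestor
    p_syn, p_nonsyn = _acceptance_probs(omega)
    seq = bytearray(ancestor.encode())
    n_events = rng.poisson(branch_length * n_sites)
    sites = rng.integers(0, n_sites, size=n_events)
    base_draws = rng.integers(0, 3, size=n_events)
    accept_draws = rng.random(size=n_events)
    bases = b"ACGT"
    for site, bdraw, u in zip(sites, base_draws, accept_draws):
        old = seq[site]
        alts = [b for b in bases if b != old]
        new = alts[bdraw]
        c0 = site - site % 3
        codon = seq[c0 : c0 + 3].decode()
        new_codon = (
            codon[: site - c0] + chr(new) + codon[site - c0 + 1 :]
        )
        if new_codon in STOP_CODONS:
            continue
        p_accept = (
            p_syn if GENETIC_CODE[codon] == GENETIC_CODE[new_codon] else p_nonsyn
        )
        if u >= p_accept:
            continue
        seq[site] = new
    return seq.decode()


# ---------------------------------------------------------------------------
# Strain tree
# ---------------------------------------------------------------------------


@dataclass
class _Node:
    name: str
    children: list = field(default_factory=list)
    branch: float = 0.0  # substitutions/site from parent, before per-gene scaling
    clade: str | None = None  # biovar of the clade this branch belongs to


def _random_clade(
    strains: list[str], biovar: str, rng: np.random.Generator
) -> tuple[_Node, float]:
    """Random bifurcating ultrametric clade; returns (root, tip depth).

    Node heights above the tips are drawn uniformly and sorted so that
    successive joins are nested; the clade root sits at the maximum
    height.  Branch lengths are rescaled later so the mean pairwise tip
    path equals the clade's divergence target.
    """
    nodes = [_Node(s, clade=biovar) for s in strains]
    heights = {id(n): 0.0 for n in nodes}
    n_joins = len(strains) - 1
    # evenly spaced joins with uniform jitter: every internal branch is a
    # bounded fraction of the clade depth, so the topology stays
    # resolvable at low divergence (strains of a real collection are
    # distinguishable)
    base = np.linspace(1.0 / n_joins, 1.0, n_joins)
    join_heights = np.sort(base * rng.uniform(0.9, 1.1, size=n_joins))
    for h in join_heights:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.branch = h - heights[id(a)]
        b.branch = h - heights[id(b)]
        parent = _Node("", [a, b], clade=biovar)
        heights[id(parent)] = h
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    return root, float(join_heights[-1])


def _pairwise_paths(root: _Node) -> list[float]:
    """Tip-to-tip path lengths within a clade."""
    paths: list[float] = []

    def collect(node, depth):
        if not node.children:
            return {node.name: depth}
        merged = {}
        for ch in node.children:
            sub = collect(ch, 0.0)
            sub = {k: v + ch.branch for k, v in sub.items()}
            for prev in merged:
                for name, d in sub.items():
                    paths.append(merged[prev] + d)
            merged.update(sub)
        return merged

    collect(root, 0.0)
    return paths


def _scale_clade(node: _Node, factor: float) -> None:
    for ch in node.children:
        ch.branch *= factor
        _scale_clade(ch, factor)


def build_strain_tree(
    config: SimulationConfig, rng: np.random.Generator
) -> _Node:
    """Two-clade strain tree calibrated in substitutions/site.

    Each biovar forms one clade whose mean pairwise tip path equals the
    JC-inverted within-biovar divergence; stem branches to the root are
    set so the mean cross-biovar path equals the inverted between-biovar
    divergence.
    """
    n_ori, n_off = config.n_strains_per_biovar
    strains = {
        ORIENTALIS: [f"ori_{i+1:02d}" for i in range(n_ori)],
        OFFICINALIS: [f"off_{i+1:02d}" for i in range(n_off)],
    }
    clades = {}
    depths = {}
    for biovar in BIOVARS:
        root, depth = _random_clade(strains[biovar], biovar, rng)
        target = invert_p_distance(config.within_biovar_divergence[biovar])
        mean_path = float(np.mean(_pairwise_paths(root)))
        factor = target / mean_path if mean_path > 0 else 0.0
        _scale_clade(root, factor)
        clades[biovar] = root
        depths[biovar] = depth * factor
    t_between = invert_p_distance(config.between_biovar_divergence)
    stem = max(0.0, (t_between - depths[ORIENTALIS] - depths[OFFICINALIS]) / 2)
    for biovar in BIOVARS:
        clades[biovar].branch = stem
        clades[biovar].clade = None  # stem branches are shared history
    return _Node("root", [clades[ORIENTALIS], clades[OFFICINALIS]])


def tree_to_newick(root: _Node) -> str:
    def fmt(node):
        if not node.children:
            return f"{node.name}:{node.branch:.6f}"
        inner = ",".join(fmt(ch) for ch in node.children)
        return f"({inner}):{node.branch:.6f}"

    inner = ",".join(fmt(ch) for ch in root.children)
    return f"({inner});"


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """Paths and ground truth of one generated collection."""

    outdir: Path
    strains: dict[str, str]  # strain_id -> biovar
    fasta_paths: dict[str, Path]
    strains_tsv: Path
    sym_genes_tsv: Path
    gene2go_tsv: Path
    truth_tsv: Path
    tree_newick: Path
    truth: pd.DataFrame


def _draw_omega(classes: list[tuple[float, float]], rng) -> float:
    fracs = np.array([f for _, f in classes])
    i = rng.choice(len(classes), p=fracs / fracs.sum())
    return float(classes[i][0])


def _evolve_on_tree(
    node: _Node,
    sequence: str,
    omega_by_biovar: dict[str, float],
    scale_by_biovar: dict[str, float],
    p_acc: dict,
    rng: np.random.Generator,
    out: dict[str, str],
) -> None:
    for ch in node.children:
        omega = omega_by_biovar.get(ch.clade, 1.0) if ch.clade else 1.0
        scale = scale_by_biovar.get(ch.clade, 1.0) if ch.clade else 1.0
        proposal_b = ch.branch * scale / p_acc[omega]
        seq = evolve_gene(sequence, proposal_b, omega, rng)
        if ch.children:
            _evolve_on_tree(
                ch, seq, omega_by_biovar, scale_by_biovar, p_acc, rng, out
            )
        else:
            out[ch.name] = seq


def generate_dataset(
    config: SimulationConfig,
    outdir: str | Path,
    force: bool = False,
) -> SyntheticDataset:
    """Generate the full synthetic collection and write its file set.

    Writes one CDS FASTA per strain (headers ``geneID|strainID``),
    ``strains.tsv``, ``sym_genes.tsv``, ``gene2go.tsv``, ``truth.tsv``
    and the true strain tree in Newick.  Identical configs (same seed)
    produce byte-identical files.  Refuses to write into an existing
    non-empty directory unless ``force``.
    """
    config.validate()
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {outdir} is not empty (use force=True)"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    tree = build_strain_tree(config, rng)
    n_ori, n_off = config.n_strains_per_biovar
    strains = {f"ori_{i+1:02d}": ORIENTALIS for i in range(n_ori)}
    strains.update({f"off_{i+1:02d}": OFFICINALIS for i in range(n_off)})

    genes: list[tuple[str, str, str]] = []  # (gene_id, group, category)
    genes += [
        (f"core_{i+1:04d}", "core", "core") for i in range(config.n_core_genes)
    ]
    for cat, n in zip(_SYM_CATEGORIES, config.n_sym_genes):
        genes += [(f"{cat}_{i+1:02d}", "sym", cat) for i in range(n)]

    lo, hi = config.gene_length_codons
    sequences: dict[str, dict[str, str]] = {s: {} for s in strains}
    truth_rows = []
    for gene_id, group, category in genes:
        length = int(rng.integers(lo, hi + 1))
        ancestor = simulate_codon_sequence(length, rng)
        omega_by_biovar = {
            b: _draw_omega(config.omega_classes[(group, b)], rng)
            for b in BIOVARS
        }
        polymorphic = {
            b: bool(rng.random() < config.polymorphic_fraction[(group, b)])
            for b in BIOVARS
        }
        scale_by_biovar = {}
        for b in BIOVARS:
            scale = 0.0 if not polymorphic[b] else 1.0
            if config.omega_divergence_coupling and polymorphic[b]:
                scale *= omega_by_biovar[b] ** config.omega_divergence_coupling
            scale_by_biovar[b] = scale
        p_acc = {
            w: acceptance_probability(ancestor, w)
            for w in set(omega_by_biovar.values()) | {1.0}
        }
        tips: dict[str, str] = {}
        _evolve_on_tree(
            tree, ancestor, omega_by_biovar, scale_by_biovar, p_acc, rng, tips
        )
        for strain_id, seq in tips.items():
            sequences[strain_id][gene_id] = seq
        truth_rows.append(
            {
                "gene_id": gene_id,
                "group": group,
                "category": category,
                "length_codons": length,
                "omega_orientalis": omega_by_biovar[ORIENTALIS],
                "omega_officinalis": omega_by_biovar[OFFICINALIS],
                "polymorphic_orientalis": polymorphic[ORIENTALIS],
                "polymorphic_officinalis": polymorphic[OFFICINALIS],
                "d_within_orientalis": (
                    config.within_biovar_divergence[ORIENTALIS]
                    * scale_by_biovar[ORIENTALIS]
                ),
                "d_within_officinalis": (
                    config.within_biovar_divergence[OFFICINALIS]
                    * scale_by_biovar[OFFICINALIS]
                ),
            }
        )

    # GO labels: geometric sizes, members sampled from the core pool so
    # terms overlap
    core_ids = [g for g, grp, _ in genes if grp == "core"]
    gene2go_rows = []
    go_by_gene: dict[str, list[str]] = {g: [] for g in core_ids}
    p_geom = 1.0 / config.go_mean_genes_per_term
    for t in range(config.n_go_terms):
        go_id = f"GO:{t+1:07d}"
        size = min(int(rng.geometric(p_geom)), len(core_ids))
        members = rng.choice(len(core_ids), size=size, replace=False)
        for m in sorted(members):
            gene2go_rows.append((core_ids[m], go_id))
            go_by_gene[core_ids[m]].append(go_id)

    truth = pd.DataFrame(truth_rows)
    truth["go_terms"] = [
        ",".join(go_by_gene.get(g, [])) for g in truth["gene_id"]
    ]

    # --- write files -------------------------------------------------------
    fasta_paths = {}
    for strain_id in strains:
        path = outdir / f"{strain_id}.fasta"
        with open(path, "w") as fh:
            for gene_id, _, _ in genes:
                fh.write(f">{gene_id}|{strain_id}\n")
                fh.write(sequences[strain_id][gene_id] + "\n")
        fasta_paths[strain_id] = path

    strains_tsv = outdir / "strains.tsv"
    with open(strains_tsv, "w") as fh:
        fh.write("strain_id\tbiovar\n")
        for s, b in strains.items():
            fh.write(f"{s}\t{b}\n")

    sym_genes_tsv = outdir / "sym_genes.tsv"
    with open(sym_genes_tsv, "w") as fh:
        fh.write("gene_id\tcategory\n")
        for gene_id, group, category in genes:
            if group == "sym":
                fh.write(f"{gene_id}\t{category}\n")

    gene2go_tsv = outdir / "gene2go.tsv"
    with open(gene2go_tsv, "w") as fh:
        fh.write("gene_id\tgo_id\n")
        for gene_id, go_id in gene2go_rows:
            fh.write(f"{gene_id}\t{go_id}\n")

    truth_tsv = outdir / "truth.tsv"
    truth.to_csv(truth_tsv, sep="\t", index=False)

    tree_newick = outdir / "true_tree.nwk"
    tree_newick.write_text(tree_to_newick(tree) + "\n")

    return SyntheticDataset(
        outdir=outdir,
        strains=strains,
        fasta_paths=fasta_paths,
        strains_tsv=strains_tsv,
        sym_genes_tsv=sym_genes_tsv,
        gene2go_tsv=gene2go_tsv,
        truth_tsv=truth_tsv,
        tree_newick=tree_newick,
        truth=truth,
    )
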