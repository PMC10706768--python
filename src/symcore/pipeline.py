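"""End-to-end orchestration: input -> orthologs -> metrics -> reports.

Stages run in order: (1) simulate or ingest a strain collection;
(2) core-genome construction by global-alignment identity; (3) per-gene
alignment, p-distance and dN/dS matrices with per-biovar means;
(4) pooled statistics, quadrant assignment and correlation tables;
(5) GOG aggregation, contrasting-GOG selection, cluster contingency,
enrichment permutation tests and High-in-High comparisons; (6) ANI
trees for core and sym gene sets and their Robinson-Foulds congruence.

All tabular outputs are one-header TSV files; a manifest records the
seed and every parameter.  All randomness flows from the single pipeline
seed, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import enrichment as enr
from . import selection as sel
from . import stats as st
from . import trees as tr
from .orthologs import GeneSequence, build_core_set, pair_genomes
from .polymorphism import align_group, gene_mean_p, p_distance_matrix
from .synthetic import (
    BIOVARS,
    OFFICINALIS,
    ORIENTALIS,
    SimulationConfig,
    generate_dataset,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_fasta_dir"]


@dataclass
class PipelineConfig:
    """Every parameter the pipeline stages receive."""

    output_dir: Path | str = "symcore_out"
    mode: str = "synthetic"  # or "fasta-dir"
    input_dir: Path | str | None = None
    min_identity: float = 0.70
    n_permutations: int = 10000
    seed: int = 1
    z: float = 1.96  # selection-class interval half-width in SEs
    jc_correction: bool = True
    external_aligner: str | None = None
    simulation: SimulationConfig | None = None
    force: bool = False

    def validate(self) -> None:
        if self.mode not in ("synthetic", "fasta-dir"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.z <= 0:
            raise ValueError("z must be > 0")
        if self.mode == "fasta-dir" and self.input_dir is None:
            raise ValueError("fasta-dir mode needs input_dir")


@dataclass
class PipelineResult:
    """In-memory handles to every stage output."""

    output_dir: Path
    strains: dict[str, str]
    gene_metrics: pd.DataFrame
    table1: pd.DataFrame
    table2: pd.DataFrame
    fractions: pd.DataFrame
    cluster_frequencies: pd.DataFrame
    contingency: pd.DataFrame
    gogs: pd.DataFrame
    high_in_high: pd.DataFrame
    core_newick: str
    sym_newick: str
    rf_congruence: float
    n_contrasting_gogs: int
    manifest: dict = field(default_factory=dict)


def load_fasta_dir(input_dir: Path):
    """Read a strain collection: per-strain FASTAs plus the three tables.

    Expects ``strains.tsv`` (strain_id, biovar), one ``<strain>.fasta``
    per strain with ``geneID|strainID`` headers, ``sym_genes.tsv``
    (gene_id, category) and optionally ``gene2go.tsv`` (gene_id, go_id).
    """
    input_dir = Path(input_dir)
    strains_df = pd.read_csv(input_dir / "strains.tsv", sep="\t")
    strains = dict(zip(strains_df["strain_id"], strains_df["biovar"]))
    sym_df = pd.read_csv(input_dir / "sym_genes.tsv", sep="\t")
    sym_categories = dict(zip(sym_df["gene_id"], sym_df["category"]))
    go_path = input_dir / "gene2go.tsv"
    gene2go = (
        pd.read_csv(go_path, sep="\t")
        if go_path.exists()
        else pd.DataFrame(columns=["gene_id", "go_id"])
    )
    genes_by_strain: dict[str, list[GeneSequence]] = {}
    for strain_id, biovar in strains.items():
        path = input_dir / f"{strain_id}.fasta"
        genes = []
        for rec in SeqIO.parse(str(path), "fasta"):
            gene_id, sid = rec.id.split("|")
            if sid != strain_id:
                raise ValueError(f"header strain {sid} != file strain {strain_id}")
            genes.append(
                GeneSequence(
                    gene_id,
                    strain_id,
                    biovar,
                    str(rec.seq).upper(),
                    sym_categories.get(gene_id, "core-candidate"),
                )
            )
        genes_by_strain[strain_id] = genes
    return strains, genes_by_strain, sym_categories, gene2go


def _detect_orthologs(strains, genes_by_strain, config):
    order = sorted(strains)
    pairings = {}
    for i, sa in enumerate(order):
        for sb in order[i + 1 :]:
            pairings[(sa, sb)] = pair_genomes(
                genes_by_strain[sa],
                genes_by_strain[sb],
                min_identity=config.min_identity,
            )
    return build_core_set(pairings, order)


def _compute_gene_metrics(groups, genes_by_strain, strains, sym_categories, config):
    """Alignment, p-distance and dN/dS matrices with per-biovar means."""
    seq_lookup = {
        (g.strain_id, g.gene_id): g.sequence
        for genes in genes_by_strain.values()
        for g in genes
    }
    by_biovar = {
        b: sorted(s for s, bb in strains.items() if bb == b) for b in BIOVARS
    }
    rows = []
    p_matrices = {}
    for group in groups:
        seqs = {
            strain: seq_lookup[(strain, gid)]
            for strain, gid in group.members.items()
        }
        aligned = align_group(
            group.group_id, seqs, external_tool=config.external_aligner
        )
        order, pmat = p_distance_matrix(aligned)
        p_matrices[group.group_id] = (order, pmat, aligned.n_columns)
        p_by = {b: gene_mean_p(pmat, order, by_biovar[b]) for b in BIOVARS}
        if aligned.in_frame:
            order_d, dmat = sel.dnds_matrix(
                aligned.rows, order, jc_correction=config.jc_correction
            )
            d_by = {
                b: sel.gene_mean_dnds(dmat, order_d, by_biovar[b])
                for b in BIOVARS
            }
        else:
            logger.warning(
                "group %s breaks codon frame; excluded from dN/dS",
                group.group_id,
            )
            d_by = {b: math.nan for b in BIOVARS}
        category = sym_categories.get(group.group_id, "core")
        rows.append(
            {
                "gene_id": group.group_id,
                "group": "sym" if category in ("nod", "nif", "fix") else "core",
                "category": category,
                "n_columns": aligned.n_columns,
                f"p_{ORIENTALIS}": p_by[ORIENTALIS],
                f"p_{OFFICINALIS}": p_by[OFFICINALIS],
                f"dnds_{ORIENTALIS}": d_by[ORIENTALIS],
                f"dnds_{OFFICINALIS}": d_by[OFFICINALIS],
            }
        )
    metrics = pd.DataFrame(rows).set_index("gene_id")
    for b in BIOVARS:
        metrics[f"polymorphic_{b}"] = metrics[f"p_{b}"] > 0
    return metrics, p_matrices


# ---------------------------------------------------------------------------
# Pooled statistics
# ---------------------------------------------------------------------------


def summarize_metrics(metrics: pd.DataFrame, z: float = 1.96):
    """Pooled mean +/- SE tables, polymorphic fractions and correlations.

    Per biovar, the p-distance pool contains the genes with non-zero
    polymorphism there, the dN/dS pool the genes with a defined ratio
    (both biovar-specific analyzed-gene conventions); polymorphic
    fractions are taken over all genes of the group; correlations use
    the intersection of the two pools.  Returns (table1, fractions,
    table2).
    """
    t1_rows, frac_rows, t2_rows = [], [], []
    pools: dict[tuple[str, str, str], pd.DataFrame] = {}
    for grp in ("core", "sym"):
        sub = metrics[metrics["group"] == grp]
        for b in BIOVARS:
            pools[("p", grp, b)] = sub[sub[f"p_{b}"] > 0]
            pools[("dnds", grp, b)] = sub[sub[f"dnds_{b}"].notna()]
            pools[("both", grp, b)] = sub[
                (sub[f"p_{b}"] > 0) & sub[f"dnds_{b}"].notna()
            ]
    for metric in ("p", "dnds"):
        for grp in ("core", "sym"):
            per_biovar = {}
            for b in BIOVARS:
                pool = pools[(metric, grp, b)]
                if len(pool) < 2:
                    per_biovar[b] = st.StatResult(math.nan, math.nan, n=len(pool))
                    continue
                per_biovar[b] = st.mean_with_se(pool[f"{metric}_{b}"])
            ro, rf_ = per_biovar[ORIENTALIS], per_biovar[OFFICINALIS]
            if ro.n >= 2 and rf_.n >= 2:
                cmp = st.compare_means(
                    ro.estimate, ro.standard_error, ro.n,
                    rf_.estimate, rf_.standard_error, rf_.n,
                )
                t_val, band = cmp.t, cmp.band
            else:
                t_val, band = math.nan, "n/a"
            row = {
                "metric": metric,
                "genes": grp,
                "mean_ori": ro.estimate,
                "se_ori": ro.standard_error,
                "n_ori": ro.n,
                "mean_off": rf_.estimate,
                "se_off": rf_.standard_error,
                "n_off": rf_.n,
                "t_biovars": t_val,
                "p0_biovars": band,
            }
            if metric == "dnds":
                for key, r in (("class_ori", ro), ("class_off", rf_)):
                    row[key] = (
                        sel.classify_selection(r.estimate, r.standard_error, z)
                        if r.n >= 2 and not math.isnan(r.estimate)
                        else "n/a"
                    )
            t1_rows.append(row)
        # core vs sym within each biovar
        for b in BIOVARS:
            pc, ps = pools[(metric, "core", b)], pools[(metric, "sym", b)]
            if len(pc) >= 2 and len(ps) >= 2:
                mc = st.mean_with_se(pc[f"{metric}_{b}"])
                ms = st.mean_with_se(ps[f"{metric}_{b}"])
                cmp = st.compare_means(
                    mc.estimate, mc.standard_error, mc.n,
                    ms.estimate, ms.standard_error, ms.n,
                )
                t1_rows.append(
                    {
                        "metric": metric,
                        "genes": f"core_vs_sym_{b}",
                        "t_biovars": cmp.t,
                        "p0_biovars": cmp.band,
                    }
                )
    for grp in ("core", "sym"):
        sub = metrics[metrics["group"] == grp]
        for b in BIOVARS:
            defined = sub[sub[f"p_{b}"].notna()]
            k = int(defined[f"polymorphic_{b}"].sum())
            n = len(defined)
            r = st.proportion_with_se(k, n) if n else st.StatResult(
                math.nan, math.nan, n=0
            )
            frac_rows.append(
                {
                    "genes": grp,
                    "biovar": b,
                    "k_polymorphic": k,
                    "n": n,
                    "fraction": r.estimate,
                    "se": r.standard_error,
                }
            )
        # correlations over polymorphic genes with defined dN/dS
        corr = {}
        for b in BIOVARS:
            pool = pools[("both", grp, b)]
            try:
                corr[b] = st.pearson_correlation(
                    pool[f"p_{b}"], pool[f"dnds_{b}"]
                )
            except ValueError:
                corr[b] = st.StatResult(math.nan, math.nan, n=len(pool))
        row = {
            "genes": grp,
            "r_ori": corr[ORIENTALIS].estimate,
            "n_ori": corr[ORIENTALIS].n,
            "p0_ori": corr[ORIENTALIS].band,
            "r_off": corr[OFFICINALIS].estimate,
            "n_off": corr[OFFICINALIS].n,
            "p0_off": corr[OFFICINALIS].band,
        }
        try:
            cc = st.compare_correlations(
                corr[ORIENTALIS].estimate,
                corr[ORIENTALIS].n,
                corr[OFFICINALIS].estimate,
                corr[OFFICINALIS].n,
            )
            row["z_biovars"], row["p0_biovars"] = cc.t, cc.band
        except (ValueError, TypeError):
            row["z_biovars"], row["p0_biovars"] = math.nan, "n/a"
        t2_rows.append(row)
    return pd.DataFrame(t1_rows), pd.DataFrame(frac_rows), pd.DataFrame(t2_rows)


def assign_quadrants(metrics: pd.DataFrame):
    """Quadrant labels for core genes polymorphic in both biovars.

    The quadrant pool is the fully-analyzed core set: core genes
    polymorphic in both biovars with both dN/dS values defined.  Pool
    means of each metric in each biovar are the quadrant thresholds.
    Returns (pool metrics with quadrant columns, pool means dict).
    """
    pool = metrics[
        (metrics["group"] == "core")
        & metrics[f"polymorphic_{ORIENTALIS}"]
        & metrics[f"polymorphic_{OFFICINALIS}"]
        & metrics[f"dnds_{ORIENTALIS}"].notna()
        & metrics[f"dnds_{OFFICINALIS}"].notna()
    ].copy()
    means = {
        (m, b): float(pool[f"{m}_{b}"].mean())
        for m in ("p", "dnds")
        for b in BIOVARS
    }
    for m, col in (("p", "quadrant_pol"), ("dnds", "quadrant_sel")):
        pool[col] = [
            st.assign_quadrant(
                row[f"{m}_{ORIENTALIS}"],
                row[f"{m}_{OFFICINALIS}"],
                means[(m, ORIENTALIS)],
                means[(m, OFFICINALIS)],
            )
            for _, row in pool.iterrows()
        ]
    return pool, means


def gog_analysis(
    pool: pd.DataFrame,
    means: dict,
    gene2go: pd.DataFrame,
    n_permutations: int,
    rng: np.random.Generator,
):
    """Contrasting-GOG selection, clustering, enrichment and Fig-3 stats."""
    annotated_pool = pool[pool.index.isin(gene2go["gene_id"])]
    gogs_all = enr.build_gogs(
        gene2go, pool, (ORIENTALIS, OFFICINALIS), min_size=2
    )
    empty = (
        pd.DataFrame(),
        pd.DataFrame(
            0,
            index=[f"C_sel-{q}" for q in st.QUADRANTS] + ["Total"],
            columns=[f"C_pol-{q}" for q in st.QUADRANTS] + ["Total"],
        ),
        pd.DataFrame(),
        0,
    )
    if len(gogs_all) < 2:
        return empty
    pool_means_p = {b: means[("p", b)] for b in BIOVARS}
    pool_means_d = {b: means[("dnds", b)] for b in BIOVARS}
    sel_p, thr_p = enr.select_contrasting_gogs(gogs_all, "p", pool_means_p)
    sel_d, thr_d = enr.select_contrasting_gogs(gogs_all, "dnds", pool_means_d)
    contrasting = sorted(
        {g.go_id: g for g in sel_p + sel_d}.values(), key=lambda g: g.go_id
    )
    enr.assign_gog_clusters(
        contrasting, pool_means_p, pool_means_d, ORIENTALIS, OFFICINALIS
    )
    contingency = enr.cluster_contingency(contrasting)

    n_genome = int(gene2go["gene_id"].nunique())
    n_sep = len(annotated_pool)
    sizes_in_genome = gene2go.groupby("go_id")["gene_id"].nunique()
    gog_rows = []
    for g in contrasting:
        s_sep = int(sizes_in_genome.get(g.go_id, g.size))
        observed = enr.p_enrich(g.size, s_sep, n_sep, n_genome)
        perm = enr.permutation_test(
            s_sep, n_sep, n_genome, observed, n_permutations, rng
        )
        gog_rows.append(
            {
                "go_id": g.go_id,
                "n_genes": g.size,
                "p_enrich": perm.p_enrich,
                "permutation_p": perm.permutation_p,
                "cluster_pol": g.cluster_pol,
                "cluster_sel": g.cluster_sel,
                **{f"mean_p_{b}": g.mean_p[b] for b in BIOVARS},
                **{f"mean_dnds_{b}": g.mean_dnds[b] for b in BIOVARS},
                **{f"enrich_p_{b}": g.enrich_p[b] for b in BIOVARS},
                **{f"enrich_dnds_{b}": g.enrich_dnds[b] for b in BIOVARS},
            }
        )
    hih_rows = []
    for biovar in BIOVARS:
        for ma, mb in (("p", "dnds"), ("dnds", "p")):
            hh, hl, cmp = enr.high_in_high(contrasting, biovar, ma, mb)
            hih_rows.append(
                {
                    "biovar": biovar,
                    "stratifier": ma,
                    "counted": mb,
                    "high_in_high": hh.estimate,
                    "hh_se": hh.standard_error,
                    "hh_n": hh.n,
                    "high_in_low": hl.estimate,
                    "hl_se": hl.standard_error,
                    "hl_n": hl.n,
                    "t": cmp.t if cmp is not None else math.nan,
                    "p0": cmp.band if cmp is not None else "n/a",
                }
            )
    return (
        pd.DataFrame(gog_rows),
        contingency,
        pd.DataFrame(hih_rows),
        len(contrasting),
    )


def _cluster_frequency_table(pool: pd.DataFrame) -> pd.DataFrame:
    rows = []
    n = len(pool)
    for metric, col in (("p", "quadrant_pol"), ("dnds", "quadrant_sel")):
        for q in st.QUADRANTS:
            k = int((pool[col] == q).sum())
            r = st.proportion_with_se(k, n) if n else st.StatResult(
                math.nan, math.nan, n=0
            )
            rows.append(
                {
                    "metric": metric,
                    "cluster": q,
                    "n_genes": k,
                    "fraction": r.estimate,
                    "se": r.standard_error,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the report bundle to ``output_dir``."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("stage: %s", name)
        timings[name] = time.time()
        return time.time()

    def done(name):
        timings[name] = round(time.time() - timings[name], 3)

    rng = np.random.default_rng(config.seed)

    stage("input")
    if config.mode == "synthetic":
        sim = config.simulation or SimulationConfig(seed=config.seed)
        dataset_dir = outdir / "dataset"
        # the pipeline owns its output directory: regenerating the nested
        # dataset on rerun is intended
        generate_dataset(sim, dataset_dir, force=True)
        input_dir = dataset_dir
    else:
        input_dir = Path(config.input_dir)
    strains, genes_by_strain, sym_categories, gene2go = load_fasta_dir(input_dir)
    done("input")

    stage("orthologs")
    groups = _detect_orthologs(strains, genes_by_strain, config)
    done("orthologs")

    stage("metrics")
    metrics, p_matrices = _compute_gene_metrics(
        groups, genes_by_strain, strains, sym_categories, config
    )
    metrics.to_csv(outdir / "gene_metrics.tsv", sep="\t")
    done("metrics")

    stage("statistics")
    table1, fractions, table2 = summarize_metrics(metrics, z=config.z)
    pool, means = assign_quadrants(metrics)
    cluster_freq = _cluster_frequency_table(pool)
    pool.to_csv(outdir / "gene_quadrants.tsv", sep="\t")
    table1.to_csv(outdir / "table1.tsv", sep="\t", index=False)
    fractions.to_csv(outdir / "polymorphic_fractions.tsv", sep="\t", index=False)
    table2.to_csv(outdir / "table2.tsv", sep="\t", index=False)
    cluster_freq.to_csv(outdir / "cluster_frequencies.tsv", sep="\t", index=False)
    done("statistics")

    stage("go_enrichment")
    gogs, contingency, hih, n_contrasting = gog_analysis(
        pool, means, gene2go, config.n_permutations, rng
    )
    gogs.to_csv(outdir / "gogs.tsv", sep="\t", index=False)
    contingency.to_csv(outdir / "contingency.tsv", sep="\t")
    hih.to_csv(outdir / "highinhigh.tsv", sep="\t", index=False)
    done("go_enrichment")

    stage("congruence")
    core_ids = [g for g in metrics.index if metrics.loc[g, "group"] == "core"]
    sym_ids = [g for g in metrics.index if metrics.loc[g, "group"] == "sym"]
    order_c, ani_core = tr.ani_matrix(p_matrices, core_ids)
    order_s, ani_sym = tr.ani_matrix(p_matrices, sym_ids)
    core_newick = tr.build_tree(order_c, ani_core)
    sym_newick = tr.build_tree(order_s, ani_sym)
    rf = tr.congruence(core_newick, sym_newick)
    (outdir / "core.nwk").write_text(core_newick + "\n")
    (outdir / "sym.nwk").write_text(sym_newick + "\n")
    pd.DataFrame(ani_core, index=order_c, columns=order_c).to_csv(
        outdir / "ani_core.tsv", sep="\t"
    )
    pd.DataFrame(ani_sym, index=order_s, columns=order_s).to_csv(
        outdir / "ani_sym.tsv", sep="\t"
    )
    done("congruence")

    manifest = {
        "seed": config.seed,
        "mode": config.mode,
        "min_identity": config.min_identity,
        "n_permutations": config.n_permutations,
        "z": config.z,
        "jc_correction": config.jc_correction,
        "n_strains": len(strains),
        "n_core_groups": len(core_ids),
        "n_sym_groups": len(sym_ids),
        "n_quadrant_pool": len(pool),
        "n_contrasting_gogs": n_contrasting,
        "rf_congruence": rf,
        "simulation": (
            asdict(config.simulation)
            if config.simulation is not None
            else ({"seed": config.seed, "defaults": True} if config.mode == "synthetic" else None)
        ),
        "stage_seconds": timings,
    }
    manifest = _jsonable(manifest)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return PipelineResult(
        output_dir=outdir,
        strains=strains,
        gene_metrics=metrics,
        table1=table1,
        table2=table2,
        fractions=fractions,
        cluster_frequencies=cluster_freq,
        contingency=contingency,
        gogs=gogs,
        high_in_high=hih,
        core_newick=core_newick,
        sym_newick=sym_newick,
        rf_congruence=rf,
        n_contrasting_gogs=n_contrasting,
        manifest=manifest,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
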