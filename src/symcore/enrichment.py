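"""Gene Ontology group (GOG) aggregation, enrichment, and cluster analysis.

A GOG is the set of analyzed genes annotated with one GO term.  Each GOG
carries per-biovar mean p-distance and dN/dS over its members and their
*enrichment* relative to the gene-pool averages (GOG mean / pool mean).
GOGs whose enrichment deviates from the across-GOG average by more than
the across-GOG standard deviation — a threshold computed from the data,
never fixed — are "contrasting" and enter the quadrant clustering
(C_pol-I..IV by p-distance, C_sel-I..IV by dN/dS).

The prevalence of a GO group in a gene sample is
P_enrich = N_obs / (S_sep * N_sep / N_genome), the ratio of observed to
expected member count under proportional sampling, with significance
from a permutation test that redraws the sample at random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import StatResult, assign_quadrant, compare_proportions, proportion_with_se

__all__ = [
    "GOGRecord",
    "EnrichmentResult",
    "p_enrich",
    "permutation_test",
    "build_gogs",
    "select_contrasting_gogs",
    "cluster_contingency",
    "high_in_high",
]


@dataclass
class GOGRecord:
    """One Gene Ontology group over the analyzed gene pool."""

    go_id: str
    genes: list[str]
    mean_p: dict[str, float] = field(default_factory=dict)  # biovar -> mean
    mean_dnds: dict[str, float] = field(default_factory=dict)
    enrich_p: dict[str, float] = field(default_factory=dict)  # GOG/pool ratio
    enrich_dnds: dict[str, float] = field(default_factory=dict)
    cluster_pol: str | None = None
    cluster_sel: str | None = None

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    """Observed P_enrich with its one-sided permutation p-value."""

    p_enrich: float
    permutation_p: float
    n_permutations: int


def p_enrich(n_obs: int, s_sep: int, n_sep: int, n_genome: int) -> float:
    """Observed/expected gene count of a GO group in a sample.

    ``n_obs`` group members seen in the sample, ``s_sep`` group size in
    the genome, ``n_sep`` sample size, ``n_genome`` GO-annotated genome
    size.
    """
    if min(n_obs, 0) < 0:
        raise ValueError("counts must be >= 0")
    if min(s_sep, n_sep, n_genome) < 1:
        raise ValueError("group, sample and genome sizes must be >= 1")
    expected = s_sep * n_sep / n_genome
    return n_obs / expected


def permutation_test(
    s_sep: int,
    n_sep: int,
    n_genome: int,
    observed: float,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
    alternative: str = "greater",
) -> EnrichmentResult:
    """Permutation null for P_enrich of one GO group.

    Each permutation draws ``n_sep`` genes at random (without
    replacement) from the ``n_genome`` annotated genes and recomputes
    P_enrich for the ``s_sep``-sized group; the member count of a random
    draw is hypergeometric, which is sampled directly.  The p-value uses
    the add-one estimator (1 + #{permuted >= observed}) / (n_perm + 1),
    one-sided for enrichment by default (``alternative="two-sided"``
    doubles the smaller tail).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_sep > n_genome:
        raise ValueError("sample larger than genome")
    rng = rng if rng is not None else np.random.default_rng()
    draws = rng.hypergeometric(s_sep, n_genome - s_sep, n_sep, size=n_perm)
    expected = s_sep * n_sep / n_genome
    permuted = draws / expected
    hi = (1 + int((permuted >= observed).sum())) / (n_perm + 1)
    if alternative == "greater":
        p = hi
    elif alternative == "two-sided":
        lo = (1 + int((permuted <= observed).sum())) / (n_perm + 1)
        p = min(1.0, 2.0 * min(hi, lo))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return EnrichmentResult(observed, p, n_perm)


def build_gogs(
    gene2go: pd.DataFrame,
    metrics: pd.DataFrame,
    biovars: tuple[str, str],
    min_size: int = 2,
) -> list[GOGRecord]:
    """Aggregate analyzed genes into GOGs with per-biovar mean metrics.

    ``gene2go`` has columns (gene_id, go_id); ``metrics`` is indexed by
    gene_id with columns ``p_<biovar>`` and ``dnds_<biovar>`` and holds
    only the analyzed gene pool (membership is intersected with it).
    GOGs smaller than ``min_size`` within the pool are dropped.
    """
    pool = set(metrics.index)
    records = []
    for go_id, sub in gene2go.groupby("go_id"):
        genes = sorted(set(sub["gene_id"]) & pool)
        if len(genes) < min_size:
            continue
        rec = GOGRecord(go_id, genes)
        m = metrics.loc[genes]
        for b in biovars:
            rec.mean_p[b] = float(np.nanmean(m[f"p_{b}"]))
            rec.mean_dnds[b] = float(np.nanmean(m[f"dnds_{b}"]))
        records.append(rec)
    return records


def select_contrasting_gogs(
    gogs: list[GOGRecord],
    metric: str,
    pool_means: dict[str, float],
) -> tuple[list[GOGRecord], dict[str, float]]:
    """GOGs whose enrichment deviates beyond the across-GOG SD.

    ``metric`` is ``"p"`` or ``"dnds"``; ``pool_means`` maps biovar to
    the gene-pool mean of that metric.  A GOG's enrichment in a biovar
    is its member mean divided by the pool mean; the selection threshold
    is the standard deviation of enrichment values across GOGs, computed
    per biovar from the data.  A GOG is contrasting when its absolute
    deviation from the across-GOG average exceeds that SD in at least
    one biovar.  Returns (selected GOGs, per-biovar SD thresholds).
    """
    if len(gogs) < 2:
        raise ValueError("need at least two GOGs")
    if metric not in ("p", "dnds"):
        raise ValueError("metric must be 'p' or 'dnds'")
    for b, m in pool_means.items():
        if not m or math.isnan(m):
            raise ValueError(f"zero or undefined pool mean for {b}")
    means_attr = "mean_p" if metric == "p" else "mean_dnds"
    enrich_attr = "enrich_p" if metric == "p" else "enrich_dnds"
    biovars = list(pool_means)
    enrich = {
        b: np.array(
            [getattr(g, means_attr)[b] / pool_means[b] for g in gogs]
        )
        for b in biovars
    }
    thresholds = {}
    selected_mask = np.zeros(len(gogs), dtype=bool)
    for b in biovars:
        e = enrich[b]
        center, sd = float(np.nanmean(e)), float(np.nanstd(e, ddof=1))
        thresholds[b] = sd
        selected_mask |= np.abs(e - center) > sd
        for g, val in zip(gogs, e):
            getattr(g, enrich_attr)[b] = float(val)
    return [g for g, s in zip(gogs, selected_mask) if s], thresholds


def assign_gog_clusters(
    gogs: list[GOGRecord],
    pool_means_p: dict[str, float],
    pool_means_dnds: dict[str, float],
    ori: str,
    off: str,
) -> None:
    """Label each GOG with its p-distance and dN/dS quadrant clusters."""
    for g in gogs:
        g.cluster_pol = assign_quadrant(
            g.mean_p[ori], g.mean_p[off], pool_means_p[ori], pool_means_p[off]
        )
        g.cluster_sel = assign_quadrant(
            g.mean_dnds[ori],
            g.mean_dnds[off],
            pool_means_dnds[ori],
            pool_means_dnds[off],
        )


def cluster_contingency(gogs: list[GOGRecord]) -> pd.DataFrame:
    """Cross-tabulate C_sel x C_pol cluster membership with margins.

    Rows are dN/dS clusters, columns p-distance clusters; the returned
    frame carries "Total" margins whose sums equal the GOG count.
    """
    quadrants = ["I", "II", "III", "IV"]
    table = pd.DataFrame(
        0,
        index=[f"C_sel-{q}" for q in quadrants],
        columns=[f"C_pol-{q}" for q in quadrants],
    )
    for g in gogs:
        if g.cluster_pol is None or g.cluster_sel is None:
            raise ValueError(f"GOG {g.go_id} lacks cluster labels")
        table.loc[f"C_sel-{g.cluster_sel}", f"C_pol-{g.cluster_pol}"] += 1
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    return table


def high_in_high(
    gogs: list[GOGRecord],
    biovar: str,
    metric_a: str = "p",
    metric_b: str = "dnds",
) -> tuple[StatResult, StatResult, StatResult | None]:
    """High-in-High vs High-in-Low frequencies for one biovar.

    Splits GOGs by whether ``metric_a`` is elevated (member mean above
    the pool mean, i.e. enrichment > the across-GOG unit baseline 1) in
    the biovar, then measures how often ``metric_b`` is elevated within
    each stratum.  Returns (High-in-High, High-in-Low, comparison); the
    comparison is None when a stratum is empty.
    """
    attr = {"p": "enrich_p", "dnds": "enrich_dnds"}
    if metric_a not in attr or metric_b not in attr:
        raise ValueError("metrics must be 'p' or 'dnds'")
    a_vals = [getattr(g, attr[metric_a])[biovar] for g in gogs]
    b_vals = [getattr(g, attr[metric_b])[biovar] for g in gogs]
    hi_a = [a > 1.0 for a in a_vals]
    hi_b = [b > 1.0 for b in b_vals]
    in_high = [b for a, b in zip(hi_a, hi_b) if a]
    in_low = [b for a, b in zip(hi_a, hi_b) if not a]
    if not in_high or not in_low:
        empty = StatResult(math.nan, math.nan, n=0)
        return (
            proportion_with_se(sum(in_high), len(in_high)) if in_high else empty,
            proportion_with_se(sum(in_low), len(in_low)) if in_low else empty,
            None,
        )
    hh = proportion_with_se(sum(in_high), len(in_high))
    hl = proportion_with_se(sum(in_low), len(in_low))
    return hh, hl, compare_proportions(hh, hl)
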