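# symcore

Comparative evolution of core and symbiotically specialized (**sym**)
genes in a polytypic, two-biovar rhizobium species.

Nodule bacteria carry two gene pools with different natural histories:
core (housekeeping) genes, whose diversification drives speciation, and
*sym* genes (nod/nif/fix — nodulation, nitrogenase, and its energy
supply), whose diversification tracks host-induced selection. `symcore`
implements the full comparative analysis for a collection of strains
from two host-specific biovars (bv. *orientalis* and bv. *officinalis*):

1. **Core-genome construction** — all-vs-all gene matching by exact
   global-alignment identity (NW, match +1/mismatch −1/gap −2), greedy
   best-first pairing at ≥70 % identity, transitive merging; a gene is
   core when found in all 14 strains.
2. **Nucleotide polymorphism** — per-gene strain×strain p-distance
   matrices (gaps/Ns excluded pairwise); a gene's polymorphism per
   biovar is the mean off-diagonal within-biovar entry.
3. **Selection (dN/dS)** — per-codon counting: each codon's synonymous
   site total is 3·syn/(syn+nonsyn) over its nine single-nucleotide
   neighbours (alanine: 3/9 = 1/3), pathway-averaged difference counts,
   Jukes–Cantor correction, dN/dS per strain pair, averaged per biovar.
   Pooled means are classified D (driving, mean − 1.96·SE > 1),
   P (purifying, mean + 1.96·SE < 1) or N (neutral).
4. **Biovar statistics** — polymorphic-gene fractions with binomial
   SEs, Student's t comparisons, Pearson correlations between
   p-distance and dN/dS, and quadrant clustering of genes
   (above/below the pool mean in each biovar: Ori±Off±).
5. **GO-group analysis** — Gene Ontology groups over the polymorphic
   core pool, contrasting-GOG selection by across-GOG SD thresholds,
   4×4 cluster contingency, P_enrich = N_obs/(S_sep·N_sep/N_genome)
   with a 10,000-draw permutation null, High-in-High vs High-in-Low
   frequencies.
6. **Phylogenetic congruence** — ANI over the core and sym gene sets,
   neighbor-joining trees, normalised Robinson–Foulds distance.

A built-in generator produces ground-truthed synthetic 14-strain
collections (6+8 strains, 200 core + 39 sym genes evolved on one shared
two-clade tree under per-group ω regimes), so every stage is testable
against known truth. See `docs/methods.md` for models, calibration and
limitations.

## Worked example

```python
from symcore.pipeline import PipelineConfig, run_pipeline
from symcore.synthetic import SimulationConfig

config = PipelineConfig(
    output_dir="demo_out",
    seed=3,
    n_permutations=2000,
    simulation=SimulationConfig(seed=3, n_core_genes=40,
                                gene_length_codons=(100, 200)),
)
result = run_pipeline(config)
print(result.table1[["metric", "genes", "mean_ori", "mean_off",
                     "class_ori", "class_off"]].to_string(index=False))
```

prints (seed 3, 40 core genes):

```
metric                  genes  mean_ori  mean_off class_ori class_off
     p                   core  0.049026  0.009649       NaN       NaN
     p                    sym  0.047971       NaN       NaN       NaN
     p core_vs_sym_orientalis       NaN       NaN       NaN       NaN
  dnds                   core  2.115970  0.843081         D         P
  dnds                    sym  1.247691       NaN         D       n/a
  dnds core_vs_sym_orientalis       NaN       NaN       NaN       NaN
```

Reading it: core genes are ~5× more polymorphic in bv. orientalis
(0.049) than in bv. officinalis (0.010), and orientalis core genes
evolve under driving selection (pooled dN/dS ≈ 2.1, class D). The
officinalis core pool is simulated neutral; at this reduced size (40
genes) its pooled ratio drifts to 0.84 and classifies P — at the
default 200 genes it sits at ≈1.07, class N (see the acceptance run
below). The officinalis sym pool is NaN because at the study-condition
polymorphic fractions almost no officinalis sym gene varies — exactly
the signal sparsity the real collection shows. `demo_out/` holds the full report bundle:
`gene_metrics.tsv`, `table1.tsv`, `table2.tsv`, `polymorphic_fractions.tsv`,
`gene_quadrants.tsv`, `gogs.tsv`, `contingency.tsv`, `highinhigh.tsv`,
`core.nwk`, `sym.nwk`, ANI matrices and a `manifest.json` recording the
seed and every parameter.

The same run from a shell:

```sh
symcore run --out demo_out --seed 3 --n-perm 2000
symcore simulate --seed 7 --out my_dataset     # just the synthetic data
symcore report --metrics demo_out/gene_metrics.tsv --out demo_out/re
```

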