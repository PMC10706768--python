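# Methods

`symcore` compares the evolutionary dynamics of core (housekeeping) and
symbiotically specialized (*sym*: nod, nif, fix) genes in a two-biovar
rhizobium strain collection. This note documents the models, estimators,
parameter choices and known limitations.

## Core-genome construction

Genes of every strain are matched against genes of every other strain by
exact Needleman–Wunsch global alignment (match +1, mismatch −1, linear
gap −2, via Biopython's `PairwiseAligner`). Identity is defined as
identical columns divided by *all* alignment columns, gap columns
included — the stricter denominator, chosen so tests are bit-exact.
Candidate pairs are pre-screened by shared 12-mers (≥3 shared) before the
exact aligner runs; the screen prunes only pairs far below the 70 %
acceptance threshold, mirroring the seeding role a heuristic aligner
plays at genome scale. Per strain pair, scored candidates are accepted
greedily in descending identity, one-to-one, at ≥70 % identity.
Accepted pairs are merged transitively (union–find); a group enters the
core set only with exactly one member in every strain. Groups where two
genes of one strain collide (paralogy) are dropped and logged —
ambiguity is resolved conservatively by exclusion.

## Polymorphism (p-distance)

Ortholog groups whose members share one length pass through unaligned
(intact orthologous CDSs stay in frame); unequal lengths trigger a
centre-star progressive alignment (centre = sequence with greatest
summed identity; once-a-gap-always-a-gap merge), or optionally an
external tool (`mafft`) via a hook that is off by default.

The pairwise p-distance counts columns where both strains have a
determined base (A/C/G/T); gaps and Ns are excluded *pairwise*, and the
substitution count is divided by the comparable-column count. No
multiple-hit correction is applied to p-distances, by definition. A
gene's polymorphism in a biovar is the mean off-diagonal entry of its
p-distance matrix restricted to that biovar's strains — within-biovar
pairs only, so divergence between biovars is not conflated with
polymorphism. A gene is polymorphic in a biovar iff this mean is > 0.

## dN/dS

Each sense codon has nine single-nucleotide neighbours; its synonymous
fraction is syn/(syn+nonsyn) with stop-codon neighbours excluded from
the denominator (alanine codons: 3/9 = 1/3). For two observed codons
differing at k ≤ 3 positions, synonymous and nonsynonymous difference
counts are averaged over all k! single-step pathways that avoid stop
codons; if every pathway is blocked, positions are classified
independently in the context of the first codon, with a step landing on
a stop counted as nonsynonymous. Codons containing a gap or N in either
row are skipped whole.

For a strain pair: Sd, Nd are the summed difference counts; synonymous
sites S = Σ 3·mean(syn fractions of the two codons), nonsynonymous sites
N = 3L′ − S over L′ comparable codons; pS = Sd/S and pN = Nd/N are
Jukes–Cantor corrected (d = −¾ ln(1 − 4p/3)) and the ratio dN/dS
returned. The ratio is undefined (NaN) when dS = 0 or a proportion is
saturated; undefined pairs are excluded from the gene's per-biovar mean
rather than imputed. An alternative per-codon-average normalisation
(raw counts divided by comparable codon count) is available behind a
flag. The pooled selection class uses a 95 % normal interval:
D (driving) if mean − 1.96·SE > 1, P (purifying) if mean + 1.96·SE < 1,
else N (neutral).

Known limitation: the pairwise ratio estimator is upward biased when the
expected synonymous count per pair is small (noisy denominator). At
within-biovar divergence 0.05 and ~200-codon genes the bias is around
+5–10 %; it falls below the across-gene standard error at divergence
≈0.10 with 400–500-codon genes, which is where the neutral-calibration
test operates. Estimates at very low divergence should be read as
upper-bounded indicators, not unbiased rates.

## Pooled statistics and quadrants

Per biovar, the p-distance pool contains genes polymorphic there; the
dN/dS pool contains genes with a defined ratio; correlations
(Pearson r, significance via t = r√((n−2)/(1−r²))) use the
intersection; polymorphic fractions k/n (binomial SE √(p(1−p)/n)) are
over all genes of the group. Pool means are compared with Student's
t = Δ/√(SE₁²+SE₂²) on n₁+n₂−2 df (plug-in SEs); correlations between
biovars are compared by Fisher z. SE of a pooled mean is sample
SD/√n over per-gene values.

Quadrants partition genes by whether a metric is above its pool mean in
each biovar: I = Ori+Off+, II = Ori−Off+, III = Ori+Off−, IV = Ori−Off−.
"Above" is strict; a value exactly at the mean counts as below (the
deterministic tie rule). The quadrant pool is the core genes polymorphic
in both biovars with both dN/dS values defined; its per-metric means are
the thresholds.

## GO groups

A GOG is the set of quadrant-pool genes annotated with one GO term
(≥2 members). Its enrichment in a biovar is member mean / pool mean of
a metric; a GOG is *contrasting* when its enrichment deviates from the
across-GOG average by more than the across-GOG SD in at least one
biovar — thresholds are computed from the data each run, never fixed.
Contrasting GOGs are cross-tabulated by their p-distance and dN/dS
quadrant clusters. High-in-High/High-in-Low compares, within one
biovar, the frequency of metric-B-elevated GOGs among metric-A-elevated
versus metric-A-decreased GOGs.

GO-group prevalence in a gene sample is
P_enrich = N_obs/(S_sep·N_sep/N_genome) — observed over expected under
proportional sampling. Significance comes from a permutation test that
redraws the sample (the member count of a uniform random sample is
hypergeometric and is sampled directly), with the add-one estimator
p = (1+k)/(n_perm+1), one-sided for enrichment; 10,000 permutations by
default. For coarse count supports (small groups/samples) the discrete
p is conservative rather than uniform under the null; uniformity holds
at genome-scale sizes (thousands of genes), which is where the
calibration test operates. GO term ancestry (DAG propagation) is not
applied; annotations are consumed as a flat gene→term table.

## Trees and congruence

ANI between two strains over a gene set is 1 − length-weighted mean
p-distance (weights = alignment lengths; pairs with undefined p for a
gene drop that gene from that pair's weighting). Trees are
neighbor-joining (scikit-bio) on 1 − ANI with negative branch lengths
clamped to zero; congruence is the Robinson–Foulds distance between the
unrooted core and sym trees normalised by its maximum 2(n−3).

## Synthetic collections

The generator emulates a 14-strain collection: 6 bv. orientalis +
8 bv. officinalis, 200 core genes and 39 sym genes (16 nod, 8 nif,
15 fix), gene lengths uniform in 100–400 codons. All genes evolve on a
single two-clade strain tree (one clade per biovar), so core and sym
phylogenies are congruent by construction — no horizontal transfer, no
recombination, no indels, no IS elements.

Sequence evolution is proposal/acceptance: substitution proposals arrive
as a Poisson process, uniform over sites and alternative bases;
stop-creating changes are always rejected; synonymous : nonsynonymous
acceptance odds are 1:ω (probabilities min(1, 1/ω) and min(1, ω)).
Ancestral sequences are uniform over the 61 sense codons.

Calibration: configured divergences are the target expected pairwise
p-distances. Within each clade, join heights are evenly spaced with
±10 % jitter (ultrametric), the topology is a random sequence of
pairwise joins, and all within-clade branch lengths are rescaled so the
mean pairwise path equals the Jukes–Cantor-inverted target; stems to
the root are set the same way for the between-biovar target. Per branch
the proposal rate is the accepted-substitution target divided by the
acceptance probability computed from the gene's ancestral sequence and
the branch's ω. Even spacing keeps every internal branch a bounded
fraction of clade depth, so the topology is recoverable at
officinalis-level divergence (0.010); iid-uniform heights would make
some branches unresolvably short.

Default evolutionary regimes mirror the study conditions: within-biovar
divergence 0.048 (orientalis) / 0.010 (officinalis), between-biovar
0.15; polymorphic gene fractions 0.746/0.759 (core, ori/off) and
0.385/0.077 (sym); single ω classes 1.571/1.013 (core) and 1.009/0.272
(sym). Per gene and biovar, a Bernoulli draw against the polymorphic
fraction decides whether the within-clade branches are active or zeroed
(an invariant gene still diverges between biovars through the stems —
which also means cross-biovar divergence of invariant genes falls
slightly short of the 0.15 target). `omega_divergence_coupling` scales a
gene's within-biovar divergence by ω^coupling (default 0 = uncoupled),
letting simulations couple selection strength to polymorphism for
sign-recovery experiments. GO labels are assigned by drawing term sizes
from a geometric distribution (mean 8 genes) and sampling members from
the core pool so terms overlap (40 terms by default).

What passing tests on these collections do **not** show: the generator
has no rate heterogeneity across sites, no codon-usage bias, no
recombination or transfer, and branch-wise ω rather than site-wise
selection — conclusions about real data rest on the estimators, not on
the realism of this null world.

## Problem sizes and determinism

All randomness flows from a single integer seed (NumPy `default_rng`);
identical configs produce byte-identical files and reports. The test
suite runs collections of 15–60 genes with 80–500-codon genes (about
30 s total); the acceptance script runs the full default-size pipeline
(200 core + 39 sym genes, 14 strains, 10,000 permutations), about three
minutes on one CPU, dominated by the exact all-strain-pair alignment
stage. At the study-default polymorphic fractions the sym gene set
carries almost no within-officinalis signal, so the sym NJ tree is
unresolved there and the reported core-vs-sym RF is nonzero; RF = 0 is
recovered when all genes are polymorphic (the transfer-free congruence
property is tested under that condition).
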