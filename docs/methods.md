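# Methods

## Scope and model

`cholnet` analyses pre-normalized log2 expression matrices from two designs
that are individually underpowered and jointly informative:

1. **Replicated two-group comparison** (e.g. hypercholesterolemic vs
   normocholesterolemic diet, n = 2 biological repeats per group). Per-gene
   evidence combines a pooled-variance two-sample t statistic and a
   log2-median-ratio statistic through permutation nulls, Storey FDRs and a
   Stouffer combination.
2. **Unreplicated two-timepoint time course** (e.g. 0/3/16 h in
   cholesterol-depleted medium, one array per timepoint). With no
   within-timepoint variance, genes are called purely by log2 fold change
   against baseline.

Downstream, DEG lists from the two systems are intersected through an
ortholog map, classified by sign concordance, and the discordant genes seed
an interaction-network model in which regulators are ranked by degree
centrality.

## Statistical choices

**Pooled-variance t, not Welch.** At n = 2 per group the Welch degrees of
freedom are degenerate and no t reference distribution is used anyway —
p-values come from permutations, so the statistic only needs to rank genes.
When the pooled standard error is zero the statistic is a signed-infinity
sentinel (zero if the mean difference is also zero); rank-based p
computation handles the sentinel without special cases.

**Log2-median-ratio** is the difference of group medians of the log2
values (equivalently the log2 ratio of antilog medians). Medians of log2
values, rather than log2 of raw-scale medians, keep the statistic a pure
location difference on the modelling scale.

**Permutation null, pooled across genes.** The set of distinct relabelings
of a 2 v 2 design has C(4,2) = 6 members, and the observed assignment and
its mirror always tie the observed |statistic|, so a per-gene permutation
p-value has a floor of 1/3 — too coarse for any FDR procedure to call
anything at 5%. The default (`null_mode="pooled"`) therefore excludes the
observed assignment and its mirror and pools the remaining relabelings'
statistics over all genes into one empirical null ensemble;
`p = (#{|null| ≥ |obs|} + 1)/(N_null + 1)` (add-one so p > 0 always). The
per-gene formula, `p = #{relabelings with |stat*| ≥ |obs|}/n_perm` counting
the identity, remains available as `null_mode="per_gene"`; both modes are
verified against brute-force enumeration. Designs with more than
`permutation_cap` (default 10,000) relabelings are sampled without
replacement from the seeded generator, identity always included.

**Storey FDR.** π₀ is the median over the λ grid (default 0, 0.05, …,
0.90) of `#{p > λ}/((1−λ)·n)`, clamped into (0, 1] with lower clamp 1/n (a
π₀ of exactly zero would zero every q-value). The median replaces Storey's
spline smoother, which is unstable at small gene counts. Q-values are the
usual `min_{j≥i} π₀·n·p_(j)/j`, capped at 1.

**Stouffer combination of FDRs.** The per-test FDRs themselves (not raw
p-values) are probit-transformed, averaged with √k scaling and transformed
back. Inputs are clamped to [1e−15, 1−1e−15] before Φ⁻¹. Z-scores are
unsigned: the two statistics share the effect's sign, and genes whose
evidence disagrees in direction are screened out by the fold-change gate
rather than by sign cancellation.

**DEG rule.** `FDR_overall < α` AND `|log2FC| > τ`, both strict, defaults
α = 0.05, τ = 0.585 (1.5-fold). log2FC for the two-group design is
mean(A) − mean(B) on the log2 scale.

**Patterns.** With states up/none/down at two post-baseline timepoints and
the all-none pair excluded, exactly 8 classes exist. Numbering is the
lexicographic order over (state_early, state_late) with up < none < down —
a fixed convention chosen for determinism, not a claim about any particular
published figure's group labels.

**Integration.** A time-course gene counts as differentially expressed if
called at either timepoint; its direction comes from the late timepoint
when called there (the late response dominates such designs), otherwise the
early one, and a direction conflict is resolved toward the larger |log2FC|.
One-to-many ortholog pairs are collapsed greedily by the map's resolution
policy (default: keep the partner with the strongest fold change, ties
alphabetical) so each symbol appears in at most one record. The four
concordance groups (both_up, both_down, and the two mixed groups) partition
the intersection; the two mixed groups form the discordant set.

**Enrichment.** Upper hypergeometric tail `P(X ≥ k)` with the universe
defined as the genes present on the platform/matrix, not the genome.
Benjamini–Hochberg q-values are reported across terms alongside raw p; the
EASE-style penalized score used by some web tools is deliberately not
reproduced.

**Network.** "Contributes to connecting DEG nodes" is operationalized as
adjacency to ≥ 2 DEG nodes; the rule is applied in a single pass and is
idempotent because removing non-DEG nodes cannot change anyone's DEG-
neighbor count. Chains of two or more neighbors between DEGs are
intentionally not rescued — in a first-neighbor network such chains are
second-order. Degree centrality counts DEG neighbors only (the quantity
that measures regulatory reach over the DEG set); total degree is emitted
alongside for transparency. Protein–DNA edges are treated as undirected for
centrality. Ranking ties break alphabetically.

## Synthetic data

The generators produce the structure the statistics assume, not realistic
microarray data. Baseline log2 expression is Normal(7, 1.5) — a
conventional gcRMA-like scale — with Gaussian noise on the log2 scale and
planted mean shifts of ±effect_size. Defaults encode the study conditions:
2 samples per group, 5% planted DEGs split evenly up/down, 2.0 log2-unit
effects, 0.25 log2-unit noise for the two-group design; 1.0-unit effects
and 0.2-unit noise for the single-sample time course (0.25/2 in the
composed study, reflecting that an unreplicated design has no averaging).
The background interactome is Erdős–Rényi — chosen for analytic expected
degrees — with hubs planted by explicitly wiring a regulator to a stated
number of distinct DEG targets; the hub supplies the heavy tail that
matters for ranking. Not emulated: probe-level effects, batch effects,
correlated genes, mean–variance dependence, scale-free background topology,
or a realistic GO DAG. Passing tests therefore demonstrate the statistical
machinery under its own assumptions, not performance on real arrays.

## Problem sizes and numerics

Simulation-based checks run at 1000 genes × (2 v 2): 200 replicates for
null FDR control, 50 for planted-effect recovery, 100 seeded interactomes
(~35 DEGs, 50 background nodes, background edge probability 1/84 for an
expected degree near 1) for hub ranking — sizes at which the Monte-Carlo
error of the reported proportions is a few percent. Exhaustive-enumeration
oracles run at ≤ 20 genes (permutations) and universes ≤ 12 (enrichment),
where brute force is exact. All randomness flows through
`numpy.random.default_rng` seeds; reruns with the same seed are
byte-identical, including GraphML output (node insertion is sorted).

## Known limitations

* The pooled empirical null assumes genes are roughly exchangeable under
  the null; strong mean–variance trends would distort it. The t statistic
  at n = 2 is heavy-tailed under permutation, so most of the small-sample
  power comes from the median-ratio branch of the combination.
* Storey's median-over-λ estimator is slightly conservative when the
  p-value distribution is very discrete.
* The time-course caller supports exactly two post-baseline timepoints; it
  is a thresholding rule, not a model-based trajectory test.
* Ortholog resolution is greedy; a maximum-weight matching could differ on
  densely many-to-many maps.
* Probe-set-to-gene collapsing is out of scope: matrices are assumed to be
  one row per gene symbol, and identifier matching is exact and
  case-sensitive.
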