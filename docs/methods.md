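# Methods

## The model

`feralmix` quantifies the ancestry of individual genotyped animals against a
panel of K reference clusters under the standard admixture model.  Each
individual carries an ancestry vector **q** on the K-simplex; cluster *k* is
characterised by allele-B frequencies *f<sub>kl</sub>* over L biallelic,
autosomal, unlinked SNP loci.  Genotypes (allele-B dosages, 0/1/2) are
binomial draws:

    g_l ~ Binomial(2, pi_l),     pi_l = sum_k q_k f_kl

The log-likelihood of one individual is
`sum_l [ log C(2,g_l) + g_l log pi_l + (2-g_l) log(1-pi_l) ]`, with missing
loci contributing zero.  Loci are treated as independent (no linkage
disequilibrium); this is both the model assumption and the condition under
which the across-locus bootstrap (below) is valid.

**Supervised mode.**  Reference samples have their ancestry pinned to unit
vectors; a single query's **q** is maximised by EM.  In `joint` mode (the
pipeline default) the cluster frequencies F are re-estimated each sweep from
the reference members *plus* the query's expected allele assignments,
mirroring supervised analyses in which the analysed sample contributes to
the frequency estimates — which is also why the pipeline queries one sample
per run, so no query perturbs another's reference frequencies.  In
`fixed_frequencies` mode F is held at the empirical per-cluster estimate
(the fast path; with clusters of ≥ 50 members the two modes agree to well
within 0.01 per component, which we test).

**Unsupervised mode.**  All samples' **q** and F are estimated jointly by
EM from seeded Dirichlet(1) starts, best of `n_restarts` (default 3) by
log-likelihood.  The pipeline uses K = 2 over declared lineage super-groups
to partition each query between two ancestral lineages while letting
reference samples show introgression.

## Estimation details

* **EM updates.**  The E-step attributes each allele to a cluster with
  responsibility `q_k f_kl / pi_l` (B alleles) or `q_k (1-f_kl) / (1-pi_l)`
  (A alleles); the M-step renormalises attributed alleles into q (and, where
  free, F).  Every sweep is monotone in the objective.
* **Acceleration.**  Both fitters wrap plain EM in a squared-extrapolation
  (SQUAREM-style) cycle: two EM steps define a secant direction, the
  extrapolated point is projected back to the constraint set, stabilised
  with one further EM step, and accepted only if it improves the objective
  — otherwise the plain double-step is kept.  The recorded log-likelihood
  trace is therefore non-decreasing either way (asserted to 1e-9 in tests).
  Observed speedup is roughly an order of magnitude at negligible cost.
* **Convergence.**  Stop when the objective improves by < `tol`
  (default 1e-6, absolute) or at `max_iter` (default 2000); non-convergence
  is flagged, not fatal.
* **Numerical floors.**  Frequencies are clamped to [1e-6, 1 - 1e-6]
  everywhere they are produced.  `estimate_cluster_frequencies` adds a
  Jeffreys-style pseudocount (default 0.5) so rare alleles in small clusters
  stay off the boundary; EM frequency updates use no pseudocount (pure
  M-step) but are clamped.
* **Degenerate inputs.**  An all-missing query raises; an all-missing locus
  in a cluster falls back to the pseudocount prior mean (0.5) and is
  flagged by a zero observation count.

## Bootstrap standard errors and significance

SEs come from resampling loci uniformly with replacement (`n_boot` default
100, matching the study design) and rerunning the supervised fit per
replicate; `se_k` is the SD of `q_k` across replicates.  The reported point
estimate is the full-data fit, not the bootstrap mean (the source design is
silent on this; full-data is the conventional choice and is logged).
Cluster *k* is called significant when `q_k - m * se_k > 0`; the "standard
error does not overlap zero" rule is read literally as m = 1 by default,
with m configurable (e.g. 1.96) for the stricter interpretation.
Calibration is checked empirically: across independently re-simulated
datasets, the mean bootstrap SE must sit within a factor 1.5 of the true
sampling SD of the estimate.

## Relatedness (pi-hat) and pruning

Pairwise IBD uses the classical method-of-moments on identity-by-state
counts: observed counts of loci at IBS 0/1/2 are compared with their
frequency-dependent expectations under IBD states Z = 0/1/2, solved
sequentially, clamped to [0,1], renormalised; `pi_hat = z1/2 + z2`.
Frequencies are clamped to [0.01, 0.99] first.  Pairs with `pi_hat` at or
above the threshold (default 0.70) are pruned greedily: the member with
more high-relatedness partners is removed first (ties: higher missingness,
then the lexicographically later id).  The source design states only that
dyad members were removed; the greedy rule is this package's declared
choice, and pruning is idempotent.

## Cross-validation over K

Model choice uses masked-entry cross-validation: non-missing genotype cells
are partitioned into folds (default 5), each fold is masked in turn, the
model refit, and masked genotypes scored by binomial deviance against the
predicted dosage `2 sum_k q_ik f_kl`.  Predictions are clamped to
`[1/(2n), 1 - 1/(2n)]` before scoring; without this continuity correction a
single held-out allele contradicting a boundary frequency estimate (clamped
at 1e-6, deviance ≈ 55) dominates the score and the CV curve loses its
minimum at the true K — we verified both behaviours on 4-cluster synthetic
panels.  Selection of K remains user-driven (the curve is returned; the
default pick is the CV minimum).

## Runs of homozygosity

A reportable ROH is a maximal run of consecutive same-chromosome markers
with ≤ 1 heterozygote, ≤ 2 missing calls, every adjacent gap ≤ 600 kb,
whole-segment density ≤ 80 kb/SNP, ≥ 25 SNPs and ≥ 500 kb — the density,
gap and heterozygote ceilings follow the source protocol; the minimum size
and missing-call allowance are unstated there and default to the
Meyermans-style conventions (configurable, and set to 0 in tests that probe
pure density/gap logic).  "Maximal" means one-marker extension on either
side violates a constraint; overlapping maximal candidates are resolved by
keeping the longer (ties: leftmost) and iterating.  These are direct
segment-scan semantics — deterministic and oracle-verifiable — rather than
the sliding-window heuristic of the original tooling, whose window
internals are not part of the stated constraints; outputs can differ from
that tool on edge cases near the window size.  Density is evaluated on the
whole segment, and segment endpoints are the first/last SNP positions.
fROH divides summed segment length by the Sscrofa11.1 autosomal constant
2,265,775 kb; "long" segments are strictly > 10 Mb.  The scanner is tested
for exact equality against an exhaustive O(n²) enumeration oracle on 1,000
random chromosomes straddling every constraint boundary.

## PCA projection

Reference PCA mean-imputes missing dosages per locus, column-centers
(optional per-locus scaling, off by default — dosages share a scale and the
source protocol does not mention scaling), and takes the thin SVD.  Signs
follow the convention that each component's largest-magnitude loading is
positive.  Queries are imputed and centered with the *reference* means and
multiplied by the reference loadings, so queries can never alter the axes.

## The synthetic generator

The generator emulates the statistical structure the estimators assume:

* **Cluster divergence** follows the Balding–Nichols model: ancestral
  frequency `p_l ~ Uniform(0.05, 0.95)` (avoiding monomorphic loci;
  overridable), cluster frequency
  `f_kl ~ Beta(p_l (1-Fst)/Fst, (1-p_l)(1-Fst)/Fst)`, so the across-cluster
  variance is `Fst p_l (1-p_l)`.  Default Fst 0.15 — the scale of
  divergence among domestic pig breed clusters.
* **Genotypes** are Hardy–Weinberg binomial draws from individual-specific
  mixed frequencies; admixed queries carry known ancestry vectors.
* **Related pairs**: duplicates (identical rows), parent–offspring (one
  allele transmitted per locus, one drawn from the population), unrelated.
* **ROH genomes**: markers at fixed spacing (default 50 kb, so density and
  gap rules are analytically checkable), planted segments fully homozygous
  with optional injected heterozygote errors, background heterozygosity
  elsewhere, optional uniform missingness.

What it does **not** emulate: linkage disequilibrium, ascertainment bias of
the SNP array (which in real data flattens resolution among Asian
lineages), genotyping error, pedigree structure beyond single dyads, or
coalescent depth.  Passing tests therefore demonstrate correctness of the
estimators under their own model assumptions — not robustness to array
ascertainment or LD, which real panels exhibit.

## Problem sizes used in tests and the acceptance script

Supervised recovery runs 50 simulations at K=5, Fst=0.15, L=5,000, n=50 per
cluster; bootstrap calibration uses 200 re-simulated datasets (L=5,000)
with 100-replicate bootstraps on 20 of them; the ROH oracle comparison uses
1,000 random 200-marker chromosomes; the end-to-end pipeline demonstration
uses a 5-cluster panel (L=3,000, n=40 per cluster) with 20 queries and
100-replicate bootstraps.  These sizes keep the full run at desk scale
while leaving each estimate's sampling noise well inside the asserted
bounds.

## Known limitations

* The supervised estimator is the exact MLE of the stated model; its
  total-variation error at K=5/L=5,000/Fst=0.15 is ~0.04 (mean per-component
  error ~0.018), dominated by one-sided spillover onto true-zero ancestry
  components — an intrinsic boundary property of simplex MLEs, not an
  optimisation failure (the grid-search oracle agrees to 0.002).
* Relatedness uses allele frequencies estimated from the supplied panel;
  strong structure in that panel biases pi-hat upward for within-cluster
  pairs.  For pruning at the 0.70 threshold this is immaterial.
* The ROH scanner is O(n · run-length) per chromosome; genuinely homozygous
  whole chromosomes approach O(n²) but stay fast at array densities.
* No haplotype/LD-aware models, no ancestry tracts, no X chromosome.
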