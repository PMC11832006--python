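# Methods

This note documents the models, statistics and design choices behind
`mrpipe`, in the order the pipeline runs them, together with what the
synthetic-data generator does and does not emulate.

## Differential expression per sample

Each tumor sample is compared alone against the reference group. This is a
deliberate departure from cohort-level models: the scientific object of
interest is the per-sample signature, so no information is shared between
tumor samples.

**Normalization.** Median-of-ratios size factors against the geometric-mean
pseudo-reference over genes with all-positive counts, rescaled to geometric
mean 1. When no gene is positive everywhere the factors fall back to
library sizes (logged). GC-content and transcript-length effects are not
modeled; the pipeline takes raw counts as given.

**Filtering.** Genes whose mean normalized count falls strictly below the
25th percentile (linear interpolation) of all gene means are removed.
Strict comparison means an all-equal cohort loses nothing.

**Test.** The tumor count x_gs is tested as an outlier of the reference
distribution: two-sided negative-binomial tail probability
min(1, 2·min(P(X ≤ x), P(X ≥ x))) including the observed point mass (the
doubling convention is stated because discreteness makes "two-sided"
ambiguous). The null mean is the normalized reference mean scaled by the
tumor size factor. The null dispersion has three components:

* a per-gene method-of-moments estimate φ̂_g = max(0, (v_g − m_g)/m_g²)
  from the reference samples;
* shrinkage toward a pooled common dispersion
  φ̂_c = Σ(v_g − m_g)/Σ m_g² with weight `dispersion_shrink` (default 0.8 —
  with ~4 residual df per gene the per-gene estimate carries little
  information relative to the pooled one);
* an inflation term for the sampling error of the estimated reference
  mean: φ_test = φ̂·(1 + 1/R) + 1/(R·m̄). With R = 5 reference samples the
  plug-in test that ignores this error is visibly anti-conservative; the
  delta-method correction restores near-nominal type-I error (the test
  suite checks the p < α rate on effect-free simulations against a 3-SE
  binomial band).

logFC uses a pseudocount of 0.5 on both sides to avoid infinities. Calls
are +1/−1 when |logFC| > 1 and BH-adjusted p < 0.05, else 0. The stage does
not attempt to reproduce any specific published DE tool; it is a pluggable
default, and externally computed signature tables can be substituted.

## TF activity

The per-sample logFC signature is reduced to fractional ranks
r_g = (rank_g − ½)/n (ties averaged) and normal scores z_g = Φ⁻¹(r_g). A
regulon with measured targets T and modes w_t ∈ {±1} scores
NES = Σ w_t z_t / √|T|, which is standard normal when gene labels carry no
information — verified by a 10⁴-draw permutation KS test. Regulons with
fewer than `min_targets` (default 5) measured targets are skipped as
statistically meaningless. p-values are BH-adjusted across TFs within each
sample (the alternative — one global adjustment — is defensible; the
per-sample choice matches the per-sample design of everything else).
Interaction-confidence weights, three-tail combinations and pleiotropy
corrections used by richer activity-inference frameworks are intentionally
omitted: with ±1 modes the two-tailed analytic rank enrichment is the core
of the statistic, and the scorer sits behind an interface that admits
replacements.

## Causal upstream reasoning

Signed breadth-first search computes, for a hypothesis node, the shortest
directed distance and the sign product to every reachable node; equal-length
shortest paths with conflicting products mark the target *ambiguous*
(non-informative — they neither support nor contradict, matching the
convention of signed causal-reasoning tools). The hypothesis "node h has
state σ" predicts state σ·sign(h→t) for each observed TF t; the score is
explained minus contradicted observations.

**Permutation null.** The observed TF-state multiset is reassigned
uniformly across the observed positions. When the number of distinct
assignments C(n, n₊) is ≤ 10⁴ the null is enumerated exhaustively
(p = #{score ≥ observed}/total); otherwise Monte-Carlo with the
(1 + count)/(1 + n_perm) estimator. A consequence worth knowing: a sample
whose observed TFs all share one sign has a degenerate null (every
reassignment ties, p = 1), so such samples can never yield causal calls —
power comes from sign-diverse observations.

**Merging.** Calls (score > 0 and p < α; the positive-score requirement is
an explicit assumption — a "regulator" that contradicts more than it
explains is not a regulator) are unioned over δ = 1..3; union rather than
intersection, since intersection would make the deeper runs redundant.
Nodes significant with opposite signs at different deltas are controversial
and removed. Hypothesis p-values are not multiplicity-adjusted by default
(a BH option exists): the selection stage downstream provides the real
error control. TFs participate as hypotheses too (distance-0 self-path,
sign +1), so TF and upstream calls live in one candidate space.

## Feedback-loop selection and integration

For each regulator, the state vector across tumor samples (+1/−1/0) is
compared with its encoding gene's DEG-call vector by cosine similarity
(zero-norm vectors score 0 by convention). Selection requires cosine > 0.3
and a percentile-bootstrap 95% CI (B = 1000 position resamples) whose lower
bound exceeds 0. Regulators without a measured encoding gene are reported
as unselected, never dropped. With 30 samples the CI criterion effectively
demands ≥ 4 concordant nonzero samples — a floor on evidence, not a bug.

States and calls merge to integers in −3..3 exactly as the truth table in
the README; the matrix is biclustered with Ward linkage (Lance–Williams on
the condensed 1−cosine distance matrix, i.e. the "ward.D2" convention —
the linkage backend is scipy, whose nearest-neighbor-chain algorithm is
deterministic on identical input). All-zero matrices are rejected rather
than clustered on degenerate distances. Dendrograms are exported as Newick.

## Network analysis

"Connected" for the induced MR subnetwork means *weak* connectivity — the
question is whether the selected regulators interact at all, not whether
they form directed cycles. The random null draws `n_draws` uniform node
subsets of the same size and records, per draw, the largest weakly
connected component's size and internal edge count (edge counts are
LCC-restricted for comparability with the observed statistic).

Structural controllability uses the maximum-matching characterization: in
the bipartite graph of out-copies vs in-copies (one edge per distinct arc),
n_drivers = max(1, N − |maximum matching|), and the nodes with unmatched
in-copies are a valid driver set (the matching is computed by Hopcroft–Karp
on a deterministically ordered graph; driver sets are not unique, the
implementation returns the one its matching realizes, sorted). Outdegree
counts distinct out-neighbors (parallel opposite-sign edges once);
closeness is 1/Σ d(u,v) over nodes reachable from u, 0 when nothing is
reachable.

The bulk TF-target network keeps an annotated stimulation when
cosine(TF state, target DEG) > 0.3 with CI lower bound > 0, and an
annotated repression when cosine < −0.3 with CI *upper* bound < 0 — the
mirror-symmetric reading; the asymmetric variant (lower bound < 0) is
available behind `literal_ci=True`. Per-TF outdegrees are reported twice:
over all included targets and restricted to a supplied MR gene list.

## Annotation

Over-representation is the one-sided hypergeometric upper tail against a
user-supplied universe, BH-adjusted, with the pipeline filter ≥ 2 query
genes in the set and raw p < 0.05. The immune infiltration score is a
single-sample rank-weighted enrichment statistic (weights rank^0.25,
difference of in-set weighted and out-set unweighted cumulative
distributions summed along the ranking); it is a pure rank statistic, so
any monotone normalization of the expression column leaves it unchanged.
No published signature lists are bundled; the score takes any gene set.
The dual-level Kendall screen requires positive, significant (p < 0.05)
tau-b at both the discrete-state level and the (normalized) expression
level; which expression quantity to correlate was an open choice and
normalized expression is used. Single-cell summaries are mean tpm and
percent of expressing cells per gene and cell type, with decile histograms
of the percentage.

## Synthetic data: what it emulates and what it does not

The generator builds a three-layer feed-forward signed network (upstream
regulators → signaling intermediates → TFs), signed regulons over a gene
universe, per-sample planted regulator states, and NB counts:

* Counts: gene baseline means log-uniform on [20, 2000]; references drawn
  NB(μ, φ), tumors NB(μ·2^Δ, φ) with Δ the planted signed logFC and
  φ = 0.05 by default. Moments verified against the NB identity
  var = μ(1 + φμ).
* Network: each possible inter-layer edge present with probability 0.35,
  inhibitory with probability 0.35; top-layer nodes are guaranteed fan-out
  ≥ 2 (a "master" regulator is pleiotropic by definition). Every network
  node has an encoding gene whose baseline mean is drawn from the upper
  three quartiles of the mean distribution — mirroring the fact that a
  signaling network restricted to expressed genes contains no
  quartile-filtered regulators.
* Planting: per tumor sample each top-layer regulator is +1 with
  probability 0.30 and −1 with 0.12. States propagate along signed shortest
  paths with the same ambiguity semantics as the causal engine; influences
  from multiple planted regulators combine *additively* (state = sign of
  the summed signed influences, ties → 0). The additive rule was chosen
  over a unanimity rule after a design-phase power analysis: unanimity
  zeroes most informative TF observations as soon as two regulators
  co-occur, making the planted-recovery task unidentifiable at the default
  scale regardless of effect size. The structural defaults above were fixed
  by the same analysis — each regulator must reach enough sign-diverse
  observed TFs for the permutation null to resolve p < 0.05 — and then
  frozen.
* Feedback: each planted regulator's own gene shifts by its state times
  the planted logFC; regulon targets are drawn from background genes only,
  so the explicit feedback rule is the *only* planted transcriptional
  feedback and the recovery target is unambiguous.
* Single cell: Bernoulli expression probability per gene and cell type
  with exponential tpm magnitudes — enough to exercise the summary
  statistics, nothing more.

Not emulated: GC/length biases, batch effects, sample contamination,
correlated gene-gene noise, regulon overlap structure, dropout beyond
Bernoulli expression, and immune infiltration gradients. Passing the
recovery tests therefore demonstrates the pipeline's statistical machinery
under its own model assumptions; it does not certify performance on real
cohorts, where normalization artifacts and mis-annotated regulons dominate.

## Problem sizes and numerical conventions

Default study: 30 tumor + 5 reference samples, 10 top-layer regulators,
10 intermediates, 20 TFs, 1000 genes — large enough that every statistic
operates in its intended regime (exhaustive vs Monte-Carlo permutation
branches, BH across 20 TFs, bootstrap over 30 positions) while a full
pipeline run stays near ten seconds. Monte-Carlo defaults: 1000
permutations, 1000 bootstrap replicates, 1000 random subnetworks. All
stochastic stages draw sub-seeds from one user seed via SHA-256 of
"seed:operation", so stages are reproducible and mutually independent.
Degenerate inputs have stated conventions rather than exceptions wherever
a convention is defensible (zero-norm cosine 0, closeness 0 for sinks,
dispersion floored at 0); genuinely ill-posed inputs (all-zero score
matrix, empty universe, regulon larger than the gene pool) raise errors.
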