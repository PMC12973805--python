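# Methods

This note documents the models and procedures the package implements,
the conventions it pins where the literature is ambiguous, what the
synthetic-data generators do and do not emulate, and the numerical
choices that matter for reproducing its outputs.

## Data model and normalization

Feature tables are taxa × samples matrices of non-negative abundances
with unique identifiers on both axes.  "Normalizing to a fixed library
size" is ambiguous between rarefaction and scaling; the default is
total-sum scaling to 100,000 reads with largest-remainder integer
rounding (column sums are exactly the target depth and within-sample
rank order is preserved), because scaling is deterministic and discards
no samples.  Rarefaction (multivariate-hypergeometric subsampling
without replacement, seeded) is available behind `mode="rarefy"` for
workflows that require equal sampling effort in the strict sense.
Per-species community profiles can be built either as summed counts or
as mean relative abundances across replicates; both modes exist because
neither is canonically "the" species profile, and the choice is
recorded in the output's provenance string.

## Diversity and PERMANOVA

Beta diversity is Bray–Curtis throughout.  Shannon entropy defaults to
natural log (the vegan convention); base 2 is available.  Faith's PD
follows the classic definition that includes the path to the tree's
root — including the root's own edge when the Newick string carries one
— because implementations differ here and the convention changes values
for shallow communities.

PERMANOVA is computed from the partition of squared distances
(SS_total = Σd²/n over all pairs, SS_within summed per group), giving
pseudo-F **and** R² = SS_between/SS_total; significance uses free
permutation of sample labels with the (1 + count)/(1 + n_perm)
estimator, so p can never be 0.  The pseudo-F is cross-checked against
scikit-bio's implementation in the test suite.  Permutation is free
(unblocked); repeated-accession designs that need restricted
permutation are out of scope.  Wilcoxon rank-sum comparisons use exact
enumeration for small groups and the tie-corrected normal approximation
otherwise (scipy's `mannwhitneyu` handles the switch).

## Phylosymbiosis testing

A phylosymbiosis test asks whether the community dendrogram (UPGMA over
Bray–Curtis distances between per-species profiles) is topologically
closer to the host phylogeny than random trees are.  Conventions:

- All three tree distances (Robinson–Foulds, matching-cluster,
  clustering-information) are **topology-only**; dendrogram branch
  lengths are ignored.  RF and CID treat trees as unrooted; the
  matching-cluster distance is computed on rooted clusters, with the
  minimum-cost perfect matching solved by the Hungarian algorithm over
  symmetric-difference costs (empty clusters as padding).
- CID is computed in bits: the summed split entropies of both trees
  minus twice the optimal-assignment mutual clustering information
  between their splits.
- The null samples **uniform unrooted binary topologies** (each leaf
  attached to a uniformly chosen edge of the growing tree), seeded.
- Congruence means *small* distance, so p = (1 + #{null ≤ observed}) /
  (1 + n_random) — a one-tailed lower-tail test.
- The normalized RF score is observed/mean(null).  Normalizing by the
  theoretical maximum 2n − 6 cannot exceed 1, but dendrograms can be
  *further* from the host tree than random trees are on average, and
  the null-mean normalization is the only convention under which such
  scores (> 1) are expressible.

Blomberg's K uses the phylogenetically corrected mean
(a = 1'V⁻¹y / 1'V⁻¹1) and the Brownian expectation
(tr V − n/Σ V⁻¹)/(n − 1); on a star phylogeny V ∝ I makes K ≡ 1
exactly, which the tests exploit as a closed-form oracle.  Significance
permutes trait values across tips (K ≈ 1 under Brownian motion; the
permutation test holds its size for exchangeable traits).  Pagel's λ is
not implemented: the congruence analysis this package supports reports
K only.

## Phylogenetic structure and assembly

SES-MPD and βNTI both standardize an observed statistic against the
"taxa labels" null — shuffling taxon identities on the phylogenetic
distance matrix (999 draws by default) — the picante default for
abundance-weighted analyses.  Weighted MPD is
Σ_{i≠j} d_ij p_i p_j / Σ_{i≠j} p_i p_j; βMNTD averages, over both
directions, each taxon's abundance-weighted distance to its nearest
taxon in the other community.  |βNTI| ≥ 2 is read as deterministic
(selection-driven) turnover and the stochastic/deterministic fractions
are simple tail counts over sample pairs.

The k-mer route replaces the taxon tree: sequences are cleaned of
non-ACGT characters (ambiguous bases are dropped, not expanded),
decomposed into overlapping 16-mers, restricted to the 5,000 k-mers of
highest document frequency, TF-IDF weighted with the smooth-idf
convention tf·(ln((1+n)/(1+df)) + 1), and L2-normalized; cosine
distance between profiles then stands in for cophenetic distance in the
weighted MPD formula.  With 16-mers, cosine distances saturate near 1
beyond ~20% sequence divergence, so the metric is most informative for
recent divergences — the tests therefore check rank structure (deep
vs shallow divergence), not absolute values.

## Sloan neutral community model

The fit estimates one parameter Nm by bounded 1-D least squares (on the
frequency scale, Nm ∈ (10⁻³, 10⁷], optimized in log space) of observed
occurrence frequencies against
f̂(p) = 1 − I_d(Nm·p, Nm(1−p)), with N the mean reads per sample and
detection limit d = 1/N (the Sloan convention).  R² = 1 − SSE/SST, and
taxa are classified against 95% Wilson binomial intervals around f̂.

A caveat the package documents rather than hides: the Sloan formula
models detection as the *latent* community frequency exceeding d,
whereas real detection is "at least one read".  On data simulated
exactly from the neutral process, the least-squares Nm therefore
converges ~25% above the process's true effective concentration
I = m(N−1)/(1−m) (verified against the closed-form beta-binomial
occurrence probabilities).  Fitted m values are best read as effective
migration rates on the model's own scale; the fit recovers Nm exactly
when occurrence is generated by the π > d rule the model assumes, which
is what the unit tests assert.

The forward simulator is a Moran process: N individuals, death/
replacement events where the replacement immigrates from the source
pool with probability m, else copies a random local individual.  Its
stationary law is Dirichlet-multinomial with concentration I, and each
community is initialized *at* stationarity by a Hoppe-urn construction
before a 10·N-event burn-in, so recorded samples are draws from the
stationary process rather than from a transient.

## Core microbiome and trait prediction

Core taxa satisfy two criteria jointly: mean relative abundance in the
top decile (taxa ranked by mean relative abundance across samples;
ties broken stably) and presence in strictly more than 50% of samples.
Levins' niche breadth B_i = 1/Σ_j q_ij² (q = the taxon's abundance
share per sample) ranges from 1 (single-habitat specialist) to the
number of samples (perfectly even generalist).

Trait prediction is random-forest regression evaluated out-of-fold:
every sample's prediction comes from the CV fold that held it out, and
MAE is computed on those predictions (10 folds and 500 trees by
default; the statistical tests use 5 folds and 120–200 trees to fit
their compute budget).  Feature importance is permutation importance
evaluated on held-out data and *pooled across folds*: one global
permutation of a feature's column, each fold's model re-predicting its
own held-out samples, importance = increase in pooled MSE, averaged
over repeats.  Pooling uses every sample for each importance score and
is substantially more precise than averaging per-fold estimates on
10-sample folds, which matters when ranking ~100 features.

The generator-side helpers `choose_trait_drivers` and
`calibrate_trait_effects` exist because a planted linear signal is only
*recoverable* if its drivers are identifiable: drivers are chosen among
core taxa by uniqueness (residual variance after ridge-regressing each
candidate on all other taxa) subject to a mutual-correlation cap, and
effect signs are assigned greedily so correlated drivers reinforce
rather than cancel, with magnitudes 1/sd equalizing variance
contributions.  A driver that is a near-linear-combination of other
taxa cannot be distinguished from its proxies by any permutation
scheme — that is a property of the inference problem, not of the
implementation.

## Correlation networks and keystone roles

SparCC estimates basis correlations from log-ratio variances
t_ij = var(log x_i/x_j) under a sparsity assumption, solving
((D−2)I + J)w = row-sums(t) for basis variances and iteratively
excluding the strongest-correlated pair (|r| above 0.1, up to 10
rounds, never isolating a taxon) before re-solving.  Point estimates
average 20 Dirichlet-resampled fraction draws (counts + 1).  Pseudo
p-values permute each taxon's counts across samples independently and
count |r_perm| ≥ |r_obs| with the (1+count)/(1+n) estimator; permuted
datasets use a single Dirichlet draw since only the null magnitude is
needed.  The permutation scheme is pinned here because bootstrap
conventions differ across SparCC implementations.

Networks keep edges with |r| above threshold and p < α; two presets
mirror common reporting (0.6 for igraph-style networks, 0.4 for SparCC
figures).  The 0.4 profile applies to |r| by default, with a signed
(r > 0.4) switch, since figure captions often omit the absolute-value
sign.  A quantitative trait can enter as a node whose edges are Pearson
correlations filtered by the same rule.  Modules come from greedy
modularity maximization on the unsigned graph (deterministic; module
ids ordered by smallest member label); Zi is the within-module degree
z-score (0 where the module's degree spread is zero), Pi = 1 − Σ
(k_is/k_i)², and roles follow the printed thresholds exactly
(≥ 2.5, ≥ 0.62; network hub = both).

## Ancestral gains and losses

Presence coding marks a taxon absent in a host species only when both
criteria fail there: mean relative abundance < 1% **and** prevalence
among that species' replicates < 20% (an OR switch exists for
sensitivity analysis; the AND reading matches "considered absent" being
the conjunction of the two printed thresholds).

Reconstruction is Sankoff dynamic programming over the rooted host tree
with asymmetric branch costs (0→1 = 1.5, 1→0 = 1 by default),
polytomies handled natively.  A character present at the root is
charged one gain on a virtual "origin" edge: every family must
originate somewhere, and without the origin charge the asymmetric
penalty could never prefer a single subtree gain (cost 1.5) over root
presence plus a loss (cost 1.0) — the reconstruction would degenerate
to "ancestrally present, lost everywhere" exactly in the cases the
gain/loss asymmetry is meant to adjudicate.  Among co-optimal
labelings, ties prefer absence (0) at the root and in the preorder
traceback, giving one deterministic labeling; the total cost is
labeling-independent and equals gain·#gains + loss·#losses, which the
DP is tested against by exhaustive enumeration.

## Synthetic-data generators

The community generator emulates the design of a replicated
common-garden study: 18 host species, 4 replicate root samples per
species (the trait analyses use 8 to approach the ~120-sample scale
such studies run), 300 taxa at 100,000 reads by default.  Host trees
are pure-birth (Yule) and ultrametric.  Per taxon, species-level
latent log-abundances are drawn from N(0, σ_b²[sC + (1−s)I]) with C the
host tree's Brownian covariance scaled to unit depth — s is the
phylosymbiosis strength; replicates add N(0, σ_n²) log-noise and are
sampled Dirichlet-multinomial (concentration 500; plain multinomial
available).  Sequences evolve on a Yule taxon tree (height 0.3
substitutions/site) under Jukes–Cantor.  Divergence classes
(early/medium/late) are assigned by thirds of the tree's tip order —
a clade-respecting proxy for real divergence phases; ploidy and life
cycle are random species-level factors.

What the generators deliberately do **not** emulate: sequencing error
and chimeras, taxon-taxon ecological interactions (taxa are
conditionally independent given host structure), compartment effects,
inter-annual environmental variation, and any coupling between the
taxon phylogeny and host-tree structure.  Passing tests therefore show
the *inference machinery* is calibrated and powerful under its own
assumptions, not that real root microbiomes satisfy those assumptions.

## Problem sizes and numerical conventions

The statistical test suite runs at desk scale, chosen to finish on one
CPU in minutes: 300 null replicates / 100 power replicates with 999
random trees for the phylosymbiosis calibration; 500 simulations for
Blomberg's K (199 permutations for size checks); 299-draw nulls for
βNTI/SES-MPD constructions; 50 neutral-model replicates at the full
m = 0.1, N = 1000, 200 × 50 design; 20 seeded trait-recovery runs at
100 taxa × 144 samples; 20 SparCC replicates at 50 × 50.  Oracle
comparisons (tree metrics, Wagner parsimony, core filters) are exact.
All stochastic procedures take explicit seeds and are reproducible;
p-value estimators everywhere use (1 + count)/(1 + n) to avoid zero.

Known limitations: PERMANOVA permutes freely (no strata); the
random-tree null is uniform over topologies (not over dendrogram
shapes, which UPGMA restricts); SparCC assumes a sparse true network
and degrades when many taxa are strongly coupled; the Sloan fit's
detection approximation biases Nm upward as described; and the k-mer
metric saturates for deep divergences.
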