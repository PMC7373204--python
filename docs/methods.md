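# Methods

## The problem

Deep-time phylogenetic inference from concatenated chloroplast
protein-coding genes faces two systematic difficulties: saturation of
synonymous sites (multiple overlaid substitutions erase signal at third
codon positions) and compositional tree-heterogeneity (equilibrium base
or amino-acid frequencies drift among lineages, violating the
stationarity assumption of standard models).  `comphet` implements the
analysis chain used to confront both: tree-independent diagnostics of
process homogeneity, codon-degenerate recoding to remove the synonymous
layer, Bayesian inference under tree-heterogeneous composition models,
and posterior predictive checking of compositional fit — together with
a synthetic-data generator that reproduces the statistical structure of
such data so every stage can be validated end to end.

## Matched-pairs tests

For sequences *i*, *j* the divergence matrix *N* counts sites by joint
state pair, using only sites where both sequences carry a canonical
state (any gap, `?`, or ambiguity code in either sequence excludes the
site; fractional allocation of ambiguity codes would break the integer
count semantics the tests assume).

* **Bowker's test of symmetry**: X² = Σ_{a<b} (n_ab − n_ba)²/(n_ab+n_ba)
  over unordered state pairs with n_ab+n_ba > 0; df = number of such
  pairs.  Pairs with an empty denominator contribute nothing and are
  excluded from the df (a fixed df of m(m−1)/2 is available via
  `fixed_df=True`; sparse amino-acid matrices make the default the
  safer convention).
* **Stuart's test of marginal homogeneity**: u = first m−1 entries of
  (row sums − column sums), V the usual covariance matrix
  (V_aa = row_a + col_a − 2n_aa, V_ab = −(n_ab+n_ba)); the statistic is
  uᵀV⁻u with a Moore–Penrose generalized inverse and df = rank(V)
  (singular values below 1e−10 of the largest are treated as zero), so
  sparse matrices degrade gracefully.
* **Ababneh's test of internal symmetry** is the difference
  Bowker − Stuart (statistic floored at 0, df difference); when V is
  nonsingular and all Bowker cells are populated the decomposition is
  exact and the dfs add.

Rejection summaries use α = 0.05 on raw p-values; no multiple-testing
correction is applied because the summaries count marginal rejections,
not discoveries.

## Degenerate recoding

`build_degen_table` groups the 64 codons into synonymous families and
maps each family to the positionwise IUPAC cover of its members
(GGA→GGN, TTT→TTY, …).  The degen-1 convention is followed: leucine
(YTN) and arginine (MGN) sixfold families are merged, serine stays as
two families (TCN, AGY — not connected by single-position synonymous
change), and the stop codons form TAR and TGA.  Recoding replaces every
complete codon by its family triplet; codons containing gap or missing
codes pass through unchanged (part-recoding would invent frame
content), and input ambiguity codes are recoded to the positionwise
union cover over all compatible codons — the package's own choice, as
the original descriptions do not address input ambiguities.

## Tree-heterogeneous composition likelihood

The model family combines symmetric exchangeabilities R (GTR for
nucleotides; empirical matrices such as gcpREV loadable from PAML-format
files for amino acids), per-node composition vectors π, and
discrete-gamma rate variation (4 equal-probability categories whose
rates are conditional bin means, overall mean 1).

* CV1: a single composition shared by all nodes — the stationary,
  homogeneous special case.
* NDCH: K composition vectors shared among nodes.
* NDCH2: one composition vector per node.

Trees are rooted.  The branch above node *v* evolves under
Q(v) with Q_ab = R_ab π_b(v), normalised so −Σ_a π_a(v) Q_aa(v) = 1:
branch lengths keep their expected-substitutions-per-site meaning in
every composition regime.  The root's own vector is the prior over root
states.  Likelihoods use Felsenstein pruning with per-pattern scaling;
each branch/rate-category transition matrix comes from the symmetric
eigendecomposition of Q (one decomposition per distinct composition
vector per evaluation).  With equal compositions this collapses exactly
to stationary GTR+Γ4 (verified against an independent implementation),
and re-rooting is a no-op by the pulley principle; with unequal
compositions the process is genuinely non-reversible and root placement
is part of the model — which is why analyses must state their rooting.

## MCMC

Metropolis–Hastings over topology (rooted NNI; SPR with explicit
Hastings accounting for prune/attach candidate counts and attachment
position densities), branch lengths and the gamma shape (multiplier
proposals), and compositions/exchangeabilities (Dirichlet proposals
centred on the current value; concentration 300/500 by default, sized
for the 20–50% acceptance range where these random-walk moves mix
best).  Priors: flat Dirichlet on all simplex parameters, exponential
(mean 0.1) branch lengths, uniform log-α on [−3, 3]; every run logs
them in its header.  Optional Metropolis coupling runs one cold plus
heated chains with inverse temperatures 1/(1+λ·rank) and periodic
adjacent-pair swap attempts.  Burnin defaults to the first 25% of
samples.

Correctness of the sampler is tested directly: NNI-only runs at fixed
parameters reproduce the brute-force enumerated topology posterior on
four taxa, and with the likelihood switched off (an all-missing
alignment) the NNI+SPR+branch-length moves sample the prior uniformly
over all 15 rooted topologies — a sensitive check of the SPR Hastings
ratio.

### Split summaries

Supports, majority-rule consensus and asdoss all operate on canonical
*unrooted* bipartitions (the side not containing the alphabetically
first taxon).  Under reversible CV1 the root is unidentifiable: rooted
clade frequencies scatter across root placements while split
frequencies are stable, so splits are the meaningful summary for both
model classes.  The consensus keeps splits with pooled frequency
strictly above 0.5 (ties at exactly 0.5 conflict and drop out), with
mean branch lengths over the trees containing each split; asdoss is the
average over splits (support ≥ 0.1 in at least one run) of the
sample standard deviation (n−1) of supports across independent runs.

### Posterior predictive composition check

The composition homogeneity statistic is the chi-square of per-taxon
canonical-state counts against pooled proportions (ambiguity and gaps
excluded, globally absent states skipped).  The posterior predictive
test thins the post-burnin trace evenly, simulates one alignment of the
original dimensions from each sampled tree/parameter set (gap-free by
default; masking the original gap pattern is an option) and reports the
fraction of simulated statistics at or above the observed one.  An
observed statistic above the whole simulated distribution (tail p ≈ 0)
means the model's compositions cannot reproduce the data's
heterogeneity.

The harmonic-mean marginal-likelihood estimate is computed stably in
log space and labelled as the crude estimator it is; it is reported for
run-legend comparability, not recommended for model choice.

## Synthetic data

`simulate_alignment` draws a root sequence from the root composition
and evolves it down the tree under each child's composition-specific
rate matrix, with one gamma category per site held fixed tree-wide.
`simulate_coding` adds the codon layer: amino acids evolve on the tree,
and each leaf's protein is back-translated by sampling codons from
leaf-specific codon-usage vectors that drift multiplicatively along
branches.  This realises synonymous variation that is rapid and
uncorrelated with topology — the saturation contrast that motivates
degenerate recoding — while guaranteeing stop-free in-frame data.
Usage vectors are defined over one degeneracy group per amino acid
(serine uses its TCN group only), which makes "recoding removes exactly
the synonymous layer" a provable property rather than an approximation;
a mechanistic codon substitution model is deliberately out of scope.

`study_like_spec` encodes the study-like conditions: ~30 taxa, 48,861
sites, per-taxon missing-data rates drawn exponential with mean ~4%
(matching the skewed per-taxon missingness of the real matrix, mean
4.38% / median 2.36%), and node compositions interpolated between an
AT-rich and a GC-rich equilibrium endpoint.  Finite branches express
only ~25–35% of the equilibrium contrast, so the endpoints (GC 0.10 and
0.75) are deliberately wider than the target: the defaults produce
observed leaf G+C spanning roughly 33–51%, the spread of the land-plant
matrix.  Defaults α = 0.5 and mean branch length 0.15 give the strong
among-lineage divergence and rate heterogeneity typical of such
concatenations.

What the generator does *not* emulate: alignment error, indels and
block-wise missingness, among-gene rate and composition differences,
selection-driven site-heterogeneity (CAT-style profiles), or
among-lineage rate variation.  Passing tests therefore demonstrate
correctness of the machinery under the model family and power against
lineage composition drift — not robustness to every real-data pathology.

## Numerical choices and scale

* Transition probabilities are clipped at 0 and rows renormalised after
  the eigendecomposition reconstruction (guards 1e−15-scale negatives).
* Per-pattern scaling in the pruning recursion prevents underflow on
  long trees; site patterns are compressed once per alignment and
  cached.
* Stuart's generalized inverse uses a relative singular-value cutoff of
  1e−10; composition vectors are floored at 1e−6 after Dirichlet
  proposals.
* Degenerate inputs are first-class: empty divergence matrices,
  all-gap rows, zero-generation chains and single-replicate predictive
  tests all return flagged results rather than raising.

Test and validation problem sizes (4–30 taxa, hundreds to a few
thousand sites, 2,000–20,000 generations) are the package's chosen desk
scale: large enough for the statistical checks to have power, small
enough that the full suite runs on one CPU in minutes.  The
parameter-recovery check uses a simultaneous 95% credible region
(Bonferroni over the seven marginal intervals: gamma shape plus six
leaf equilibrium-GC values) because independent marginal intervals
would fail ~30% of the time even under perfect calibration; sampler
calibration at this scale was verified over five independent
data/chain replicates.

## Known limitations

* The NDCH2 posterior over node compositions mixes slowly on large
  trees with single-node Dirichlet proposals; independent runs plus
  asdoss are the supported convergence check, and thresholds are left
  to the user.
* The harmonic-mean marginal likelihood has unbounded variance.
* Rooted SPR never moves the root's immediate children as a prune
  target; on very small trees this slightly restricts the move set
  (NNI retains ergodicity).
* No maximum-likelihood optimisation, bootstrap, codon models,
  site-heterogeneous mixtures (CAT), or among-lineage rate (clock)
  models.
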