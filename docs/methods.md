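# Methods

This note documents the statistical procedures, the generative model behind
the simulator, the defaults and why they were chosen, and what the test
suite does and does not demonstrate.

## Diversity estimation

Rarefaction draws exactly `d` reads from a library **without replacement**
(multivariate hypergeometric). The marginal expectation of each taxon's
subsampled count is `d·N_i/N` and the expected richness is
`Σ_i (1 − C(N−N_i, d)/C(N, d))`; both identities are verified against the
sampler in the test suite. Sampling without replacement is the convention
behind "rarefied to even depth" in community ecology software; with
replacement would be a (slightly noisier) multinomial and is not offered.

Metric conventions, where the literature is ambiguous:

* **Simpson** is reported in complement form `1 − Σp²` (values near 0.8 on
  diverse soils), not dominance `Σp²` or inverse `1/Σp²`.
* **Simpson evenness** is inverse Simpson divided by observed richness,
  `(1/Σp²)/S ∈ (0, 1]`.
* **Chao1** uses the classic `S + F1²/(2·F2)` with the bias-corrected
  fallback `S + F1(F1−1)/2` when no doubletons exist, so the estimate is
  always finite and never below observed richness.
* **Fisher's α** solves `S = α·ln(1 + N/α)` by bracketed root finding
  (Brent, absolute tolerance 1e-9). The left side is monotone in α and
  ranges over (0, N), so a unique root exists iff `S < N`; `N ≤ S` raises.
* **β-sim** uses the presence-based turnover form `min(b,c)/(min(b,c)+a)`.
  Several variants circulate; this one makes nested communities score 0 and
  satisfies `β-sim ≤ Jaccard` always. The choice is configurable at the
  function level (all three metrics are plain functions of two vectors).

`alpha_table` averages each metric over `n_rarefactions = 10` independent
rarefaction draws by default: averaging removes most single-draw subsampling
noise (verified by a variance-reduction test) at negligible cost.
`distance_matrix` deliberately uses **one** rarefaction draw per sample,
shared across all pairs, so the matrix is internally consistent; the seed is
recorded on the object.

## Reproducibility procedures

**Pseudo-β-diversity** is the dissimilarity between technical replicates of
one source sample — libraries that would be identical in a noise-free world.
`pseudo_beta_curve` rarefies every deep-enough replicate to each requested
depth (`n_draws` independent draws), scores all between-replicate pairs per
draw, and reports mean/sd per depth. Depths that fewer than two replicates
reach are dropped with a warning. The number of draws is exposed because
one-draw and averaged-draw versions of this curve both appear in practice.

**Detection consistency.** For each OTU seen in at least one replicate,
`detection_frequency` records the mean within-sample read count (zeros
included) and the fraction of replicates detecting it.
`fit_detection_model` fits detection ~ log₁₀(mean abundance) as a binomial
GLM with logit link by damped Newton/IRLS (gradient norm < 1e-8, ≤ 100
iterations), with the likelihood-ratio χ² against the intercept-only model.
Zero means must be made loggable first; two replacement conventions are both
used in the field, so both are implemented: half the minimum positive mean
(default) and a fixed 0.1. Perfect separation (including the degenerate
all-detected response) has no finite MLE; it is detected — either directly
or by the fit "converging" at saturated coefficients, where the count
gradient vanishes numerically — and returned with `converged=False` and
coefficients capped at |β| = 35.

Under pure Poisson read sampling, an OTU with mean count μ is detected with
probability `1 − e^(−μ)` (`detection_probability_closed_form`); at μ = 10
that is 0.99995, which is why "OTUs averaging > 10 reads are detected
essentially always" is a sampling-theory fact, not a biological one.

**Concordance.** `abundance_concordance` compares two libraries of one
sample over OTUs present in either, after `log₁₀(x+1)`: OLS slope/intercept
(second on first) and Pearson r. Self-comparison returns exactly
(1, 0, 1).

## Inference

`factorial_anova` wraps statsmodels OLS with **sequential (Type-I)** sums of
squares — the default of R's `aov`, which is what ecology pipelines report —
with term order following the formula. A constant response yields F = 0,
p = 1 rather than 0/0; rank deficiency beyond the listed terms raises and
names the first aliased term. The replication analysis fits the full
factorial `value ~ pool_size * source_id * platform` with pooling level as a
numeric covariate; the source × platform interaction must be in the model
because source richness differences scale with platform depth, and leaving
that interaction in the residual makes every F conservative.

`mantel` correlates the upper off-diagonal entries of two aligned distance
matrices and permutes rows+columns of the second; `permanova` partitions
squared dissimilarities one-way (`SS_total = Σ_{i<j} d²_ij / n`, within-group
analogues over group sizes) and permutes labels. Both report
`p = (1 + b)/(1 + m)`, so p is never 0 and never below `1/(m+1)`; both are
deterministic given a seed. Only separate one-way perMANOVA tests are
provided (one per factor), matching how platform and bioregion effects are
usually reported; multi-factor partitions and dispersion tests are out of
scope. With `SS_within = 0` (duplicated samples per group) the pseudo-F is
reported as +inf and the permutation test still behaves: only
partition-preserving relabelings tie it.

For joint analyses across platforms rarefied to *different* depths, the
combined distance matrix is computed on relative abundances; otherwise an
abundance-weighted metric between a 1,000-read and a 40,000-read vector
mostly measures the depth difference.

## The simulator

One library is generated as:

1. **Community.** `n_taxa = 1500` relative abundances from a lognormal
   (default σ_ln = 4.0, μ_ln = 0; a geometric series is also available),
   sorted and normalized. σ and n were calibrated once so that observed
   richness lands near 30–60 OTUs at 500 reads and 200–350 at 38,000 reads —
   the ranges a shallow and a deep platform recover from real pine-soil
   fungal communities. The three replication-design sources use
   σ_ln = 3.8/4.0/4.2 so the soils differ systematically in diversity.
2. **Template sampling.** `template_molecules = 1,000,000` molecules drawn
   multinomially from the community. Real extracts contain orders of
   magnitude more amplifiable template than the sequencer samples reads, so
   the template pool must exceed the read depth for sequencing — not
   pipetting — to be the binding noise source; 10⁶ ≫ the deepest default
   depth (65,000). Shrinking this number below the read depth makes pooling
   genuinely matter (rare taxa become template-limited), which is a useful
   regime to explore but is not the default condition.
3. **PCR.** Per-taxon efficiency `clip(0.8 + taxon offset + reaction offset,
   0.01, 1)`. Taxon offsets (~N(0, 0.02)) are redrawn per platform —
   persistent primer bias, identical across every sample on that platform.
   The reaction offset is a single scalar per reaction (~N(0, 0.02)):
   reaction-wide condition shifts move all taxa together and are therefore
   nearly composition-neutral. The first `stochastic_cycles = 5` cycles
   branch exactly (each molecule duplicates with probability e, a binomial
   per taxon); the remaining 25 of 30 cycles multiply deterministically by
   `(1+e)^25`. Branching matters only while copy numbers are small; full
   30-cycle branching would overflow integer ranges without adding
   compositional noise.
4. **Pooling.** Equal-volume averaging of the replicate reaction profiles.
5. **Sequencing.** Multinomial read sampling at the platform depth (defaults
   1,200 reads for the shallow platform, 65,000 for the deep one, matching
   the library sizes such platforms deliver). Each read independently
   becomes a spurious-OTU read with probability `error_rate = 0.005`,
   relabelled `ERR_<parent>_<j>` with geometric j (p = 0.5), so repeated
   errors on an abundant parent can hit the same spurious OTU and recur
   across replicates — as real error OTUs do. An optional per-platform
   detectable fraction can mask taxa entirely (default 1.0: cross-platform
   OTU differences then emerge from depth and error alone, which already
   reproduces the observed near-zero count of shallow-platform-only OTUs).

The cross-platform design adds bioregion structure: each of 3 regions draws
its own metacommunity restricted to a random 60% of the global taxon pool
(`group_taxon_fraction`), sites and samples are Dirichlet perturbations with
concentration `group_concentration = 200` (site level uses 5× that), and
every sample is amplified and sequenced on both platforms.

**What the simulator does not model:** chimeras, per-base quality and
read-length effects, primer thermodynamics, clustering artifacts beyond the
single-parent error model, template degradation, and the occasional failed
library (real studies drop a few samples for bench reasons). Passing tests
therefore demonstrate that the *estimators and procedures* behave correctly
under a faithful sampling-theoretic model of library prep — not that every
quantitative default matches any particular wet-lab system.

## Numerical choices

* Seeds: one master seed fans out via `SeedSequence` keyed on stable string
  tags (`_seeds.derive_seed`), so every stage is independently reproducible
  and all derived seeds stay below 2³¹. Study pipelines are byte-deterministic.
* Fisher's α bracket `[1e-12, 1e12]`; IRLS damping halves the Newton step
  until the log-likelihood stops decreasing; logistic coefficients capped at
  |β| = 35 (the logit is numerically saturated far earlier).
* Distance matrices validate symmetry, zero diagonal and the [0, 1] range on
  construction; matrix construction uses row-vs-matrix vectorized arithmetic
  identical to the scalar metric functions, so the two routes agree exactly.
* Missing table cells are an error, never implicit zeros; duplicate
  identifiers are rejected at parse time.

## Test-suite design

Estimators are checked against independent oracles: pure-python naive
implementations and scipy.spatial for the metrics, a bisection for
Fisher's α, hypergeometric closed forms for rarefaction, a refined grid
search and statsmodels GLM for the logistic fit, a literal double-loop
partition and scikit-bio for perMANOVA/Mantel. Permutation tests are
calibration-checked (type-I error within the binomial 95% band of 0.05 over
400 null simulations). The study-level checks run the whole pipeline: 50
simulated replication experiments reproduce the null pooling term alongside
overwhelming sample and platform terms, and re-sequenced replicates
reproduce the Bray-Curtis-decays / Jaccard-plateaus depth contrast. Problem
sizes (30–50 simulated experiments, 10,000 rarefaction draws, 400 null
permutation simulations) were chosen to keep Monte-Carlo error well inside
the tested bands while the full suite stays fast.

Where a Monte-Carlo band covers many simultaneous comparisons (20 per-taxon
rarefaction means), the per-comparison threshold carries a Šidák adjustment
so the family has the same confidence a single 3-SE comparison has.

## Known limitations

* The logistic detection model treats replicates as independent Bernoulli
  trials per OTU; overdispersion between replicate libraries (shared PCR
  history) is not modelled (no quasi-binomial option).
* perMANOVA is one-way only; confounded factors must be tested separately.
* β-sim's pseudo-F can be negative (non-Euclidean dissimilarities admit
  `SS_within > SS_total`); the value is reported as computed.
* The BIOM import handles only the dense JSON dialect.
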