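# Methods

`decaywood` re-implements, as a tested library, the statistical analysis
chain used to study bacterial and fungal community succession in
naturally decaying pine wood: alpha-diversity regressions against wood
density, decay-stage partitioning with a multivariate regression tree
(MRT) on Bray–Curtis dissimilarity, Metastats-style permutation
differential abundance, genus co-occurrence networks, and — the core —
classification of community assembly as neutral or niche-based from
rank-abundance-distribution (RAD) model likelihoods compared by AIC and
Akaike weights. A synthetic-data generator reproduces the *shape* of
such a study (19 wood samples × 3 replicates on a density gradient) with
known ground truth, so every stage is testable without sequence data.

## Data model and conventions

Count tables are samples × taxa non-negative integer matrices (TSV,
first header cell `#SampleID` or `#TaxonID`). Taxonomy lineages use
QIIME-style `k__...;g__...` strings; taxa unclassified at the
aggregation rank are pooled into one `<kingdom>;unclassified@<rank>`
taxon so per-sample totals are conserved. Metadata carries one row per
sequenced replicate: wood density (g/cm³), pH, relative moisture (% of
dry mass), C/N ratio, ergosterol (mg/kg), and `replicate_of`, the
parent wood sample.

Replicate averaging operates on relative abundances (count / replicate
total), not raw counts. At equal rarefaction depth the two coincide;
the relative form stays correct if depths ever differ.

## Rarefaction and diversity

Rarefaction draws a uniform multiset subsample *without replacement* to
a fixed depth (defaults: 1,080 reads for bacterial 16S tables, 2,000
for fungal ITS), per replicate, before any averaging. Samples below
depth are excluded per kingdom and logged. Each sample's subsample uses
an independent substream derived from the global seed and the sample
id, so results do not depend on which other samples are present.

Chao1 is the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)); the +1 in
the denominator keeps samples without doubletons well-defined, at the
cost of differing slightly (and predictably) from the classic
F₁²/(2F₂) form. Shannon entropy uses natural log. Diversity-vs-density
regressions are ordinary least squares over all replicates (pooling,
not averaging; an upstream caller can average first if preferred), with
the two-sided slope p-value from the t distribution with n−2 df. Both
r and r² are reported, since a signed "R²" in a report invariably means
Pearson r.

## Decay-stage MRT

The tree greedily partitions samples on numeric covariates to minimize
the distance-based within-node sum of squares SS(node) =
Σ_{i<j} d²(i,j)/n_node with d = Bray–Curtis (a Euclidean option
exists). Candidate thresholds are midpoints between consecutive sorted
unique covariate values; at each step the (leaf, variable, threshold)
triple with the largest impurity decrease is split, ties broken by
variable order then lower threshold — fully deterministic. There is no
cross-validated pruning: tree size is a parameter, default
`max_leaves=3` to mirror the three decay stages; leaves are named
early/middle/late by descending mean wood density. On the default
synthetic study the recovered density split points fall within ±0.03
g/cm³ of the planted 0.40/0.30 band edges in the large majority of
seeds (the acceptance suite requires ≥80% of 50).

## Differential abundance

Two-group comparisons use an unequal-variance (Welch) t statistic on
per-sample relative abundances, with a permutation null built from
relabelings of samples across the two groups and the add-one two-sided
p-value (1 + #{|t*| ≥ |t|})/(B+1), B = 1,000 by default. "Bootstrap"
relabeling with replacement is available behind a flag; exhaustive
enumeration is used when requested (and in tests, where 3v3 groups have
only 20 distinct relabelings). q-values come from the
Benjamini–Hochberg step-up applied across taxa. Taxa with fewer than
two nonzero samples in a group are flagged `low_information` rather
than excluded or routed to a different test (the original Metastats
switches to Fisher's exact test for sparse taxa; we keep one test and
an explicit flag instead).

## Co-occurrence networks

Genus-aggregated tables are filtered to genera with ≥5 total reads
across samples ("five representatives" read as reads; a prevalence mode
— present in ≥5 samples — is a flag). Pairwise Pearson correlations on
replicate-averaged relative abundances get two-sided p-values from
t = r√((n−2)/(1−r²)); edges require |r| > 0.80 strictly and p < 0.05,
optionally q < q_max after BH adjustment across pairs (off by default,
matching the main-text thresholds; the figure-caption variant
q < 0.001 is reachable via configuration). Nodes are genera with at
least one edge. Exports are Cytoscape-readable: edge and node attribute
TSVs plus GraphML. With ~6 parents per stage, |r| > 0.81 is already the
p < 0.05 point, so per-stage networks at this sample size are noisy;
this is a property of the method at the study's n, not of the
implementation, and the null-calibration acceptance test quantifies it.

## Rank-abundance models and assembly classification

Five niche-oriented RAD models give expected abundances λ_r at ranks
r = 1..S:

- broken stick: λ_r = (J/S) Σ_{k=r}^{S} 1/k (0 parameters)
- geometric preemption: λ_r = J α(1−α)^{r−1}/(1−(1−α)^S) (α)
- log-normal: λ_r = exp(μ + σ Φ⁻¹((S−r+0.5)/S)) (μ, σ)
- Zipf: λ_r = J p₁ r^γ (p₁, γ)
- Zipf–Mandelbrot: λ_r = J c (r+β)^γ (c, γ, β)

Parameters maximize the Poisson rank likelihood
Σ_r [a_r ln λ_r − λ_r − ln a_r!] by Nelder–Mead from five deterministic
starts on transformed (unconstrained) coordinates; the Zipf solution
seeds one Zipf–Mandelbrot start, which guarantees the nesting
monotonicity logL(mandelbrot) ≥ logL(zipf).

The neutral model is Hubbell's zero-sum multinomial (ZSM) with
parameters θ (fundamental biodiversity number) and m (immigration
probability), I = m(J−1)/(1−m). Its exact likelihood is the Etienne
sampling formula for the probability of the observed abundance
configuration, evaluated entirely in log space: unsigned Stirling
numbers of the first kind by the log-space recurrence, per-species
coefficient polynomials convolved with log-sum-exp, and the
(θ,m)-independent K(D,A) cached per sample so the likelihood surface
costs microseconds per point after a one-off O(J²) setup. At m = 1 the
formula reduces to the Ewens sampling formula, evaluated directly. The
implementation is validated against an independently coded Ewens oracle
on every configuration of J ≤ 10 and by total-probability sums over all
configurations of J = 6 (1 ± 1e-8).

### Scoring constructions

AIC = −2 logL + 2 npar with npar = 0/1/2/2/3/2, and Akaike weights
w_i = exp(−ΔAIC_i/2)/Σ exp(−ΔAIC/2). Which likelihood enters that
formula is a genuine design choice, because the exact ZSM likelihood
and the conventional niche-model likelihoods live on different outcome
spaces. Three constructions are implemented; the default is the one
that is *calibrated* — simulation from each model family recovers that
family.

**`scoring="mixed"`** reproduces the historical radfit + TeTame
construction: niche models keep the Poisson rank likelihood, the ZSM
is scored by the Etienne configuration likelihood. The configuration
probability aggregates over species-to-rank assignments and so carries
a combinatorial term of order ln(S!/Π_j Φ_j!) the rank likelihood
lacks — tens of log units at S ≈ 50, dwarfing genuine fit differences.
Under this construction the ZSM wins against data *generated from*
log-normal, Zipf or broken-stick expectations essentially always; only
strongly geometric (preemption) data overcome the handicap. The mode
exists for fidelity to the original toolchain, not for inference.

**`scoring="rank"`** scores all six models on the Poisson rank
likelihood. For the ZSM, expected rank abundances come from its
expected species-abundance distribution under dispersal-limited
sampling,

    E[Φ_n] = ∫₀¹ θ(1−x)^{θ−1}/x · C(J,n) B(n+Ix, J−n+I(1−x))/B(Ix, I(1−x)) dx

(binomial kernel at m = 1), integrated by fixed log-spaced quadrature
on both ends of (0,1) and converted to rank expectations by the same
midpoint-quantile device the log-normal model uses; the survivor
function continues linearly below one individual so observed richness
in excess of the expected richness is penalized smoothly rather than
catastrophically. (θ, m) are optimized against that rank likelihood,
seeded by the Etienne-likelihood estimate. Diagnostics: Σ n·E[Φ_n]
recovers J and, at m = 1, Σ E[Φ_n] matches the closed-form Ewens
expected richness to ~1%. This mode is symmetric, but biased *against*
neutrality: a realized sorted abundance curve is smooth, adjacent ranks
are strongly dependent, and 3-parameter niche curves fit that smooth
realization better than the constrained ZSM expectation even on truly
neutral data (measured neutral-or-both rate ≈ 60% at S≈90, J=1080).
Per-sample rank-AIC comparisons overstate niche support — a caveat
that applies to any per-sample rank-AIC comparison of this model
family, whatever software computes it.

**`scoring="configuration"` (default)** scores every model on the
probability of the observed abundance *multiset*. The ZSM uses the
exact Etienne likelihood. Each niche model uses an
exchangeable-species mixture likelihood: with expected niche sizes
λ_1..λ_S, a species' abundance is modeled iid from the finite mixture
(1/S)Σ_r Poisson(λ_r) — a Poissonization of the exact
one-species-per-niche assignment sum, which is a matrix permanent and
intractable — giving multiset probability
(S!/Π_j Φ_j!)·Π_i mix(a_i), conditioned on the total read count J by a
normal approximation to the mixture-sum distribution so that both
families condition on J. Niche parameters are the rank-likelihood
estimates (the field-standard fit), evaluated under the configuration
likelihood; npar is unchanged. Under this construction the
model-recovery experiment (5 generator families, S ≈ 50, J = 1080,
100 seeds each) recovers every family in ≥80% of seeds, which is the
calibration property the acceptance suite enforces.

The verdict rule: "both" if the best neutral and best niche AIC are
within ΔAIC ≤ 2 (configurable margin), otherwise the family with the
smaller AIC.

`fit_zsm` (the Etienne-likelihood fit) reports boundary solutions —
e.g. the θ → ∞ divergence on an all-singleton sample — with
`converged=False` and a capped estimate.

## Synthetic data

The neutral generator is the sequential urn: individual j is an
immigrant with probability I/(I+j−1) (the first individual always is);
immigrant ancestry follows a Ewens(θ) urn over immigration events;
non-immigrants copy a uniformly chosen earlier individual. At m = 1 it
is exactly Ewens(θ), checked against the closed-form expected richness.
The niche generator draws counts independently Poisson(λ_r) around the
model's expected abundances rescaled to sum to J — the same error model
the fitter assumes, which keeps generator and fitter conjugate and
makes the recovery experiments a clean test of the selection machinery
rather than of model misspecification robustness.

`simulate_decay_study` (defaults: 19 parents × 3 replicates, density
gradient 0.50 → 0.15 g/cm³, bands >0.40 / 0.30–0.40 / <0.30) plants:

- per-stage assembly mechanism for bacteria — early parents neutral
  (θ=30, m=0.2), middle and late Zipf (p₁=0.2, γ=−0.9) with richness
  rising through decay;
- a bacterial richness gradient: the early stage's observed richness
  (~80 species at depth 1,080) follows from (θ, m, J); the niche
  stages draw their species count from a density gradient placed above
  it (targets 95 → 150 species as density falls, Gaussian jitter
  sd 6), so observed richness increases monotonically with decay and
  the diversity-vs-density regressions carry a strong negative slope;
- community identity through a stage-offset rank-to-taxon mapping
  (rank r in stage s names taxon r + offset_s, offsets 0/60/120):
  replicates and same-stage parents share taxa, stages are shifted
  against each other — between-stage contrast for the MRT without
  distorting any sample's RAD;
- fungal replicates dominated by one parent-specific phylotype
  (expected share 0.6, floor enforced at >50%) over a shared geometric
  tail — each wood sample keeps its own fungal signature. The
  ground-truth manifest makes assembly-mechanism claims only for the
  bacterial tables: a one-dominant-plus-tail fungal profile is also
  what a dispersal-limited neutral community with small m looks like,
  and the model comparison accordingly tends to call synthetic fungal
  samples neutral-compatible — a property of that community shape, not
  a planted mechanism;
- stage-indicator genera confined to one stage (~0.6% of reads) and
  three correlated genus pairs (ρ = +0.95, −0.90 bacterial–bacterial,
  +0.90 bacterial–fungal; ~1% of reads each) driven by per-parent
  latent Gaussian fields with abundance responding *linearly* (clipped
  at 5% of baseline) — a log-linear response would cap attainable
  negative Pearson correlations near −0.56 and the planted negative
  pair would be unrecoverable by design; the planted shares are kept
  small so these additions do not distort the per-sample rank-abundance
  distributions the assembly classifier reads;
- metadata with per-stage means for pH (4.90/3.96/4.16), moisture
  (31.6/33.3/139.0%), C/N (1009/743/267), ergosterol (14.2/42.0/46.1
  mg/kg) and small within-stage spreads.

Per-replicate read depth is 1.25× the rarefaction target so rarefaction
always succeeds by default. One global seed expands into per-sample
substreams via `SeedSequence(seed, spawn_key=(counter,))` with
documented counters (metadata 0, bacterial replicates 1000+i, fungal
2000+i, correlation fields 3000), so any single sample can be
regenerated in isolation.

What the generator does *not* emulate: sequencing error, chimeras, OTU
clustering noise, compositional coupling between planted taxa and the
rest of the community (planted counts are added on top), overdispersion
beyond Poisson, and any real taxonomic structure. Passing tests
therefore demonstrate that the statistical machinery is correct and
calibrated under its own assumptions, not that those assumptions hold
for 454 amplicon data.

## Pipeline

Stage order: per-replicate rarefaction → diversity + regressions → MRT
staging on replicate-averaged bacterial communities with parent-mean
covariates → per-stage-pair differential abundance (replicate-level
samples grouped by their parent's stage) → per-stage and global
co-occurrence networks (parent-averaged) → per-sample RAD comparison
for both kingdoms → summary JSON. Samples failing rarefaction are
excluded only from the kingdom that failed. Outputs are a pure function
of (inputs, config, seed); reruns are byte-identical (the manifest
records the config verbatim, including the output path, and is the one
file excluded from byte comparison across differently-named run
directories).

Problem sizes used by the shipped experiments: model recovery at
S = 50, J = 1080 with 100 seeds per generator; parameter recovery at
J = 1000 with 20 replicates; threshold recovery over 50 study seeds;
type-I calibration over 200 tables of 30 taxa with 999 permutations;
network null calibration over 200 seeds of 50 genera × 19 samples.
These sizes match the study's own scale (a 454 amplicon survey of 19
wood samples), which is what makes the calibration claims relevant.

## Known limitations

- The Poisson rank likelihood treats ranked abundances as independent;
  true RAD sampling induces ordering constraints. All models share the
  approximation under the default scoring, which is the point.
- `fit_zsm`'s likelihood surface is flat in m when m̂ → 1 or S is
  small; estimates near boundaries carry little information (flagged
  via `converged`).
- Pearson co-occurrence on relative abundances is compositionally
  biased; SparCC-style corrections are out of scope deliberately.
- MRT assumes numeric covariates and binary splits; no surrogate
  splits, no categorical variables, no cross-validated size selection.
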