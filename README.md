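# decaywood

Statistical analysis of microbial community succession in decaying
wood, for microbial ecologists working with amplicon count tables
(16S/ITS) from environmental gradients.

Dead wood is colonized by fungi and bacteria whose communities shift as
decay progresses; wood density is the standard field proxy for decay
stage. Given OTU/taxon count tables, taxonomy lineages and per-sample
wood covariates (density, pH, moisture, C/N, ergosterol), `decaywood`
runs the full analysis chain such a study needs:

- **Rarefaction and alpha diversity** — subsampling without replacement
  to fixed depth; bias-corrected Chao1, S_obs + F₁(F₁−1)/(2(F₂+1));
  Shannon entropy H = −Σ pᵢ ln pᵢ; OLS regressions of diversity on
  wood covariates.
- **Decay-stage partitioning** — a multivariate regression tree on the
  Bray–Curtis dissimilarity matrix, minimizing the distance-based
  within-node sum of squares Σ_{i<j} d²(i,j)/n; leaves named
  early/middle/late by descending mean wood density.
- **Differential abundance** — Metastats-style two-group comparison:
  Welch t on relative abundances, permutation null (B = 1,000),
  p = (1+#{|t*|≥|t|})/(B+1), Benjamini–Hochberg q-values.
- **Co-occurrence networks** — genus-level all-pairs Pearson r with
  t-based p-values, optional FDR, edges at |r| > 0.80 and p < 0.05,
  degree statistics, Cytoscape-readable exports (TSV + GraphML).
- **Neutral vs. niche community assembly** — each sample's rank
  abundance distribution is fit to broken stick, geometric preemption,
  log-normal, Zipf and Zipf–Mandelbrot models and to Hubbell's neutral
  zero-sum multinomial (ZSM), whose exact likelihood is the Etienne
  sampling formula (log-space Stirling-number convolution; Ewens
  sampling formula at m = 1). Models are compared by
  AIC = −2 logL + 2 npar and Akaike weights
  wᵢ = exp(−ΔAICᵢ/2)/Σ exp(−ΔAIC/2); a per-sample verdict calls the
  assembly neutral, niche, or both (ΔAIC ≤ 2).
- **Synthetic decay study** — a generator producing a complete mock
  study (19 wood samples × 3 replicates on a 0.50 → 0.15 g/cm³ density
  gradient) with known ground truth: planted stage bands, per-stage
  assembly mechanism, stage-indicator taxa and correlated genus pairs.

By default all six assembly models are scored on one common outcome
space — the probability of the observed abundance multiset (exact
Etienne likelihood for the ZSM, an exchangeable-species mixture
likelihood for the niche models) — which makes the Akaike weights
comparable across models and is calibrated: simulating from any of the
six families recovers that family in ≥80% of samples at this study's
scale. Two alternative constructions are kept behind a flag: a common
Poisson rank likelihood (`scoring="rank"`) and the historical mixed
construction of the radfit/TeTame toolchain (`scoring="mixed"`). See
`docs/methods.md` for the full story.

## Worked example

Generate a synthetic study and run the whole pipeline:

```sh
decaywood simulate --seed 11 --out study/
decaywood -v run --config config.yaml   # or use the library directly:
```

```python
from decaywood import simulate_decay_study, RunConfig
from decaywood.pipeline import run_objects

bacteria, fungi, taxonomy, meta, truth = simulate_decay_study(seed=11)
cfg = RunConfig(bacterial_table="", fungal_table="", taxonomy="",
                metadata="", output_dir="run11", seed=11)
run_objects(bacteria, fungi, taxonomy, meta, cfg)
```

`run11/summary.json` then contains (seed 11):

```
mrt.density_thresholds   [0.3931, 0.2958]
mrt.stage_sizes          {early: 6, middle: 5, late: 8}
regressions.bacteria.chao1     slope -140.97  r2 0.726  (p = 4.1e-17)
regressions.bacteria.shannon   slope  -0.90   r2 0.453  (p = 9.8e-09)
sad.bacteria.stage_verdicts
    early:  {neutral: 14, both: 3, niche: 1}
    middle: {niche: 15}
    late:   {niche: 23, both: 1}
```

Reading this: the tree recovered the planted density bands (0.40 and
0.30 g/cm³) to within the spacing of the gradient — samples denser than
~0.39 g/cm³ form the early stage; bacterial richness and diversity
fall with increasing density (negative slopes: richness *rises* as wood
decays, the classic successional signal); and the per-sample model
comparison recovers the planted assembly mechanisms — mostly
neutral/both verdicts in the early stage, uniformly niche verdicts in
middle and late stages, the same qualitative pattern reported for
natural pine-wood communities.

Every stage also writes its own artifacts: rarefied tables, per-sample
diversity, the rendered tree, per-stage-pair differential-abundance
tables sorted by q, edge/node/GraphML network files per stage, and a
samples × models Akaike-weight matrix (`sad_weights_bacteria.tsv`).

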