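# Methods

## The simulated experiment

The unit of observation is one qRT-PCR (or RNA-seq) expression measurement
of the target gene in one CRISPR-edited single-cell clone. A design is
described by `ExperimentDesign`:

| parameter | meaning | default |
|---|---|---|
| `n_guides` (G) | targeted SNPs in the credible interval | 10 |
| `causal_guides` | guides whose edit truly shifts expression | {0} |
| `clones_per_guide` | clones representing each guide | 1 |
| `replicates` (r) | technical replicates per clone | 8 (study grid: 2, 4, 8, 16) |
| `effect_sdu` (δ) | causal shift, standard deviation units | grid 0–2, step 0.1 |
| `sigma_clone` (σ_c) | clone random-intercept sd, sdu | 0 or 0.2 |
| `sigma_batch` (σ_b) | batch random-intercept sd, sdu | 0 or 0.2 |
| `sigma_resid` | residual sd | fixed at 1 |

A measurement is `y = δ·1[guide causal] + clone + batch + ε` with clone,
batch and residual effects independent Gaussians. Fixing the residual sd
at 1 makes δ literally an effect in sdu; a 1-sdu substitution effect is
the size of a typical eQTL explaining ~10% of expression variance. All
random effects are Gaussian — field magnitudes motivate the sds, not the
distribution shape, which is a modelling choice. With two batches, guides
0–4 form batch 0 and guides 5–9 batch 1 (contiguous blocks; assignment is
deterministic, not randomised). Generalising to more batches keeps the
block rule; designs with many batches exist solely so variance-component
recovery can be validated.

The five scenarios:

| panel | label | structure |
|---|---|---|
| a | `baseline` | σ_c = σ_b = 0, one causal guide |
| b | `clone_effects` | σ_c = 0.2 |
| c | `clone_plus_batch` | σ_c = σ_b = 0.2, two batches of five guides |
| d | `duplicate_causal_clones` | causal guide represented by 2 clones, σ_c = 0.2 |
| e | `three_causal` | guides 0–2 each carry δ, σ_c = 0.2 |

"0.2 sdu" clone/batch effects are read as standard deviations (that is
what "sdu" means), not variances. In scenarios a–c and e each guide is
represented by one clone; only scenario d duplicates the causal guide's
clone. An alternative reading — duplicated clones for every guide — is
expressible through `clones_per_guide` but is not a canonical scenario.

## The contrast test

The scientific question is whether the causal guide differs from the other
guides in the interval, so the tested quantity is the two-sided contrast
`mean(causal guides) − mean(non-causal guides)` in the mixed model with
guide fixed and clone (and batch) random. Under the balanced designs the
generators produce, the likelihood-based test reduces exactly to
clone-aggregated *t*-tests, and that is what the vectorised engine
computes:

- **`ols`** (no declared random effects): pooled within-guide residual,
  df = Gr − G. The contrast SE at r = 8, G = 10 is
  `sqrt(s²(1/8 + 1/72))`.
- **`clone_means`** (clone effects, one clone per guide): the clone means
  are sufficient; the error term is their scatter within the causal and
  reference groups, df = G − 2 (ten clone means, 8 df in the canonical
  design). Clone variance and residual noise enter the error term
  together, which is what makes clone variability so costly.
- **`nested`** (within-guide clone replication): the error term is the
  between-clone-within-guide mean square, df = n_clones − n_guides. With
  one duplicated causal guide this leaves a *single* error degree of
  freedom: the only clean yardstick for "does this guide differ" when
  clones of the same guide disagree is that disagreement itself. This is
  deliberately conservative and is why reliability is never reached in
  scenario d. A Satterthwaite blend that borrows the large residual df
  would report high power at large effects, but it answers a different
  question (is the *average* of these particular clones shifted) and
  ignores the clone-level replication structure the scenario exists to
  model.
- **`mixed`**: REML via statsmodels `MixedLM` with a Satterthwaite-type
  denominator df assembled from the clone and residual strata. When the
  clone intercepts are confounded with the guide fixed effects (no
  within-guide clone replication) or the fit is singular, the result falls
  back to the aggregated test and is flagged. Because the aggregated tests
  are exact under balance, `mixed` exists for irregular data and as a
  cross-check, not as the Monte Carlo workhorse.

`method="auto"` resolves from the declared design: `nested` if any guide
has ≥ 2 clones, else `clone_means` if random effects are declared, else
`ols`. The choice keys on the declared design (the analyst's model), never
on the realised data.

In the three-causal scenario the default contrast groups **all three**
causal guides against the seven non-causal ones (df = 8). Testing only
the first causal guide and discarding the other two (available as
`contrast="first_causal"`, df = 6) wastes information and, by exact
noncentral-*t* computation, pushes the 80% threshold from 1.0 to ~1.5 sdu
— inconsistent with the scenario's purpose of modelling a summed eQTL
effect. In scenario c the clone-means test simply ignores batch labels:
with two batches the batch variance is not estimable, its contribution
inflates the between-guide error term, and the realised test size stays
within Monte Carlo tolerance of the nominal level (verified empirically at
α = 0.05, 0.01, 0.001).

## Power estimation

Power at one grid point is the rejection fraction over `n_sims = 5000`
vectorised simulations (a `(n_sims, clones, replicates)` Gaussian array and
closed-form *t* statistics; a full 21-point curve takes well under a
second). Monte Carlo error is the binomial `sqrt(p(1−p)/n)`. Curves reuse
one random stream across grid points (common random numbers — marginals
unchanged, curves smoother; recorded in the output), are isotonically
smoothed before any threshold search (power is monotone in effect; raw MC
estimates jitter), and "reliably detected" means smoothed power ≥ 0.80,
with ties at the boundary counting as reached. All reported numbers use
α = 0.05 two-sided; 0.01 and 0.001 are options.

The baseline oracle is the noncentral *t*:
`ncp = δ/sqrt(1/r + 1/((G−1)r))`, `df = Gr − G`, two-sided rejection at
`t_{1−α/2}`. At G = 2 this reduces to the classical two-sample *t* power,
which is cross-checked against `statsmodels.stats.power.TTestIndPower`.

Under these conventions the exact 80% thresholds are: baseline 1.1 sdu
(8 replicates), 0.8 (16), 1.6 (4); clone effects 1.4 (8) and 1.9 (4);
duplicate causal clones never (maximum power ≈ 39% on the grid); three
causal variants 1.0 per-variant sdu (8). The original screening study was
powered with a closed commercial mixed-model utility whose denominator-df
and sidedness conventions are not published; its printed baseline
thresholds (1.0/0.7/1.5) sit exactly one 0.1 grid step below the two-sided
values here (and match a one-sided convention exactly), while its
clone-effect thresholds (1.7/2.0) sit above. No single convention we
could construct reproduces both families simultaneously, so this package
fixes the transparent two-sided convention and reports the residual
discrepancy rather than fitting to it.

## Synthetic data beyond the mixed model

**Chips.** `ChipSpec` emulates a 48×48 nanoscale qRT-PCR chip: 2304
assays, 30 amplification cycles, per-probe Gaussian Ct with a bimodal
abundance profile (~25% of probes near the detection floor, giving the
characteristic bimodal 30 − Ct distribution), a fresh/frozen split with a
+2-cycle additive offset on the frozen half (batch effects of this order
dominated the real chips), and 2% dropout encoded as Ct ≥ 30. What it does
*not* emulate: amplification-efficiency differences between probes,
correlated expression across genes, melt-curve artefacts. Passing tests
therefore demonstrate the correctness of the transform/QC/adjustment
logic, not robustness to chemistry-level artefacts.

**Genomes and variants.** Toy genomes are iid uniform A/C/G/T with one
annotated SNP and optionally planted NGG PAMs; variant-call fixtures are
uniformly placed SNVs with uniform depths. Neither has realistic base
composition, linkage structure, repeats, or error profiles — they exist to
exercise coordinate conventions and filter boundaries exactly.

## Fluidigm processing conventions

Expression is `max(0, 30 − Ct)`; missing reactions and reactions at or
past the cycle ceiling are 0, and "unexpressed" means exactly 0 on this
scale. QC removes samples with **more than** 40 unexpressed probes first,
then probes expressed in **fewer than** 5 samples (boundaries survive); the
order is fixed and a regression test documents the boundary cases where
swapping it matters. The sample filter counts probes before any probe has
been removed. Batch adjustment is a per-probe, per-batch location-scale
transform followed by per-probe standardisation to mean 0, sd 1 (ddof = 1)
— an exactly specified stand-in for empirical-Bayes batch correction,
adequate because the use case is removing a single two-batch offset before
standardisation anyway. Technical replicates, when present, are averaged
before QC. Clone-vs-control comparisons are plain two-sided two-sample
*t*-tests per probe; groups that are exactly constant and tied return
p = 1 with a warning.

## PVCA

Probes are centred (scaling optional), the sample-covariance PCs computed
by SVD, and each of the first `n_pcs = 5` PC score vectors decomposed into
per-factor variance components by REML (`MixedLM`, each factor a random
effect, main effects only, no interactions) with a balanced-ANOVA
method-of-moments fallback; negative components truncate at zero. Factor
shares are averaged over PCs with eigenvalue weights and renormalised.
Two weightings are available: `"selected"` (default) weights within the
chosen PCs and therefore describes the captured subspace — diffuse
residual variance outside the leading PCs is under-represented;
`"total"` weights by share of total variance and books the uncaptured
remainder as residual, which is the configuration that recovers absolute
planted shares within ±0.05 on synthetic fixtures. Factors with a single
level get proportion 0; factors inducing identical sample partitions are
aliased and reported merged (`"a/b"`) rather than having their shared
variance split arbitrarily.

## Guide design conventions

Candidates are every `protospacer_len`-mer followed by NGG on either
strand. The protospacer length defaults to **19** nt to match the original
screening design; 20 is the more common SpCas9 choice and is a parameter.
Coordinates are 0-based half-open internally (1-based only at VCF/report
boundaries). The blunt cut falls between the 3rd and 4th nucleotide 5′ of
the PAM; `cut_pos` is the base immediately 5′ of the scission *on the
candidate's strand*, a convention that is strand-symmetric (window and
reverse-complement give mirrored candidate sets) and stated in the TSV
header. SNP distance is measured from `cut_pos`, not from the nearest
protospacer edge. GC boundaries are inclusive (10% and 80% survive);
candidates containing ambiguous bases are skipped with a logged reason.
The off-target scan is an exhaustive Hamming-distance count (≤ 2
mismatches, NGG required, no bulges, no scoring model) — a transparent
stand-in, not a prediction tool.

## Variant filter conventions

A cluster is a run of ≥ 3 consecutive SNVs whose first-to-last positions
differ by ≤ 35 (the window semantics of standard hard-filtering practice;
the alternative pairwise-gap reading was considered and rejected because
it removes arbitrarily long sparse runs). Indels bypass the cluster filter
but not the depth filter. Depth ≥ 50 survives. Replicate consistency is a
*site-level* intersection on (chrom, pos, ref, alt) — matching genotype
calls are not required — keeping the minimum depth. Exons are 0-based
half-open intervals, merged before lookup. Divergence is the symmetric
difference between clone and consensus call sets over the sites assessed,
reported as a percentage to two decimals. Filter order follows the
cascade's narrative order; the final set is order-insensitive and every
stage is monotone (output ⊆ input), both property-tested.

## Numerical and testing choices

- Every generator and every Monte Carlo routine takes an explicit seed
  (NumPy `default_rng` / `SeedSequence`); identical seeds give identical
  results to the last bit.
- Stochastic test assertions use 3×(Monte Carlo SE) bands; calibration
  batteries run 10⁴ simulations per condition, threshold curves 5×10³ per
  grid point — sizes at which a full suite runs in well under a minute
  while keeping the bands tight enough to be meaningful.
- Degenerate inputs fail loudly: invalid designs, α outside (0, 1),
  negative Ct, single-sample batches, zero divergence denominators and
  malformed variant records all raise with the offending field named;
  empty-after-QC matrices and dropped housekeeping probes warn instead.
- Isotonic regression uses scikit-learn with inverse-variance sample
  weights; threshold comparisons tolerate 10⁻⁹ to keep exact boundary
  ties deterministic across platforms.

## Known limitations

- The power engine assumes balanced designs (equal replicates per clone);
  unbalanced data route through the slower `mixed` path.
- Batch variance with two batches is structurally inestimable; the
  clone-means test absorbs it into the error term rather than modelling it.
- PVCA percentages from real chips depend on preprocessing choices
  upstream of this package; the module is validated on synthetic recovery
  only.
- The off-target scan counts sites; it does not rank or score them, and
  ignores bulges and alternative PAMs.
- The location-scale batch adjustment has no shrinkage, so with very few
  samples per batch it can overfit probe-level batch means.
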