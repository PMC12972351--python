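# Methods

## The analysis in brief

The pipeline operates on a sites × samples matrix of methylation beta
values (fractions in [0, 1], missing allowed) with per-sample metadata
(tissue, group label, age, sex).  Four stages:

1. **Unique-site identification.**  For each candidate tissue and each
   site with enough valid values, the tissue's central beta value is
   compared with the empirical q and 1−q quantiles (default q = 0.05)
   of the pooled non-missing values of all *other* tissues combined.  A
   site is unique-low when `center ≤ q_low − margin` and unique-high
   when `center ≥ q_high + margin`, with margin 0.1 by default and both
   inequalities inclusive.  The center is the mean by default; the
   median is available because robustly skewed sites can differ under
   the two statistics and both conventions appear in practice.
   Quantiles interpolate linearly between order statistics (numpy's
   default); the estimator is switchable since published analyses
   rarely state one.  A site may qualify in more than one tissue; both
   records are kept and reported.

2. **Direction of change.**  Each unique site carries an expectation:
   at a low site the rest of the body is *more* methylated, so a gain
   in disease/aging moves toward the common level.  Group mode compares
   case and control means of the focal tissue's samples (Δ = case −
   control); correlation mode uses Pearson r of methylation against
   age or a 0/1 status indicator, with an optional robustness filter
   |r| ≥ threshold (0.3 or 0.4 are typical working points).  The call
   is *regression* when the change is toward the pan-tissue level,
   *divergence* when away; Δ = 0 (or r = 0) is a tie, and missing
   means/undefined correlations are *undefined*.  Ties and undefined
   calls are counted and disclosed but never enter the statistic: a tie
   supports neither direction, and the null is about direction only.

3. **The exact binomial statistic.**  Under the null that each
   informative site's direction is a fair coin, the majority count k of
   n sites is scored with the one-sided upper tail P(X ≥ k),
   X ~ Bin(n, ½), summed term by term in log space (log-sum-exp over
   `lgamma`-based log binomial coefficients).  This keeps results exact
   to ~1e−12 relative error in log10 down to magnitudes like 10⁻²⁰⁰⁰,
   where any linear-space computation underflows; p-values are
   therefore always reported as log10.  One-sided is the default
   because the published intestine count (237/242, bound 10⁻⁶³) holds
   one-sided (≈ 9.6 × 10⁻⁶⁴) but not doubled (≈ 1.9 × 10⁻⁶³); the
   two-sided variant is exposed (`two_sided=True`) for sensitivity
   analyses.  An arbitrary null p₀ is supported, but the default 0.5 is
   the reproducible convention: low- and high-direction sites are
   summarized separately, so any global methylation trend would lower
   one group's p-value while raising the other's.

4. **Projection and classification.**  PCA (scikit-learn, full SVD)
   with samples as observations and the chosen sites as dimensions;
   per-site mean-centering, no variance scaling by default (beta values
   share a scale; scaling is an option).  Component signs are fixed by
   making each component's largest-magnitude loading positive, so fits
   are deterministic.  Sites with any missing value among the training
   samples are dropped and reported rather than imputed — imputation is
   a deliberate non-goal.  Classification is in 2D; three distance
   models: ratio of mean distances to the two groups, nearest group
   centroid (unweighted mean of member coordinates), and "sick iff
   within twice the sick group's spread of its centroid".  Accuracy is
   leave-one-out: the basis is refit without the held-out sample, which
   is then projected with the retained loadings and classified against
   the remaining labeled coordinates.  Ties classify as healthy,
   conservative toward no-disease.

### The radius2sd spread

The third model's radius is 2·SD where SD measures the sick group's
spread about its centroid.  Two readings exist: (a) the SD of the
scalar member-to-centroid distances, and (b) the RMS deviation of
member positions from the centroid.  Reading (a) is exactly zero for
any point-symmetric cloud (e.g. members equidistant from their center),
which would make the model degenerate on perfectly well-behaved data;
(b) is zero only when all members coincide and equals the usual scalar
SD of a point set about its mean.  The default is (b); (a) remains
available via `classify_sample(..., spread="distance_sd")`.

## The synthetic generator

`generate_multitissue` emulates the statistical structure the analyses
assume, not array chemistry:

* **Background sites** share one generating mean μ across tissues,
  drawn from a bimodal mixture (45% Beta(2, 8), 45% Beta(8, 2), 10%
  uniform) that mimics the genome-wide beta distribution's two modes.
* **Planted unique sites** (n per tissue, split evenly low/high) place
  the focal tissue's mean in [0.05, 0.15] and every other tissue's mean
  in [0.70, 0.90] (mirrored for high).  The displacement therefore
  always exceeds `planted_margin`, which is validated as a minimum.
  The displacement is deliberately much larger than the detection
  margin: the criterion subtracts the margin from an empirical quantile
  of noisy pooled values, so at κ = 50 (observation SD ≈ 0.06) a site
  needs roughly `margin + 1.6·SD ≈ 0.2` of displacement to be
  detectable at all — the planted pattern mirrors the published
  single-tissue examples (≈ 0.1 in the tissue, ≈ 0.8 elsewhere) rather
  than sitting at the detection boundary.
* **Observation noise** is Beta(μκ, (1−μ)κ) per entry; κ defaults to
  50, giving SD ≈ 0.07 near μ = 0.5 and less near the boundaries,
  comparable to array replicate noise.  Generating means are clipped to
  (0.01, 0.99) to keep both shape parameters positive.
* **Erosion** moves the case group's generating mean at each planted
  site of a tissue to `μ_t + λ(μ_o − μ_t)`: λ = 1 is full regression to
  the pan-tissue level, λ < 0 amplifies the signature (clipped).
* **Age drift** shifts generating means by `slope · (age − mean age)`
  at planted sites, sign-oriented per site so a positive slope models
  regression to the mean.  The default `age_slope` of 0 disables it; a
  drift of 0.12 beta over a 60-year span at κ = 100 is comfortably
  recovered by the |r| > 0.3 correlation filter.
* **Missing values** are independent per entry at `missing_rate`
  (default 1%, in the range of masked probes in processed matrices).

Default cohort dimensions — 8 tissues × (20 + 20) samples × 20,000
sites with 50 planted unique sites per tissue — are desk-scale stand-ins
for compendium data: large enough for stable quantiles and clearly
powered statistics, small enough to generate in seconds.

One integer seed drives everything through deterministically derived
sub-streams (background, planting, metadata, observation, missingness),
so identical configurations are bit-identical.  `apply_erosion` and
`apply_age_drift` redraw affected entries by inverse-CDF sampling on
uniforms drawn independently of the shift; because the Beta family at
fixed concentration is stochastically ordered in its mean, redrawn
values are monotone in λ at a fixed seed, which makes erosion sweeps
well-behaved.

**What the generator does not emulate:** genome coordinates, probe
design (type I/II chemistry), cell-composition mixtures, batch effects,
spatially correlated missingness, or sex-linked methylation structure.
Passing recovery tests on this generator shows the estimators are
correct under the stated model — bounded bimodal signal, independent
Beta noise, independent missingness — not that real cohorts satisfy
that model; cell-composition drift in particular can mimic or mask
regression to the mean in bulk tissue.

## Parameter defaults that matter

| parameter | default | units | why |
|---|---|---|---|
| margin | 0.1 | beta | published criterion; detectable against array noise |
| quantile | 0.05 | fraction | published 5%/95% outer quantiles |
| center | mean | — | operational description; median switchable |
| min_valid | 0.5 | fraction of samples | desk-scale analogue of the 2,000-valid-values compendium filter; pass an int ≥ 1 for an absolute count |
| κ (concentration) | 50 | — | SD ≈ 0.06–0.07 mid-range, like replicate noise |
| erosion λ | 0 | — | no effect unless asked for; 1 = full regression |
| missing_rate | 0.01 | probability | typical masked-probe fraction |
| r threshold (global trend) | 0.3 | — | published robust-change working point |
| binomial null p₀ | 0.5 | probability | random-direction null |

## Numerical choices and degenerate inputs

* Beta values marginally outside [0, 1] by ≤ 1e−9 are clamped (float
  text artifacts); larger violations are errors naming site, sample and
  value.  Duplicate identifiers are rejected naming the first
  duplicate.
* Matrix round trips are documented at 6 significant digits; a second
  write of a read matrix is byte-identical.
* BED export is 0-based half-open; array manifests are commonly
  1-based, so positions must be converted when building a manifest.
* Pearson correlations are pairwise-complete over missing entries and
  undefined (call = undefined) with fewer than 3 pairs or a constant
  vector.
* `binom_log10_sf(0, n)` returns exactly 0 (certainty); results are
  clamped to ≤ 0 against rounding.
* PCA requires ≥ n_components + 1 samples and ≥ n_components complete
  sites; leave-one-out identifies the failing sample when a refit or
  projection fails; a degenerate sick group (fewer than 2 members, or
  zero spread) is an error under radius2sd rather than a silent call.

## Known limitations

* The min_valid filter, quantile estimator and center statistic are the
  main places where reasonable conventions differ between analyses;
  all are parameters, but defaults will not reproduce someone else's
  exact site list without matching their choices.
* The correlation mode's 0/1 disease indicator treats group labels as
  exchangeable with a continuous covariate; rank-based alternatives are
  not implemented.
* No multiple-testing correction across tissues or cohorts: the
  binomial p-values are reported raw, as single-hypothesis statistics
  per summary.
* Classification is deliberately simple (three Euclidean distance
  models in 2D); it demonstrates that the unique-site signature carries
  label information, not that these are competitive classifiers.
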