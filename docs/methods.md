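# Methods

## Problem setting

Multi-hospital histopathology archives carry acquisition-site fingerprints:
each contributing hospital's stain chemistry shifts the H&E color spectrum,
and each scanner leaves a characteristic low-amplitude noise texture. Frozen
patch embeddings computed from such images can therefore encode *which
hospital* a slide came from, and because site composition is confounded with
diagnosis in consortium archives, models and retrieval systems built on those
embeddings can exploit the site instead of the morphology. This package
measures that leakage with two instruments — a supervised site probe and an
observed-vs-expected retrieval audit — on synthetic cohorts where the ground
truth site effect is controlled by a single knob.

## Synthetic cohorts

A cohort is defined by `CohortConfig`: number of sites and classes, per-site
slide shares (largest-remainder apportioned so counts are exact), a
site × class composition table, patches per slide (default 55, the mosaic
budget used downstream), and a site-effect amplitude `alpha ≥ 0`.

**Image mode.** A patch is rendered as elliptical dark "nuclei" (count
Poisson with class-dependent density, radius class-dependent, lognormal size
jitter) on a pale eosin-like background, then passed through the site's
stain matrix `I + alpha·Δ` (entries of `Δ` drawn once per site, uniform in
[−0.15, 0.15]) and perturbed by the site's fixed band-limited Gaussian noise
texture (coarse 1/8-resolution white noise, bicubically upsampled,
unit-standardized) at amplitude `alpha·0.05` of the dynamic range. At
`alpha = 0` every site renders identically — an exact null. Patch edge
defaults to 128 px (configurable up to 1000): the pipeline's behaviour, not
image resolution, is under study.

**Feature mode** (the fast path). A patch vector is
`mu_class + alpha·u_site + eps`, with unit-norm class means and site-shift
directions drawn once per cohort and isotropic noise of expected norm 0.5.
`alpha` is thus the site shift in units of the class-separation scale;
`alpha = 4` puts the site signal far above the noise, `alpha = 0.25` makes
it comparable to it.

**Patients.** By default 7% of patients own two slides (both in the same
site and project), mirroring the minority of multi-slide patients in real
cohorts; these exist purely to exercise the leakage guards.

**Balanced composition.** Cohorts used for null calibration set
`balanced_classes=True`: per-site class counts follow the composition table
deterministically (largest remainder) instead of independent draws. With
random draws the realized site mix *within* a class fluctuates, and because
test slides are the complement of training slides, an overfit probe
anti-predicts the test composition and lands measurably below chance — a
composition artifact, not a feature-space site effect. Pinning the
composition (and stratifying splits by site × project, below) removes the
artifact; we verified the null probe then sits at 0.19–0.22 against chance
0.2 across seeds.

What the generator does *not* emulate: realistic tissue morphology, nucleus
shape families, compression artifacts, scanner optics, demographic
covariates. Passing tests show the pipeline's statistics behave correctly
when site effects are exactly the stain-plus-noise mechanism; they do not
show that real cohorts' site signal has that form or magnitude, and the
calibration of `alpha` to any real archive is deliberately left open.

## Mosaic sampling

Candidate patches are filtered by cellularity — the fraction of
hematoxylin-like pixels, defined as luminance < 0.55 of the dynamic range
with blue exceeding red; a patch passes at ≥ 0.1 by default — then clustered
by RGB histogram (16 bins/channel, L1-normalized, concatenated) with seeded
k-means (9 clusters, 10 restarts), and the 55-patch budget is allocated to
clusters proportionally by largest remainder, capped at cluster size, with
uniform without-replacement sampling inside each cluster. Filtering precedes
allocation so budgets reflect eligible patches only. The cellularity
formula and the histogram dialect are this package's own documented choices;
both are configurable.

## Feature extraction

The extractor contract is the pipeline's only coupling point: any
deterministic raster → fixed-width vector callable can be plugged in. The
shipped `BaselineExtractor` is handcrafted and weight-free: per-channel
histograms (stain-sensitive), an axial gradient-orientation histogram
(morphology-sensitive, nearly color-invariant), and a local-variance pyramid
(texture/noise energy), projected to d = 1024 by a fixed Gaussian matrix
generated from a shipped seed, so features are reproducible to the bit.
Features are used raw (no normalization) by default, with an optional
cohort z-score. `SiteAwareExtractor` is an *oracle* contrast: it appends the
unit-norm direction of the true stain deviation plus the normalized noise
amplitude (10 dimensions) to the baseline vector — the direction rather than
the raw deviation, whose magnitude at weak effects (~1e−3) would vanish next
to the base features; at `alpha = 0` the cue is exactly zero.

## Site probe

A two-hidden-layer MLP (500 and 200 ReLU units, Adam, batch size 60,
5 epochs, cross-entropy on integer site labels; sklearn `MLPClassifier`)
is trained on per-patch features to predict the institution. Splits are
~90/10 by slide, per-site quotas spread over the site's projects
proportionally (site × project stratification), with all slides of
multi-slide patients confined to training; the full split → train → evaluate
cycle is repeated (default 30×) with seeds derived from one root seed.
Patch-level accuracy and slide-level accuracy (majority vote over patch
predictions, ties to the highest mean class probability) are both reported;
slide-level is the headline, since the slide is the unit at which site
membership is defined. Per-site one-vs-rest precision/recall/F1 and the
confusion matrix accompany each report. Scopes restrict the experiment to
contribution group A or B (institutions above/below 1% of slides, strict
boundary) or to one cancer project.

## Retrieval and the bias audit

Slide-to-slide distance is the directional median-of-min: for each query
patch, the minimum Euclidean distance to the other slide's patches, then the
median over query patches (lower-middle element for even counts, so the
value is always an attained distance; midpoint convention available). A
mean-pooled variant (distance between per-slide mean vectors) is provided.
Search is restricted to the query's diagnosis, excludes the query and, by
default, other slides of the query's patient, and breaks distance ties by
slide id.

For each (diagnosis, site), every slide of the site queries the diagnosis
corpus with k = 5 and the same-site results are counted. Expected values
under no bias: naive `q·k·n_i/N` and self-excluded `q·k·(n_i−1)/(N−1)`;
the self-excluded form equals the mean of the permutation null exactly (only
pair counts matter under label exchange) and is the default reference.
Significance comes from permuting site labels across slides within the
diagnosis (≥ 1000 permutations) with neighbor lists held fixed — neighbor
lists are dependent across queries, so no parametric count model applies —
with the two-sided p-value
`(1 + #{|O_perm − mean| ≥ |O_obs − mean|})/(n_perm + 1)`. Degenerate strata
(single-site diagnosis, single-slide site) are reported with NaN EV/p rather
than dropped. P-values are reported raw, without multiple-testing
correction, as the audit is descriptive per site.

## Reference studies and problem sizes

The studies in `sitebias.studies` fix desk-scale conditions shared by the
analysis drivers, tests and acceptance script:

* null/effect cohorts: 5 equal sites, 2 classes, 200 slides, 20
  patches/slide, feature width 64, `alpha` 0 or 4; probe repeated 30×
  (null) / 10× (effect); audit with k = 5, 2000 permutations, and 20
  independent cohorts for null calibration;
* alpha sweep: 100 slides, 10 patches, width 32, `alpha ∈ {0, 0.25, 0.5, 1}`,
  10 repeats per level;
* extractor contrast: rendered 64-px patches, 100 slides × 8 patches,
  `alpha = 0.02` — chosen so the plain descriptor sits well below ceiling
  (color histograms saturate site detection already at `alpha ≈ 0.05`),
  leaving room for the oracle's strict improvement;
* EV consistency: 5 random configurations, 10,000 permutations, agreement
  within 3 Monte-Carlo standard errors.

With 5 equal sites, the per-site ceiling of the observed/EV ratio is
`(N−1)/(n_i−1) ≈ 5.1`; the >4× response check is therefore attainable but
close to the ceiling. A 3-site equal-share design cannot exceed ~3× and is
unusable for that check.

## Numerical and degenerate-input conventions

Largest-remainder rounding everywhere counts must conserve totals (site
shares, class composition, cluster budgets, test quotas), with ties broken
by index. All randomness flows from named integer streams derived from a
single cohort or experiment seed; every stage is a pure function of its
config. Histogram equalization of a constant channel returns it unchanged.
Empty patch sets, single-class training data, empty eligible corpora, and
malformed slide barcodes raise explicit errors naming the offending object.

## Known limitations

The probe's absolute accuracies on synthetic cohorts say nothing about any
real archive: both the effect mechanism and its amplitude are simulated.
The median-of-min distance is asymmetric and is used as such; rankings can
differ from symmetrized variants. The institution alias table performs no
fuzzy matching, so unresolved naming variants remain distinct sites. The
audit's permutation null exchanges labels at slide level; with many
multi-slide patients a patient-level exchangeability null would differ
slightly (at the default 7% the difference is negligible, and the audit's
false-flag rate was measured at the nominal 5%).
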