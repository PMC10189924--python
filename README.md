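# sitebias

Acquisition-site bias audit for histopathology patch embeddings.

Hospitals that contribute whole-slide images (WSIs) to multi-center archives
leave fingerprints in the pixels — stain chemistry shifts the H&E color
spectrum, scanners add characteristic noise textures — and frozen deep (or
handcrafted) patch features can encode *which hospital* a slide came from.
Because site composition is confounded with diagnosis in consortium archives,
classifiers may score by recognizing hospitals instead of morphology, and
image search may return "similar" slides that are merely same-site slides.
`sitebias` is a pipeline for measuring that leakage, aimed at computational
pathology researchers who want to audit an embedding or a retrieval system
before trusting it:

* **synthetic cohorts** (`sitebias.synthetic`) — multi-site, multi-class
  slide cohorts, as rendered RGB patches or directly in feature space, with
  one knob `alpha` scaling both a per-site stain matrix `I + alpha·Δ` and a
  per-site noise texture; `alpha = 0` is an exact null;
* **metadata** (`sitebias.metadata`) — TCGA-style barcode parsing
  (`TCGA-<TSS>-<participant>` → site code, patient), institution alias
  normalization, contribution groups A/B at the 1% threshold;
* **mosaic sampling** (`sitebias.mosaic`) — RGB-histogram k-means (9
  clusters), proportional largest-remainder patch budgets (55/slide),
  cellularity filtering;
* **features** (`sitebias.features`) — pluggable extractor contract with a
  deterministic handcrafted baseline (d = 1024), so no trained weights are
  needed anywhere;
* **site probe** (`sitebias.probe`) — a 2-hidden-layer MLP (500/200 ReLU,
  Adam, batch 60, 5 epochs) predicting the site from patch features under a
  patient-aware, site×project-stratified 90/10 split, repeated 30×;
* **retrieval + audit** (`sitebias.search`, `sitebias.audit`) — slide search
  with the directional **median-of-min** distance
  (for each query patch, the minimum distance to the other slide's patches;
  then the median over query patches), restricted to the query's diagnosis,
  and the observed-vs-expected same-site statistic: with site *i* holding
  `n_i` of `N` slides and `q` queries returning `k` results each,

  ```
  EV_naive         = q·k·n_i/N
  EV_self_excluded = q·k·(n_i−1)/(N−1)     (equals the permutation-null mean)
  ```

  with a label-permutation test for significance.

## Worked example

```python
from sitebias import CohortConfig, generate_feature_cohort, ProbeConfig
from sitebias.probe import repeat_experiment
from sitebias.audit import audit_report

cfg = CohortConfig(n_sites=5, n_classes=2, n_slides=200, patches_per_slide=20,
                   feature_dim=64, site_effect_alpha=4.0, balanced_classes=True,
                   seed=1)
manifest, features = generate_feature_cohort(cfg)

probe = repeat_experiment(manifest, features, ProbeConfig(n_repeats=10, seed=1))
print(f"slide-level site accuracy {probe['slide_accuracy_mean']:.3f}")

audit = audit_report(features, manifest, k=5, n_permutations=2000, seed=1)
print(audit.per_site()[["site", "observed", "ev_self_excluded", "ratio"]])
```

prints

```
slide-level site accuracy 1.000
          site  observed  ev_self_excluded     ratio
0  Hospital 00       200         38.388350  5.209914
1  Hospital 01       200         38.388350  5.209914
2  Hospital 02       200         38.388350  5.209914
3  Hospital 03       200         38.532448  5.190431
4  Hospital 04       200         38.707205  5.166997
```

At `alpha = 4` the site shift dwarfs the feature noise: the probe identifies
every test slide's hospital, and all 200 top-5 search results per site come
from the query's own site — 5.2× the count expected under no bias (the
ceiling for 5 equal sites is `(N−1)/(n_i−1) ≈ 5.1`, so retrieval is maximally
site-biased). Rerun with `site_effect_alpha=0.0` and the probe drops to
chance (0.2) while every ratio sits near 1. The numbered scripts under
`analysis/` walk through the full study set (composition, null calibration,
alpha sweep, retrieval audit, extractor contrast) and write their tables
under `results/`.

A CLI mirrors the pipeline stages for on-disk stores
(`sitebias simulate | metadata | sample | extract | probe | search | audit`).

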