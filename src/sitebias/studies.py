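"""Canonical study configurations and end-to-end experiment runners.

These functions define the package's reference experiments at desk scale and
are shared by the analysis drivers, the test suite and the acceptance script,
so every consumer runs the same study conditions:

* **Null calibration** — a zero-site-effect cohort (5 equal sites, 200
  slides, 20 patches/slide, feature mode, uniform class composition).  The
  probe must sit at chance and the retrieval audit must flag nothing beyond
  its nominal false-positive rate.
* **Effect response** — the same geometry at a large site effect (``alpha``
  = 4, site shift far above the feature noise), where the probe should
  approach perfect slide-level accuracy and every site's observed same-site
  retrieval count should exceed 4× its expected value.
* **Alpha sweep** — probe accuracy as a function of the site-effect knob.
* **Extractor contrast** — rendered-image cohort, plain handcrafted extractor
  versus a site-cue oracle extractor, measuring how much a site-aware
  representation inflates site decodability.

Cohort sizes, feature widths and repeat counts here are deliberate desk-scale
choices (documented in the methods note); the generator's own defaults mirror
the full-cohort geometry.
"""

from __future__ import annotations

import numpy as np

from .audit import audit_report, expected_same_site
from .features import BaselineExtractor, SiteAwareExtractor, extract_features
from .mosaic import PatchSet
from .probe import ProbeConfig, repeat_experiment
from .synthetic import (
    CohortConfig,
    generate_cohort,
    generate_feature_cohort,
    make_site_effects,
    site_code,
)

#: Site-effect levels for the monotonicity sweep.
SWEEP_ALPHAS = (0.0, 0.25, 0.5, 1.0)

#: Large site effect: shift norm 4 against feature noise norm 0.5.
EFFECT_ALPHA = 4.0

#: Site effect for the rendered-image extractor-contrast study: strong enough
#: for the stain/noise cue to be learnable, weak enough that the plain
#: handcrafted descriptor stays below ceiling.
CONTRAST_ALPHA = 0.02

AUDIT_K = 5
AUDIT_PERMUTATIONS = 2000


def null_cohort_config(seed: int, alpha: float = 0.0) -> CohortConfig:
    """The calibration cohort: 5 equal sites, 2 uniform classes, feature mode.

    The class composition is uniform across sites on purpose: a site × class
    association would let the probe predict the site through the class, which
    is a cohort-composition confounder rather than a feature-space site
    effect, and would break the chance-level null.
    """
    return CohortConfig(
        n_sites=5,
        n_classes=2,
        n_slides=200,
        patches_per_slide=20,
        feature_dim=64,
        site_effect_alpha=alpha,
        balanced_classes=True,
        seed=seed,
    )


def sweep_cohort_config(seed: int, alpha: float) -> CohortConfig:
    return CohortConfig(
        n_sites=5,
        n_classes=2,
        n_slides=100,
        patches_per_slide=10,
        feature_dim=32,
        site_effect_alpha=alpha,
        balanced_classes=True,
        seed=seed,
    )


def contrast_cohort_config(seed: int) -> CohortConfig:
    return CohortConfig(
        n_sites=5,
        n_classes=2,
        n_slides=100,
        patches_per_slide=8,
        patch_px=64,
        feature_dim=1024,
        site_effect_alpha=CONTRAST_ALPHA,
        seed=seed,
    )


def run_null_probe(seed: int, n_repeats: int = 30) -> dict:
    """30-repeat probe on the zero-effect cohort; should sit at chance (1/5)."""
    manifest, store = generate_feature_cohort(null_cohort_config(seed))
    config = ProbeConfig(n_repeats=n_repeats, seed=seed)
    result = repeat_experiment(manifest, store, config, scope="all")
    result["chance"] = 1.0 / manifest["institution"].nunique()
    return result


def run_null_audit_calibration(seed: int, n_seeds: int = 20) -> dict:
    """Bias audits on ``n_seeds`` independent zero-effect cohorts.

    Returns the fraction of (diagnosis, site) strata flagged at p < 0.05,
    which should stay near the nominal 5% level.
    """
    n_tests = 0
    n_flagged = 0
    ratios = []
    for i in range(n_seeds):
        cohort_seed = int(np.random.default_rng([seed, i]).integers(0, 2**31 - 1))
        manifest, store = generate_feature_cohort(null_cohort_config(cohort_seed))
        rep = audit_report(
            store, manifest, k=AUDIT_K,
            n_permutations=AUDIT_PERMUTATIONS, seed=cohort_seed,
        )
        t = rep.table.dropna(subset=["p"])
        n_tests += len(t)
        n_flagged += int((t["p"] < 0.05).sum())
        ratios.extend(t["ratio"].tolist())
    return {
        "n_seeds": n_seeds,
        "n_tests": n_tests,
        "n_flagged": n_flagged,
        "flag_fraction": n_flagged / n_tests if n_tests else float("nan"),
        "mean_ratio": float(np.mean(ratios)),
    }


def run_effect_probe(seed: int, n_repeats: int = 10) -> dict:
    """Probe on the strong-site-effect cohort; should approach perfect accuracy."""
    manifest, store = generate_feature_cohort(null_cohort_config(seed, alpha=EFFECT_ALPHA))
    config = ProbeConfig(n_repeats=n_repeats, seed=seed)
    return repeat_experiment(manifest, store, config, scope="all")


def run_effect_audit(seed: int) -> dict:
    """Bias audit on the strong-site-effect cohort.

    With 5 equal sites the per-site ceiling of the observed/EV ratio is
    (N−1)/(n_i−1) ≈ 5.1, so the >4× response is attainable but not trivial.
    """
    manifest, store = generate_feature_cohort(null_cohort_config(seed, alpha=EFFECT_ALPHA))
    rep = audit_report(
        store, manifest, k=AUDIT_K, n_permutations=AUDIT_PERMUTATIONS, seed=seed
    )
    per_site = rep.per_site()
    return {
        "report": rep,
        "per_site": per_site,
        "min_ratio": float(per_site["ratio"].min()),
    }


def run_alpha_sweep(seed: int, n_repeats: int = 10, alphas=SWEEP_ALPHAS) -> list[dict]:
    """Probe accuracy across site-effect levels (same cohort geometry and seed)."""
    out = []
    for alpha in alphas:
        manifest, store = generate_feature_cohort(sweep_cohort_config(seed, alpha))
        config = ProbeConfig(n_repeats=n_repeats, seed=seed)
        res = repeat_experiment(manifest, store, config, scope="all")
        out.append(
            {
                "alpha": alpha,
                "slide_accuracy_mean": res["slide_accuracy_mean"],
                "slide_accuracy_sd": res["slide_accuracy_sd"],
                "patch_accuracy_mean": res["patch_accuracy_mean"],
                "patch_accuracy_sd": res["patch_accuracy_sd"],
            }
        )
    return out


def count_inversions(means, sds) -> tuple[int, bool]:
    """Count decreases along the accuracy-vs-alpha curve and whether the
    sequence is acceptable: non-decreasing up to one inversion within 1 sd."""
    inversions = [
        (i, means[i + 1] - means[i]) for i in range(len(means) - 1) if means[i + 1] < means[i]
    ]
    if not inversions:
        return 0, True
    if len(inversions) == 1:
        i, drop = inversions[0]
        tol = max(sds[i], sds[i + 1])
        return 1, abs(drop) <= tol
    return len(inversions), False


def run_extractor_contrast(seed: int, n_repeats: int = 5) -> dict:
    """Plain baseline vs site-cue oracle extractor on one rendered cohort.

    Both extractors see the same rendered patches; the oracle variant also
    receives each slide's true stain/noise fingerprint as a 10-dimensional
    cue.  Mean patch-level site accuracy should be strictly higher with the
    cue whenever the plain descriptor is below ceiling.
    """
    cfg = contrast_cohort_config(seed)
    manifest, patch_store = generate_cohort(cfg, mode="images")
    effects = make_site_effects(cfg)
    code_to_idx = {site_code(i): i for i in range(cfg.n_sites)}
    base = BaselineExtractor(dim=cfg.feature_dim)
    aware = SiteAwareExtractor(base, cue_scale=1.0)
    plain_store, aware_store = {}, {}
    site_of = manifest.set_index("slide_id")["site_code"]
    for sid, sp in patch_store.items():
        ps = PatchSet(
            slide_id=sid, coords=sp.coords, cluster_level=5.0, sample_level=20.0,
            rasters=sp.rasters,
        )
        plain_store[sid] = extract_features(ps, base)
        aware.bind_site(effects[code_to_idx[site_of[sid]]])
        aware_store[sid] = extract_features(ps, aware)
    config = ProbeConfig(n_repeats=n_repeats, seed=seed)
    plain = repeat_experiment(manifest, plain_store, config, scope="all")
    aware_res = repeat_experiment(manifest, aware_store, config, scope="all")
    return {
        "plain_patch_accuracy": plain["patch_accuracy_mean"],
        "aware_patch_accuracy": aware_res["patch_accuracy_mean"],
        "plain_slide_accuracy": plain["slide_accuracy_mean"],
        "aware_slide_accuracy": aware_res["slide_accuracy_mean"],
        "gain": aware_res["patch_accuracy_mean"] - plain["patch_accuracy_mean"],
    }


def run_ev_consistency(seed: int, n_configs: int = 5, n_perm: int = 10_000) -> list[dict]:
    """Self-excluded analytic EV vs permutation-null mean on random cohorts.

    For each random configuration a small feature cohort is generated, the
    audit's permutation null is run at ``n_perm`` permutations, and the
    standardized gap z = (perm mean − EV) / (null sd / √n_perm) is recorded
    per (diagnosis, site) stratum.
    """
    rng = np.random.default_rng(seed)
    out = []
    for c in range(n_configs):
        n_sites = int(rng.integers(3, 6))
        cfg = CohortConfig(
            n_sites=n_sites,
            n_classes=int(rng.integers(1, 3)),
            n_slides=int(rng.integers(40, 70)),
            patches_per_slide=int(rng.integers(3, 8)),
            feature_dim=16,
            site_effect_alpha=float(rng.uniform(0.0, 2.0)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        k = int(rng.integers(3, 6))
        manifest, store = generate_feature_cohort(cfg)
        rep = audit_report(
            store, manifest, k=k, n_permutations=n_perm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        zs = []
        for row in rep.table.itertuples():
            if row.n_i < 2 or not np.isfinite(row.ev_self_excluded):
                continue
            se = row.perm_sd / np.sqrt(n_perm)
            zs.append((row.perm_mean - row.ev_self_excluded) / se if se > 0 else 0.0)
        out.append(
            {
                "config_index": c,
                "n_sites": n_sites,
                "n_slides": cfg.n_slides,
                "k": k,
                "alpha": cfg.site_effect_alpha,
                "max_abs_z": float(np.max(np.abs(zs))),
                "n_strata": len(zs),
            }
        )
    return out
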