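import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats

from sitebias.synthetic import (
    CohortConfig,
    SiteEffect,
    amplify_noise,
    generate_cohort,
    generate_feature_cohort,
    generate_manifest,
    largest_remainder,
    make_site_effects,
    render_patch,
)


def _cfg(**kw):
    base = dict(n_sites=4, n_classes=2, n_slides=40, patches_per_slide=4,
                patch_px=64, feature_dim=16, seed=5)
    base.update(kw)
    return CohortConfig(**base)


class TestConfigValidation:
    def test_rejects_shares_not_summing_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            _cfg(site_shares=[0.5, 0.4, 0.05, 0.04])

    def test_rejects_share_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            _cfg(site_shares=[0.5, 0.5])

    def test_rejects_bad_class_given_site_row(self):
        rows = [[0.9, 0.2]] + [[0.5, 0.5]] * 3
        with pytest.raises(ValueError, match="row must sum to 1"):
            _cfg(class_given_site=rows)


class TestManifest:
    def test_equal_shares_divide_exactly(self):
        m = generate_manifest(_cfg())
        assert m.groupby("site_code")["slide_id"].count().tolist() == [10] * 4

    def test_twenty_percent_share_owns_twenty_of_hundred(self):
        cfg = _cfg(n_slides=100, site_shares=[0.20, 0.30, 0.30, 0.20])
        m = generate_manifest(cfg)
        assert m.groupby("site_code")["slide_id"].count()["00"] == 20

    def test_manifests_identical_across_runs(self):
        m1, m2 = generate_manifest(_cfg()), generate_manifest(_cfg())
        pd.testing.assert_frame_equal(m1, m2)

    def test_multi_slide_patients_at_configured_fraction(self):
        cfg = _cfg(n_slides=428, multi_slide_patient_frac=0.07)
        m = generate_manifest(cfg)
        counts = m.groupby("patient_id")["slide_id"].count()
        frac = (counts > 1).sum() / len(counts)
        assert frac == pytest.approx(0.07, abs=0.015)
        # both slides of a patient share site and project
        for _, sub in m.groupby("patient_id"):
            assert sub["site_code"].nunique() == 1
            assert sub["project"].nunique() == 1

    @given(
        n=hst.integers(min_value=1, max_value=500),
        shares=hst.lists(hst.floats(min_value=0.01, max_value=1.0), min_size=1, max_size=8),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_largest_remainder_conserves_and_bounds(self, n, shares):
        total = sum(shares)
        shares = [s / total for s in shares]
        counts = largest_remainder(shares, n)
        assert counts.sum() == n
        for c, s in zip(counts, shares):
            assert abs(c - s * n) < 1.0


class TestSiteEffects:
    def test_alpha_zero_gives_identity_stain_and_no_noise(self):
        effects = make_site_effects(_cfg(site_effect_alpha=0.0))
        for e in effects:
            np.testing.assert_array_equal(e.stain_matrix, np.eye(3))
            assert e.noise_amplitude == 0.0

    def test_alpha_zero_rasters_identical_across_sites(self):
        cfg = _cfg(site_effect_alpha=0.0)
        e1, e2 = make_site_effects(cfg)[:2]
        r1 = render_patch(0, e1, np.random.default_rng(9), patch_px=64)
        r2 = render_patch(0, e2, np.random.default_rng(9), patch_px=64)
        np.testing.assert_array_equal(r1, r2)

    def test_channel_means_shift_with_stain_matrices(self):
        # over >=100 patches, each site's mean color must equal the mean of
        # the identity-stain pixels pushed through that site's matrix (with
        # clipping), recomputed here from the base rasters
        cfg = _cfg(site_effect_alpha=1.0)
        effects = make_site_effects(cfg)[:2]
        base = SiteEffect(np.eye(3), 1, 0.0)
        rng = np.random.default_rng(4)
        raw = [render_patch(1, base, rng, patch_px=64) for _ in range(100)]
        site_means = []
        for eff in effects:
            noiseless = SiteEffect(eff.stain_matrix, eff.noise_texture_seed, 0.0)
            rng = np.random.default_rng(4)
            shifted = [render_patch(1, noiseless, rng, patch_px=64) for _ in range(100)]
            got = np.mean([r.mean(axis=(0, 1)) for r in shifted], axis=0)
            expected = np.mean(
                [np.clip(r @ eff.stain_matrix.T, 0, 1).mean(axis=(0, 1)) for r in raw],
                axis=0,
            )
            np.testing.assert_allclose(got, expected, atol=1e-12)
            site_means.append(got)
        assert np.abs(site_means[0] - site_means[1]).max() > 0.01

    def test_blank_class_is_background_plus_site_transform(self, identity_effect):
        r = render_patch(None, identity_effect, np.random.default_rng(0), patch_px=64)
        assert np.unique(r.reshape(-1, 3), axis=0).shape[0] == 1

    def test_zero_effect_sites_statistically_indistinguishable(self):
        # two-sample t-test on per-channel patch means: non-significant at
        # the 0.01 level in at least 95 of 100 seeded runs
        cfg = _cfg(site_effect_alpha=0.0)
        e1, e2 = make_site_effects(cfg)[:2]
        significant = 0
        for run in range(100):
            rng1 = np.random.default_rng([run, 1])
            rng2 = np.random.default_rng([run, 2])
            m1 = np.array([render_patch(0, e1, rng1, patch_px=64).mean(axis=(0, 1))
                           for _ in range(8)])
            m2 = np.array([render_patch(0, e2, rng2, patch_px=64).mean(axis=(0, 1))
                           for _ in range(8)])
            pvals = [stats.ttest_ind(m1[:, c], m2[:, c]).pvalue for c in range(3)]
            if min(pvals) < 0.01:
                significant += 1
        assert significant <= 5


class TestImageCohort:
    def test_cohort_shape_and_determinism(self):
        cfg = _cfg(n_slides=8)
        m1, s1 = generate_cohort(cfg, mode="images")
        m2, s2 = generate_cohort(cfg, mode="images")
        assert len(m1) == 8
        pd.testing.assert_frame_equal(m1, m2)
        for sid in m1["slide_id"]:
            assert len(s1[sid].rasters) == cfg.patches_per_slide
            for a, b in zip(s1[sid].rasters, s2[sid].rasters):
                np.testing.assert_array_equal(a, b)


class TestFeatureCohort:
    def test_alpha_zero_site_means_agree(self):
        cfg = _cfg(n_slides=100, patches_per_slide=10, site_effect_alpha=0.0,
                   balanced_classes=True)
        m, store = generate_feature_cohort(cfg)
        by_site = {}
        for row in m.itertuples():
            by_site.setdefault(row.site_code, []).append(store[row.slide_id].X)
        means = {s: np.vstack(v).mean(axis=0) for s, v in by_site.items()}
        codes = list(means)
        gaps = [np.linalg.norm(means[a] - means[b]) for a in codes for b in codes if a < b]
        # sampling error only: ~sigma/sqrt(n_patches_per_site)
        assert max(gaps) < 0.15

    def test_large_alpha_recovers_sites_by_nearest_centroid(self):
        cfg = _cfg(n_slides=100, patches_per_slide=10, site_effect_alpha=5.0)
        m, store = generate_feature_cohort(cfg)
        X = np.vstack([store[s].X for s in m["slide_id"]])
        y = np.repeat(m["site_code"].to_numpy(), cfg.patches_per_slide)
        codes = sorted(set(y))
        centroids = np.vstack([X[y == c].mean(axis=0) for c in codes])
        d = ((X[:, None, :] - centroids[None]) ** 2).sum(axis=2)
        pred = np.array(codes)[d.argmin(axis=1)]
        assert (pred == y).mean() >= 0.99

    def test_same_seed_gives_identical_matrices(self):
        _, s1 = generate_feature_cohort(_cfg())
        _, s2 = generate_feature_cohort(_cfg())
        for sid in s1:
            np.testing.assert_array_equal(s1[sid].X, s2[sid].X)


class TestAmplifyNoise:
    def test_constant_patch_unchanged(self):
        img = np.full((32, 32, 3), 0.5)
        np.testing.assert_array_equal(amplify_noise(img), img)

    def test_equalization_raises_variance_of_faint_noise(self):
        rng = np.random.default_rng(0)
        img = np.clip(0.95 + 0.01 * rng.normal(size=(64, 64, 3)), 0, 1)
        out = amplify_noise(img)
        assert out.var() > img.var()

    def test_equalization_nearly_idempotent(self):
        eff = SiteEffect(np.eye(3), 7, 0.05)
        rng = np.random.default_rng(3)
        for _ in range(10):
            img = render_patch(1, eff, rng, patch_px=64)
            once = amplify_noise(img)
            twice = amplify_noise(once)
            assert np.abs(twice - once).mean() < 0.02
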