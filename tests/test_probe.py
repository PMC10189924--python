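import numpy as np
import pandas as pd
import pytest

from sitebias.probe import (
    ProbeConfig,
    SplitPlan,
    evaluate_probe,
    majority_vote,
    make_split,
    repeat_experiment,
    train_probe,
)
from sitebias.synthetic import CohortConfig, generate_feature_cohort, generate_manifest


@pytest.fixture(scope="module")
def cohort():
    cfg = CohortConfig(
        n_sites=3, n_classes=2, n_slides=60, patches_per_slide=6,
        feature_dim=16, site_effect_alpha=3.0, balanced_classes=True, seed=2,
    )
    return generate_feature_cohort(cfg)


class TestMakeSplit:
    def test_multi_slide_patients_never_reach_test(self):
        cfg = CohortConfig(n_sites=2, n_classes=1, n_slides=40, patches_per_slide=2,
                           feature_dim=4, multi_slide_patient_frac=0.3, seed=3)
        manifest = generate_manifest(cfg)
        counts = manifest.groupby("patient_id")["slide_id"].count()
        multi_patients = set(counts[counts > 1].index)
        assert multi_patients  # the fixture must actually contain them
        plan = make_split(manifest, ProbeConfig(seed=1))
        test_patients = set(
            manifest.set_index("slide_id").loc[plan.test_ids, "patient_id"]
        )
        assert not (test_patients & multi_patients)

    def test_ten_percent_of_single_slide_cohort_goes_to_test(self):
        cfg = CohortConfig(n_sites=2, n_classes=1, n_slides=100, patches_per_slide=2,
                           feature_dim=4, multi_slide_patient_frac=0.0, seed=3)
        manifest = generate_manifest(cfg)
        plan = make_split(manifest, ProbeConfig(test_fraction=0.1, seed=1))
        assert len(plan.test_ids) == 10

    def test_same_seed_reproduces_plan_distinct_seeds_differ(self, cohort):
        manifest, _ = cohort
        cfg = ProbeConfig(seed=5)
        p1 = make_split(manifest, cfg, seed=5)
        p2 = make_split(manifest, cfg, seed=5)
        p3 = make_split(manifest, cfg, seed=6)
        assert p1.test_ids == p2.test_ids
        assert p1.test_ids != p3.test_ids

    def test_no_patient_spans_train_and_test(self, cohort):
        manifest, _ = cohort
        plan = make_split(manifest, ProbeConfig(seed=0))
        pid = manifest.set_index("slide_id")["patient_id"]
        assert not (set(pid[plan.train_ids]) & set(pid[plan.test_ids]))

    def test_overlapping_plan_rejected_at_construction(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitPlan(0, ["a", "b"], ["b"], 0)


class TestTrainProbe:
    def test_separable_sites_reach_near_perfect_training_accuracy(self, cohort):
        manifest, store = cohort
        labels = manifest.set_index("slide_id")["institution"]
        X = np.vstack([store[s].X for s in manifest["slide_id"]])
        y = np.repeat(
            labels[manifest["slide_id"]].to_numpy(),
            [store[s].n_patches for s in manifest["slide_id"]],
        )
        clf = train_probe(X, y, ProbeConfig(), seed=0)
        assert (clf.predict(X) == y).mean() >= 0.99

    def test_shuffled_labels_approach_chance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5000, 8))
        y = rng.integers(0, 4, size=5000).astype(str)
        holdout_X = rng.normal(size=(2000, 8))
        holdout_y = rng.integers(0, 4, size=2000).astype(str)
        clf = train_probe(X, y, ProbeConfig(), seed=0)
        acc = (clf.predict(holdout_X) == holdout_y).mean()
        assert abs(acc - 0.25) < 0.03

    def test_single_class_input_rejected(self):
        X = np.zeros((10, 4))
        with pytest.raises(ValueError, match="2 sites"):
            train_probe(X, np.array(["a"] * 10), ProbeConfig(), seed=0)

    def test_fixed_seed_gives_identical_predictions(self, cohort):
        manifest, store = cohort
        labels = manifest.set_index("slide_id")["institution"]
        X = np.vstack([store[s].X for s in manifest["slide_id"][:30]])
        y = np.repeat(labels[manifest["slide_id"][:30]].to_numpy(), 6)
        p1 = train_probe(X, y, ProbeConfig(), seed=9).predict(X)
        p2 = train_probe(X, y, ProbeConfig(), seed=9).predict(X)
        np.testing.assert_array_equal(p1, p2)


class TestEvaluate:
    def test_hand_built_confusion_matrix(self):
        # 2 slides x 3 patches, predictions fixed by a stub classifier
        class Stub:
            classes_ = np.array(["H0", "H1"])

            def predict(self, X):
                return np.array(["H0", "H0", "H1", "H1", "H1", "H0"])

            def predict_proba(self, X):
                p = np.array([[0.9, 0.1]] * 6)
                return p

        from sitebias.features import SlideFeatures

        store = {
            "s1": SlideFeatures("s1", np.zeros((3, 2))),
            "s2": SlideFeatures("s2", np.ones((3, 2))),
        }
        labels = pd.Series({"s1": "H0", "s2": "H1"})
        rep = evaluate_probe(Stub(), store, ["s1", "s2"], labels)
        # s1: votes H0,H0,H1 -> H0 (correct); s2: H1,H1,H0 -> H1 (correct)
        assert rep.slide_accuracy == 1.0
        assert rep.patch_accuracy == pytest.approx(4 / 6)
        np.testing.assert_array_equal(rep.confusion, np.eye(2, dtype=int))

    def test_tie_broken_by_highest_mean_class_score(self):
        pred = np.array(["H0", "H1"])
        proba = np.array([[0.2, 0.8], [0.3, 0.7]])
        slides = np.array(["s", "s"])
        out = majority_vote(pred, proba, slides, np.array(["H0", "H1"]))
        assert out["s"] == "H1"

    def test_uniform_random_probe_scores_near_chance(self):
        rng = np.random.default_rng(1)
        sites = np.array([f"H{i}" for i in range(5)])

        class RandomStub:
            classes_ = sites

            def predict(self, X):
                return rng.choice(sites, size=len(X))

            def predict_proba(self, X):
                return np.full((len(X), 5), 0.2)

        from sitebias.features import SlideFeatures

        store = {f"s{i}": SlideFeatures(f"s{i}", np.zeros((10, 2))) for i in range(1000)}
        labels = pd.Series({f"s{i}": sites[i % 5] for i in range(1000)})
        rep = evaluate_probe(RandomStub(), store, list(store), labels)
        assert rep.patch_accuracy == pytest.approx(0.2, abs=0.01)


class TestRepeatExperiment:
    def test_single_repeat_equals_manual_cycle(self, cohort):
        manifest, store = cohort
        config = ProbeConfig(n_repeats=1, seed=4)
        agg = repeat_experiment(manifest, store, config, scope="all")
        ss = np.random.SeedSequence(4)
        rseed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
        labels = manifest.set_index("slide_id")["institution"]
        plan = make_split(manifest, config, repeat_index=0, seed=rseed)
        X = np.vstack([store[s].X for s in plan.train_ids])
        y = np.repeat(labels[plan.train_ids].to_numpy(), 6)
        clf = train_probe(X, y, config, seed=rseed)
        rep = evaluate_probe(clf, store, plan.test_ids, labels)
        assert agg["slide_accuracy_mean"] == rep.slide_accuracy
        assert agg["patch_accuracy_mean"] == rep.patch_accuracy

    def test_scope_with_single_site_rejected(self, cohort):
        manifest, store = cohort
        one_site = manifest[manifest["site_code"] == "00"]
        with pytest.raises(ValueError, match="fewer than 2 sites"):
            repeat_experiment(one_site, store, ProbeConfig(n_repeats=1), scope="all")

    def test_project_scope_restricts_to_one_cancer_type(self, cohort):
        manifest, store = cohort
        config = ProbeConfig(n_repeats=1, seed=1)
        agg = repeat_experiment(manifest, store, config, scope="project:SYN00")
        test_ids = agg["plans"][0].test_ids
        projects = manifest.set_index("slide_id")["project"]
        assert all(projects[s] == "SYN00" for s in test_ids)
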