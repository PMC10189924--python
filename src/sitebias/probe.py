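"""Site-leakage probe: a small MLP predicting the acquisition site from features.

How much acquisition-site information do frozen patch features carry?  The
probe is a two-hidden-layer network (500 and 200 ReLU units, Adam, batch size
60, 5 epochs, cross-entropy on integer site labels) trained on per-patch
features and evaluated under a patient-aware repeated-split protocol: roughly
90/10 train/test by slide, stratified by site, with every multi-slide patient
confined to the training set so no patient spans the split.  The whole cycle
(split → train → evaluate) is repeated (default 30×) with distinct derived
seeds and results are aggregated as mean ± sd.

Accuracy is reported at two levels: per patch, and per slide via majority
vote over the slide's patch predictions (ties broken by the highest mean
predicted class probability).  Slide-level accuracy is the headline number —
the slide is the unit at which site membership is defined.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.neural_network import MLPClassifier

from .features import SlideFeatures
from .metadata import assign_groups

logger = logging.getLogger(__name__)


@dataclass
class ProbeConfig:
    hidden_sizes: tuple[int, int] = (500, 200)
    epochs: int = 5
    batch_size: int = 60
    test_fraction: float = 0.1
    n_repeats: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_repeats < 1 or self.epochs < 1:
            raise ValueError("n_repeats and epochs must be positive")


@dataclass
class SplitPlan:
    """One repeat's train/test partition with patient-leakage guarantees."""

    repeat_index: int
    train_ids: list[str]
    test_ids: list[str]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test slide sets overlap")


@dataclass
class ClassifierReport:
    patch_accuracy: float
    slide_accuracy: float
    per_site: pd.DataFrame  # site, precision, recall, f1, support (test slides)
    confusion: np.ndarray
    site_order: list[str]


def make_split(
    manifest: pd.DataFrame, config: ProbeConfig, repeat_index: int = 0, seed: int | None = None
) -> SplitPlan:
    """Draw one patient-aware, site-stratified train/test split.

    Slides of multi-slide patients go to training unconditionally.  Per site,
    ``round(test_fraction · site slides)`` test slides (at least 1) are drawn
    from single-slide patients, spread across the site's cancer projects in
    proportion to their size so the test composition mirrors the cohort's
    site × class table.  A site with fewer than 2 eligible single-slide
    patients contributes no test slides (warned).
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng([seed, repeat_index])
    patient_counts = manifest.groupby("patient_id")["slide_id"].count()
    multi = set(patient_counts[patient_counts > 1].index)
    test_ids: list[str] = []
    any_site_ok = False
    for site, sub in manifest.groupby("institution"):
        elig = sub[~sub["patient_id"].isin(multi)]
        if len(elig) < 2:
            logger.warning("site %s has < 2 eligible single-slide patients; "
                           "excluded from test scope", site)
            continue
        any_site_ok = True
        n_test = max(1, int(round(config.test_fraction * len(sub))))
        n_test = min(n_test, len(elig) - 1)
        picked: list[str] = []
        # proportional (largest-remainder) allocation over the site's projects
        cells = [cell for _, cell in sub.groupby("project")]
        sizes = np.array([len(c) for c in cells], dtype=float)
        quotas = sizes / sizes.sum() * n_test
        counts = np.floor(quotas).astype(int)
        order = np.lexsort((np.arange(len(cells)), -(quotas - counts)))
        counts[order[: n_test - counts.sum()]] += 1
        leftovers: list[str] = []
        for cell, c in zip(cells, counts):
            cell_elig = cell[~cell["patient_id"].isin(multi)]["slide_id"].to_numpy()
            c_take = min(int(c), len(cell_elig))
            take = rng.choice(cell_elig, size=c_take, replace=False)
            picked.extend(take.tolist())
            leftovers.extend(sorted(set(cell_elig) - set(take)))
        if len(picked) < n_test and leftovers:
            extra = rng.choice(
                np.array(sorted(leftovers)), size=min(n_test - len(picked), len(leftovers)),
                replace=False,
            )
            picked.extend(extra.tolist())
        test_ids.extend(picked)
    if not any_site_ok:
        raise ValueError("no site has eligible test slides")
    test_set = set(test_ids)
    train_ids = [s for s in manifest["slide_id"] if s not in test_set]
    return SplitPlan(
        repeat_index=repeat_index,
        train_ids=train_ids,
        test_ids=sorted(test_ids),
        seed=seed,
    )


def _stack(store: dict[str, SlideFeatures], slide_ids, labels: pd.Series):
    X, y, slides = [], [], []
    for sid in slide_ids:
        sf = store[sid]
        X.append(sf.X)
        y.extend([labels[sid]] * sf.n_patches)
        slides.extend([sid] * sf.n_patches)
    return np.vstack(X), np.asarray(y), np.asarray(slides)


def train_probe(X: np.ndarray, y: np.ndarray, config: ProbeConfig, seed: int = 0):
    """Fit the two-hidden-layer probe; reproducible for a fixed seed."""
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least 2 sites")
    clf = MLPClassifier(
        hidden_layer_sizes=config.hidden_sizes,
        activation="relu",
        solver="adam",
        batch_size=config.batch_size,
        max_iter=config.epochs,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # the probe intentionally stops after a fixed epoch budget
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        clf.fit(X, y)
    if not np.isfinite(clf.loss_):
        raise RuntimeError("probe training diverged (non-finite loss)")
    return clf


def majority_vote(
    pred: np.ndarray, proba: np.ndarray, slides: np.ndarray, classes: np.ndarray
) -> dict[str, object]:
    """Slide label by majority vote over patch predictions; ties go to the
    class with the highest mean predicted probability over the slide."""
    out: dict[str, object] = {}
    for sid in np.unique(slides):
        m = slides == sid
        votes = pd.Series(pred[m]).value_counts()
        top = votes.max()
        tied = sorted(votes[votes == top].index)
        if len(tied) == 1:
            out[sid] = tied[0]
        else:
            mean_p = proba[m].mean(axis=0)
            scores = {c: mean_p[np.flatnonzero(classes == c)[0]] for c in tied}
            out[sid] = max(tied, key=lambda c: (scores[c], c))
    return out


def evaluate_probe(
    clf, store: dict[str, SlideFeatures], test_ids, labels: pd.Series
) -> ClassifierReport:
    """Patch- and slide-level accuracy plus per-site one-vs-rest P/R/F1."""
    if len(test_ids) == 0:
        raise ValueError("empty test set")
    X, y, slides = _stack(store, test_ids, labels)
    pred = clf.predict(X)
    proba = clf.predict_proba(X)
    patch_acc = float((pred == y).mean())
    slide_pred = majority_vote(pred, proba, slides, clf.classes_)
    true_by_slide = {sid: labels[sid] for sid in test_ids}
    slide_ids = sorted(true_by_slide)
    y_true = [true_by_slide[s] for s in slide_ids]
    y_hat = [slide_pred[s] for s in slide_ids]
    site_order = sorted(set(y_true) | set(y_hat))
    prec, rec, f1, supp = precision_recall_fscore_support(
        y_true, y_hat, labels=site_order, zero_division=0
    )
    per_site = pd.DataFrame(
        {"site": site_order, "precision": prec, "recall": rec, "f1": f1, "support": supp}
    )
    cm = confusion_matrix(y_true, y_hat, labels=site_order)
    slide_acc = float(np.mean([a == b for a, b in zip(y_true, y_hat)]))
    return ClassifierReport(
        patch_accuracy=patch_acc,
        slide_accuracy=slide_acc,
        per_site=per_site,
        confusion=cm,
        site_order=site_order,
    )


def _restrict_scope(manifest: pd.DataFrame, scope: str) -> pd.DataFrame:
    if scope == "all":
        return manifest
    if scope in ("groupA", "groupB"):
        groups = assign_groups(manifest)
        keep = set(groups.members(scope[-1]))
        return manifest[manifest["institution"].isin(keep)]
    if scope.startswith("project:"):
        return manifest[manifest["project"] == scope.split(":", 1)[1]]
    raise ValueError(f"unknown scope {scope!r}")


def repeat_experiment(
    manifest: pd.DataFrame,
    store: dict[str, SlideFeatures],
    config: ProbeConfig,
    scope: str = "all",
) -> dict:
    """Run the full repeated protocol in a scope and aggregate the reports.

    ``scope`` is ``"all"``, ``"groupA"``/``"groupB"`` (contribution groups at
    the 1% threshold) or ``"project:<name>"`` (one cancer type).  Each repeat
    uses a distinct seed derived from the config seed.
    """
    sub = _restrict_scope(manifest, scope).reset_index(drop=True)
    if sub["institution"].nunique() < 2:
        raise ValueError(f"scope {scope!r} has fewer than 2 sites")
    labels = sub.set_index("slide_id")["institution"]
    ss = np.random.SeedSequence(config.seed)
    repeat_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(config.n_repeats)]
    reports: list[ClassifierReport] = []
    plans: list[SplitPlan] = []
    for r, rseed in enumerate(repeat_seeds):
        plan = make_split(sub, config, repeat_index=r, seed=rseed)
        Xtr, ytr, _ = _stack(store, plan.train_ids, labels)
        clf = train_probe(Xtr, ytr, config, seed=rseed)
        reports.append(evaluate_probe(clf, store, plan.test_ids, labels))
        plans.append(plan)
    patch = np.array([r.patch_accuracy for r in reports])
    slide = np.array([r.slide_accuracy for r in reports])
    per_site = (
        pd.concat([r.per_site for r in reports])
        .groupby("site", as_index=False)
        .agg(
            precision=("precision", "mean"),
            recall=("recall", "mean"),
            f1=("f1", "mean"),
            support=("support", "sum"),
        )
    )
    return {
        "scope": scope,
        "n_repeats": config.n_repeats,
        "patch_accuracy_mean": float(patch.mean()),
        "patch_accuracy_sd": float(patch.std(ddof=1)) if len(patch) > 1 else 0.0,
        "slide_accuracy_mean": float(slide.mean()),
        "slide_accuracy_sd": float(slide.std(ddof=1)) if len(slide) > 1 else 0.0,
        "per_site": per_site,
        "reports": reports,
        "plans": plans,
        "n_test_slides_total": int(sum(len(p.test_ids) for p in plans)),
    }
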