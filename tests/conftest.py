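"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

from sitebias.features import SlideFeatures

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from sitebias.synthetic import CohortConfig, SiteEffect, generate_feature_cohort


def brute_median_of_min(A: np.ndarray, B: np.ndarray) -> float:
    """Exhaustive double-loop median-of-min (lower-middle median).

    Independent of the library implementation: plain Python loops over all
    patch pairs.
    """
    mins = []
    for a in A:
        best = None
        for b in B:
            d = float(np.sqrt(np.sum((np.asarray(a) - np.asarray(b)) ** 2)))
            if best is None or d < best:
                best = d
        mins.append(best)
    mins.sort()
    return mins[(len(mins) - 1) // 2]


def brute_allocation(sizes: list[int], budget: int) -> tuple[int, ...]:
    """Proportional-optimum allocation by exhaustive enumeration.

    Among all integer tuples that sum to min(budget, total) and respect the
    per-cluster caps, pick the one closest (L1) to the exact proportional
    quotas, breaking ties lexicographically by preferring earlier clusters to
    round up (the largest-remainder convention with index tie-breaks).
    """
    total = sum(sizes)
    target = min(budget, total)
    quotas = [s / total * target for s in sizes]
    best, best_key = None, None
    for combo in itertools.product(*(range(s + 1) for s in sizes)):
        if sum(combo) != target:
            continue
        cost = sum(abs(c - q) for c, q in zip(combo, quotas))
        key = (cost, tuple(-c for c in combo))
        if best_key is None or key < best_key:
            best, best_key = combo, key
    return best


@pytest.fixture(scope="session")
def identity_effect() -> SiteEffect:
    return SiteEffect(stain_matrix=np.eye(3), noise_texture_seed=1, noise_amplitude=0.0)


@pytest.fixture(scope="session")
def small_feature_cohort():
    """Tiny feature-mode cohort shared by search/audit/probe tests."""
    cfg = CohortConfig(
        n_sites=3, n_classes=2, n_slides=30, patches_per_slide=5,
        feature_dim=8, site_effect_alpha=1.0, balanced_classes=True, seed=11,
    )
    manifest, store = generate_feature_cohort(cfg)
    return cfg, manifest, store


def make_features(slide_id: str, rows) -> SlideFeatures:
    return SlideFeatures(slide_id, np.asarray(rows, dtype=float), extractor="test")
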