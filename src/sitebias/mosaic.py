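"""Mosaic patch selection: histogram clustering, proportional budgets, cellularity.

A slide is summarized by a small "mosaic" of patches: candidate patches are
clustered by RGB histogram at low magnification, the patch budget (default 55)
is allocated to clusters proportionally to their size, and patches with low
cellularity — too few nucleus-dense pixels — are discarded before allocation
so the budget is spent on tissue-rich regions.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)


class EmptyMosaicError(ValueError):
    """No patch of a slide passed the cellularity filter."""


@dataclass
class MosaicConfig:
    n_clusters: int = 9
    histogram_bins_per_channel: int = 16
    budget: int = 55
    cellularity_threshold: float = 0.1
    cluster_level: float = 5.0
    sample_level: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if not 0.0 <= self.cellularity_threshold <= 1.0:
            raise ValueError("cellularity_threshold must be in [0, 1]")


@dataclass
class PatchSet:
    """A slide's selected mosaic: coordinates (0-based, half-open, level-tagged),
    magnification tags, and the selected rasters."""

    slide_id: str
    coords: list[tuple[int, int, int]]
    cluster_level: float
    sample_level: float
    rasters: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if len(set(self.coords)) != len(self.coords):
            raise ValueError(f"duplicate patch coordinates in {self.slide_id}")

    def __len__(self) -> int:
        return len(self.coords)


def rgb_histograms(patches: Sequence[np.ndarray], bins: int = 16) -> np.ndarray:
    """Concatenated per-channel histograms, each L1-normalized, one row per patch."""
    rows = []
    for p in patches:
        chans = []
        for c in range(3):
            h, _ = np.histogram(p[..., c], bins=bins, range=(0.0, 1.0))
            chans.append(h / max(h.sum(), 1))
        rows.append(np.concatenate(chans))
    return np.vstack(rows)


def cluster_patches(histograms: np.ndarray, n_clusters: int, seed: int = 0) -> np.ndarray:
    """Centroid-based partition of histogram rows into at most ``n_clusters``.

    With fewer patches than clusters every patch becomes its own cluster.
    Deterministic given the seed (10 restarts).
    """
    n = histograms.shape[0]
    if n < n_clusters:
        logger.info("only %d patches for %d clusters; singleton clusters", n, n_clusters)
        return np.arange(n)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    return km.fit_predict(histograms)


def allocate_budget(cluster_sizes: Sequence[int], budget: int) -> np.ndarray:
    """Largest-remainder proportional allocation, capped at cluster sizes.

    Counts sum to ``min(budget, total)``; each count is within 1 of its
    proportional quota unless capped by its cluster's size.
    """
    sizes = np.asarray(cluster_sizes, dtype=int)
    if np.any(sizes < 0) or sizes.sum() == 0:
        raise ValueError("cluster sizes must be nonnegative and not all zero")
    total = int(sizes.sum())
    target = min(budget, total)
    quotas = sizes / total * target
    counts = np.minimum(np.floor(quotas).astype(int), sizes)
    # hand out the remainder by descending fractional part, ties by index,
    # skipping clusters already at capacity
    order = np.lexsort((np.arange(len(sizes)), -(quotas - np.floor(quotas))))
    while counts.sum() < target:
        for i in order:
            if counts.sum() >= target:
                break
            if counts[i] < sizes[i]:
                counts[i] += 1
    return counts


def cellularity_score(patch: np.ndarray) -> float:
    """Fraction of hematoxylin-like pixels: dark (luminance < 0.55 of range)
    and blue-dominant (B > R), the signature of stained nuclei."""
    img = np.asarray(patch, dtype=float)
    lum = img @ np.array([0.299, 0.587, 0.114])
    nuclear = (lum < 0.55) & (img[..., 2] > img[..., 0])
    return float(nuclear.mean())


def sample_mosaic(slide, config: MosaicConfig) -> PatchSet:
    """Select a slide's mosaic: filter by cellularity, cluster, allocate, sample.

    The cellularity filter runs before clustering and allocation, so budgets
    reflect eligible patches only.  Within-cluster sampling is uniform without
    replacement, seeded by the config seed and the slide id, so the mosaic is
    a pure function of (slide, config).
    """
    rasters = slide.rasters
    scores = np.array([cellularity_score(r) for r in rasters])
    eligible = np.flatnonzero(scores >= config.cellularity_threshold)
    if eligible.size == 0:
        raise EmptyMosaicError(
            f"no patch of slide {slide.slide_id} passes cellularity "
            f">= {config.cellularity_threshold}"
        )
    hists = rgb_histograms(
        [rasters[i] for i in eligible], bins=config.histogram_bins_per_channel
    )
    labels = cluster_patches(hists, config.n_clusters, seed=config.seed)
    uniq = np.unique(labels)
    sizes = np.array([(labels == u).sum() for u in uniq])
    counts = allocate_budget(sizes, config.budget)
    rng = np.random.default_rng(
        [config.seed, zlib.crc32(slide.slide_id.encode()) & 0x7FFFFFFF]
    )
    chosen: list[int] = []
    for u, c in zip(uniq, counts):
        members = eligible[labels == u]
        pick = rng.choice(members, size=int(c), replace=False)
        chosen.extend(int(i) for i in np.sort(pick))
    chosen.sort()
    return PatchSet(
        slide_id=slide.slide_id,
        coords=[slide.coords[i] for i in chosen],
        cluster_level=config.cluster_level,
        sample_level=config.sample_level,
        rasters=[rasters[i] for i in chosen],
    )
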