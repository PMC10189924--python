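"""Slide-to-slide retrieval over patch feature bags.

The slide distance is the "median-of-min": for each patch of the query slide,
take its minimum Euclidean distance to the other slide's patches, then take
the median of those minima.  The measure is directional (query → corpus) and
is used as written, without symmetrization.  A mean-pooled variant (distance
between per-slide mean feature vectors) is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .features import SlideFeatures, pool_features


@dataclass
class SearchResult:
    query_id: str
    k: int
    neighbor_ids: list[str]
    distances: list[float]
    restricted_to_diagnosis: bool
    excluded_same_patient: bool

    def __post_init__(self) -> None:
        if self.query_id in self.neighbor_ids:
            raise ValueError("neighbors must exclude the query slide")
        if any(b < a for a, b in zip(self.distances, self.distances[1:])):
            raise ValueError("distances must be sorted ascending")


def _median_low(values: np.ndarray) -> float:
    """Lower-middle median: for even counts the lower of the two middle
    elements, so the result is always an attained min-distance."""
    s = np.sort(values)
    return float(s[(len(s) - 1) // 2])


def median_of_min_distance(
    A: SlideFeatures, B: SlideFeatures, median: str = "low"
) -> float:
    """Directional A→B distance: median over A's patches of each patch's
    minimum Euclidean distance to B's patches."""
    if A.n_patches == 0 or B.n_patches == 0:
        raise ValueError("median_of_min requires nonempty feature sets on both sides")
    mins = cdist(A.X, B.X).min(axis=1)
    if median == "low":
        return _median_low(mins)
    if median == "mid":
        return float(np.median(mins))
    raise ValueError(f"unknown median convention {median!r}")


def mean_pooled_distance(A: SlideFeatures, B: SlideFeatures) -> float:
    """Euclidean distance between the slides' mean-pooled feature vectors."""
    return float(np.linalg.norm(pool_features(A) - pool_features(B)))


def slide_distance(A: SlideFeatures, B: SlideFeatures, metric: str) -> float:
    if metric == "median_of_min":
        return median_of_min_distance(A, B)
    if metric == "mean_pooled":
        return mean_pooled_distance(A, B)
    raise ValueError(f"unknown metric {metric!r}")


def search(
    query_id: str,
    store: dict[str, SlideFeatures],
    manifest: pd.DataFrame,
    k: int,
    metric: str = "median_of_min",
    restrict_to_diagnosis: bool = True,
    exclude_same_patient: bool = True,
) -> SearchResult:
    """Rank the ``k`` nearest slides to a query under the chosen metric.

    The corpus is restricted to the query's diagnosis (cancer project) by
    default and the query itself — plus, by default, any other slide of the
    query's patient — is excluded.  Distance ties are broken by slide id so
    the ranking is deterministic.
    """
    meta = manifest.set_index("slide_id")
    if query_id not in meta.index:
        raise KeyError(f"unknown slide id {query_id!r}")
    q_project = meta.at[query_id, "project"]
    q_patient = meta.at[query_id, "patient_id"]
    eligible = []
    for sid in store:
        if sid == query_id:
            continue
        if restrict_to_diagnosis and meta.at[sid, "project"] != q_project:
            continue
        if exclude_same_patient and meta.at[sid, "patient_id"] == q_patient:
            continue
        eligible.append(sid)
    if not eligible:
        raise ValueError(f"no eligible corpus slides for query {query_id!r}")
    qf = store[query_id]
    pairs = sorted(
        ((slide_distance(qf, store[sid], metric), sid) for sid in eligible),
        key=lambda t: (t[0], t[1]),
    )
    top = pairs[: min(k, len(pairs))]
    return SearchResult(
        query_id=query_id,
        k=k,
        neighbor_ids=[sid for _, sid in top],
        distances=[d for d, _ in top],
        restricted_to_diagnosis=restrict_to_diagnosis,
        excluded_same_patient=exclude_same_patient,
    )


def all_pairs_median_of_min(
    features: list[SlideFeatures], median: str = "low"
) -> np.ndarray:
    """Directional median-of-min distance matrix over a list of slides.

    Fast path for whole-cohort audits: one stacked pairwise patch-distance
    computation, reduced per slide pair.  Entry (i, j) is the i→j distance;
    the diagonal is 0.  Slides may have unequal patch counts.
    """
    sizes = [sf.n_patches for sf in features]
    X = np.vstack([sf.X for sf in features])
    D = cdist(X, X)
    n = len(features)
    if len(set(sizes)) == 1:
        p = sizes[0]
        mins = D.reshape(n, p, n, p).min(axis=3)  # (i, patch_of_i, j)
        srt = np.sort(mins, axis=1)
        out = srt[:, (p - 1) // 2, :] if median == "low" else np.median(mins, axis=1)
        np.fill_diagonal(out, 0.0)
        return out
    offs = np.concatenate([[0], np.cumsum(sizes)])
    out = np.zeros((n, n))
    for i in range(n):
        rows = D[offs[i]:offs[i + 1]]
        for j in range(n):
            if i == j:
                continue
            mins = rows[:, offs[j]:offs[j + 1]].min(axis=1)
            out[i, j] = _median_low(mins) if median == "low" else float(np.median(mins))
    return out
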