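"""Retrieval bias audit: observed vs expected same-site counts in search results.

For each acquisition site, every one of its slides is used as a query against
all slides of the same diagnosis, and the number of top-``k`` results coming
from the query's own site is counted.  Under a no-bias null the expected
same-site count follows from the site's share of the corpus: a site holding
20% of the slides should supply about 1 in 5 results.  Two analytic variants
are implemented:

* ``naive``:          EV = q · k · n_i / N
* ``self_excluded``:  EV = q · k · (n_i − 1) / (N − 1)

where ``n_i`` is the site's slide count, ``N`` the eligible corpus size and
``q`` the number of queries.  The self-excluded form accounts for the query
never retrieving itself and equals the mean of the label-permutation null
exactly, so it is the default reference.  Significance is assessed with that
permutation null (site labels shuffled across slides within a diagnosis,
neighbor lists held fixed) rather than a parametric count model, because
neighbor lists are dependent across queries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import SlideFeatures
from .search import all_pairs_median_of_min, slide_distance


def expected_same_site(
    k: int, n_i: int, N: int, q: int, variant: str = "self_excluded"
) -> float:
    """Expected same-site count among q·k results under the no-bias null."""
    if not 1 <= n_i <= N:
        raise ValueError("need 1 <= n_i <= N")
    if q > n_i:
        raise ValueError("cannot have more same-site queries than site slides")
    if not 1 <= k <= N - 1:
        raise ValueError("need 1 <= k <= N - 1")
    if variant == "naive":
        return q * k * n_i / N
    if variant == "self_excluded":
        if n_i < 2:
            raise ValueError("self-excluded EV requires n_i >= 2")
        return q * k * (n_i - 1) / (N - 1)
    raise ValueError(f"unknown variant {variant!r}")


def observed_same_site(results, manifest: pd.DataFrame) -> dict[str, int]:
    """Count, per site, the (query, neighbor) pairs sharing the query's site."""
    site_of = manifest.set_index("slide_id")["institution"]
    counts: dict[str, int] = {}
    for r in results:
        try:
            q_site = site_of[r.query_id]
            same = sum(site_of[nb] == q_site for nb in r.neighbor_ids)
        except KeyError as e:
            raise KeyError(f"slide id not resolvable in manifest: {e}") from e
        counts[q_site] = counts.get(q_site, 0) + same
    return counts


def permutation_null(
    query_idx: np.ndarray,
    neighbor_idx: np.ndarray,
    site_labels: np.ndarray,
    n_perm: int,
    seed: int,
) -> dict[int, dict]:
    """Permutation null of per-site same-site counts on fixed neighbor lists.

    ``query_idx`` and ``neighbor_idx`` are parallel arrays of slide indices —
    one entry per (query, neighbor) pair — and ``site_labels`` assigns a site
    to each slide.  Site labels are permuted across slides; for each site the
    null distribution of the same-site count O and a two-sided p-value
    ``(1 + #{|O_perm − mean| >= |O_obs − mean|}) / (n_perm + 1)`` are returned.
    With a single site in scope the p-value is undefined and reported as NaN.
    """
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    site_labels = np.asarray(site_labels)
    sites = np.unique(site_labels)
    rng = np.random.default_rng(seed)
    n_slides = len(site_labels)
    perms = np.empty((n_perm, n_slides), dtype=site_labels.dtype)
    for p in range(n_perm):
        perms[p] = site_labels[rng.permutation(n_slides)]
    lq = perms[:, query_idx]
    ln = perms[:, neighbor_idx]
    same = lq == ln
    out: dict[int, dict] = {}
    obs_q = site_labels[query_idx]
    obs_n = site_labels[neighbor_idx]
    for s in sites:
        null_o = np.sum(same & (lq == s), axis=1)
        o_obs = int(np.sum((obs_q == s) & (obs_n == s)))
        mean = float(null_o.mean())
        if len(sites) < 2:
            p_val = float("nan")
        else:
            p_val = float(
                (1 + np.sum(np.abs(null_o - mean) >= abs(o_obs - mean))) / (n_perm + 1)
            )
        out[s] = {
            "observed": o_obs,
            "null": null_o,
            "null_mean": mean,
            "null_sd": float(null_o.std()),
            "p": p_val,
        }
    return out


@dataclass
class BiasReport:
    """Per-(diagnosis, site) audit table plus the audit's parameters."""

    table: pd.DataFrame
    k: int
    n_permutations: int
    seed: int

    def per_site(self) -> pd.DataFrame:
        """Aggregate over diagnoses: per-site totals and pooled O/EV ratio."""
        g = self.table.groupby("site", as_index=False).agg(
            n_slides=("n_i", "sum"),
            q=("q", "sum"),
            observed=("observed", "sum"),
            ev_naive=("ev_naive", "sum"),
            ev_self_excluded=("ev_self_excluded", "sum"),
        )
        g["ratio"] = g["observed"] / g["ev_self_excluded"]
        return g


def audit_report(
    store: dict[str, SlideFeatures],
    manifest: pd.DataFrame,
    k: int = 5,
    metric: str = "median_of_min",
    n_permutations: int = 2000,
    seed: int = 0,
    exclude_same_patient: bool = True,
) -> BiasReport:
    """Run the full observed-vs-expected same-site audit, per diagnosis and site.

    Every slide of every diagnosis is queried against its diagnosis corpus;
    per (diagnosis, site) the observed same-site count O, both analytic EVs,
    the ratio O/EV(self-excluded) and a permutation p-value are tabulated.
    Degenerate strata (a diagnosis with a single site, or a site with a single
    slide) are flagged: their EV and/or p are NaN.
    """
    rows = []
    for project, sub in manifest.groupby("project"):
        sub = sub.reset_index(drop=True)
        ids = list(sub["slide_id"])
        feats = [store[s] for s in ids]
        sites = sub["institution"].to_numpy()
        patients = sub["patient_id"].to_numpy()
        N = len(ids)
        if N < 2:
            continue
        kk = min(k, N - 1)
        D = all_pairs_median_of_min(feats) if metric == "median_of_min" else None
        if D is None:
            D = np.zeros((N, N))
            for i in range(N):
                for j in range(N):
                    if i != j:
                        D[i, j] = slide_distance(feats[i], feats[j], metric)
        # rank neighbors per query; exclude self (and same patient if asked),
        # breaking distance ties by slide id for determinism
        id_rank = np.argsort(np.argsort(ids))
        q_list, nb_list = [], []
        for i in range(N):
            mask = np.ones(N, dtype=bool)
            mask[i] = False
            if exclude_same_patient:
                mask &= patients != patients[i]
            cand = np.flatnonzero(mask)
            order = cand[np.lexsort((id_rank[cand], D[i, cand]))]
            for j in order[:kk]:
                q_list.append(i)
                nb_list.append(int(j))
        site_codes_, site_int = np.unique(sites, return_inverse=True)
        null = permutation_null(
            np.asarray(q_list), np.asarray(nb_list), site_int,
            n_perm=n_permutations, seed=seed,
        )
        for s_idx, site in enumerate(site_codes_):
            n_i = int((site_int == s_idx).sum())
            q = n_i  # every slide of the site is queried
            info = null[s_idx]
            ev_naive = q * kk * n_i / N
            ev_self = (
                q * kk * (n_i - 1) / (N - 1) if n_i >= 2 else float("nan")
            )
            rows.append(
                {
                    "project": project,
                    "site": site,
                    "n_i": n_i,
                    "N": N,
                    "q": q,
                    "k": kk,
                    "observed": info["observed"],
                    "ev_naive": ev_naive,
                    "ev_self_excluded": ev_self,
                    "ratio": info["observed"] / ev_self if n_i >= 2 else float("nan"),
                    "perm_mean": info["null_mean"],
                    "perm_sd": info["null_sd"],
                    "p": info["p"],
                }
            )
    table = pd.DataFrame(rows)
    return BiasReport(table=table, k=k, n_permutations=n_permutations, seed=seed)


def plot_observed_vs_expected(report: BiasReport, path=None):
    """Bar chart of observed same-site counts against the self-excluded EV,
    one group per (diagnosis, site)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = report.table
    labels = [f"{r.project}\n{r.site} (n={r.n_i})" for r in t.itertuples()]
    x = np.arange(len(t))
    fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(t)), 4))
    ax.bar(x - 0.2, t["observed"], width=0.4, color="seagreen", label="observed")
    ax.bar(x + 0.2, t["ev_self_excluded"], width=0.4, color="orange", label="EV")
    ax.set_xticks(x)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_ylabel(f"same-site results among top-{report.k}")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
        return None
    return fig
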