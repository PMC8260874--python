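"""Consensus k-means clustering of protein trajectories.

Trajectories are per-protein log2 fold changes versus uninjured controls
over the post-injury timepoints.  For each candidate k, many k-means runs
on random protein subsamples are aggregated into a consensus matrix (the
fraction of co-sampled runs in which two proteins co-cluster); the final
assignment cuts an average-linkage dendrogram of 1 - consensus into k
groups.  The number of clusters is chosen from the relative change in the
area under the consensus CDF: k grows until adding a cluster no longer
appreciably increases the area.  Tiny clusters are pruned, and each
cluster is tested for gene-set enrichment with the upper-tail
hypergeometric test against the clustered background.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from sklearn.cluster import KMeans

from .containers import AbundanceMatrix, SampleTable
from .de import bh_adjust

__all__ = [
    "ConsensusResult",
    "logfc_trajectories",
    "consensus_kmeans",
    "prune_small_clusters",
    "cluster_enrichment",
]

log = logging.getLogger(__name__)

UNASSIGNED = -1


@dataclasses.dataclass
class ConsensusResult:
    consensus: dict[int, pd.DataFrame]  # k -> proteins x proteins co-clustering fraction
    assignments: dict[int, pd.Series]  # k -> protein -> cluster id (1..k)
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    chosen_k: int

    @property
    def chosen_assignment(self) -> pd.Series:
        return self.assignments[self.chosen_k]


def logfc_trajectories(
    m: AbundanceMatrix,
    samples: SampleTable,
    control_group: str,
    timepoints: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Mean log2 fold change of injured samples versus the control group,
    per protein and timepoint (observed values only).  Proteins never
    observed in controls are dropped."""
    meta = samples.aligned(m.sample_ids).set_index("sample_id")
    is_control = meta["group"] == control_group
    if not is_control.any():
        raise ValueError(f"control group {control_group!r} has no samples")
    ctrl = m.data.loc[:, is_control.to_numpy()]
    ctrl_mean = ctrl.mean(axis=1, skipna=True)
    missing_ctrl = ctrl_mean.isna()
    if missing_ctrl.any():
        log.warning("dropping %d proteins unobserved in controls", int(missing_ctrl.sum()))
    injured = meta.loc[~is_control]
    if timepoints is None:
        timepoints = sorted(t for t in injured["timepoint_h"].unique() if t > 0)
    cols = {}
    for t in timepoints:
        ids = injured.index[injured["timepoint_h"] == t]
        if len(ids) == 0:
            raise ValueError(f"no injured samples at timepoint {t}")
        cols[t] = m.data.loc[:, ids].mean(axis=1, skipna=True) - ctrl_mean
    out = pd.DataFrame(cols).loc[~missing_ctrl]
    return out.dropna(axis=0)


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus entries."""
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = np.sort(consensus[iu])
    n = len(vals)
    xs = np.concatenate([[0.0], vals, [1.0]])
    cdf = np.concatenate([[0.0], (np.arange(n) + 1) / n, [1.0]])
    return float(np.sum(np.diff(xs) * cdf[:-1]))


def consensus_kmeans(
    trajectories: pd.DataFrame,
    k_range: Sequence[int],
    n_subsamples: int = 100,
    item_fraction: float = 0.8,
    seed: int = 0,
    n_restarts: int = 10,
    elbow_tol: float = 0.1,
) -> ConsensusResult:
    """Consensus clustering over ``k_range`` with protein subsampling.

    chosen_k is the largest k whose relative delta area
    (A(k) - A(k-1)) / A(k-1) is still >= ``elbow_tol``, i.e. k stops
    growing once adding a cluster raises the consensus-CDF area by less
    than 10% (the conventional relative-increase rule); the smallest k in
    the range anchors the recursion and is always admissible.
    """
    X = trajectories.to_numpy(dtype=float)
    n = X.shape[0]
    k_range = sorted(k_range)
    if k_range[0] < 2 or k_range[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}], got {k_range}")
    rng = np.random.default_rng(seed)
    n_items = max(2, int(round(item_fraction * n)))
    subsamples = [np.sort(rng.choice(n, size=n_items, replace=False)) for _ in range(n_subsamples)]
    co_sampled = np.zeros((n, n))
    for idx in subsamples:
        co_sampled[np.ix_(idx, idx)] += 1.0
    if (co_sampled == 0).any():
        raise ValueError(
            "some protein pairs were never co-sampled; increase n_subsamples or item_fraction"
        )

    consensus: dict[int, pd.DataFrame] = {}
    assignments: dict[int, pd.Series] = {}
    cdf_area: dict[int, float] = {}
    for k in k_range:
        co_cluster = np.zeros((n, n))
        for b, idx in enumerate(subsamples):
            km = KMeans(n_clusters=k, n_init=n_restarts, random_state=int(seed % 2**31) + 7919 * k + b)
            labels = km.fit_predict(X[idx])
            for c in range(k):
                members = idx[labels == c]
                co_cluster[np.ix_(members, members)] += 1.0
        M = co_cluster / co_sampled
        np.fill_diagonal(M, 1.0)
        consensus[k] = pd.DataFrame(M, index=trajectories.index, columns=trajectories.index)
        dist = squareform(1.0 - M, checks=False)
        Z = linkage(dist, method="average")
        labels = fcluster(Z, t=k, criterion="maxclust")
        assignments[k] = pd.Series(labels, index=trajectories.index)
        cdf_area[k] = _cdf_area(M)

    delta_area: dict[int, float] = {}
    ks = list(k_range)
    delta_area[ks[0]] = cdf_area[ks[0]]
    for prev, k in zip(ks, ks[1:]):
        base = cdf_area[prev]
        delta_area[k] = (cdf_area[k] - base) / base if base > 0 else 0.0
    chosen = ks[0]
    for k in ks[1:]:
        if delta_area[k] >= elbow_tol:
            chosen = k
        else:
            break
    return ConsensusResult(
        consensus=consensus,
        assignments=assignments,
        cdf_area=cdf_area,
        delta_area=delta_area,
        chosen_k=chosen,
    )


def prune_small_clusters(assignment: pd.Series, min_size: int = 3) -> pd.Series:
    """Drop clusters with fewer than ``min_size`` members; their proteins
    become unassigned (-1) and surviving clusters are renumbered 1..K in
    order of their original ids."""
    sizes = assignment.value_counts()
    keep = sorted(c for c in sizes.index if sizes[c] >= min_size and c != UNASSIGNED)
    remap = {c: i + 1 for i, c in enumerate(keep)}
    return assignment.map(lambda c: remap.get(c, UNASSIGNED))


def cluster_enrichment(
    assignment: pd.Series,
    gene_sets: Mapping[str, Sequence[str]],
    background: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each gene set in each
    cluster, against the clustered background; BH correction within each
    cluster."""
    if background is None:
        background = list(assignment.index)
    bg = set(background)
    if not bg >= set(assignment.index):
        raise ValueError("background must contain every clustered protein")
    N = len(bg)
    rows = []
    clusters = sorted(c for c in assignment.unique() if c != UNASSIGNED)
    for c in clusters:
        members = set(assignment.index[assignment == c])
        for set_id, genes in gene_sets.items():
            in_bg = set(genes) & bg
            if not in_bg:
                continue
            overlap = len(members & in_bg)
            p = float(hypergeom.sf(overlap - 1, N, len(in_bg), len(members)))
            rows.append(
                {
                    "cluster": c,
                    "set_id": set_id,
                    "overlap": overlap,
                    "cluster_size": len(members),
                    "set_size": len(in_bg),
                    "background_size": N,
                    "p": p,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["q"] = np.nan
    for c in clusters:
        sel = table["cluster"] == c
        table.loc[sel, "q"] = bh_adjust(table.loc[sel, "p"].to_numpy())
    return table.sort_values(["cluster", "p"]).reset_index(drop=True)
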