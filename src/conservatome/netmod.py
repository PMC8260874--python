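"""Sample-similarity networks and group modularity.

Samples are nodes; an edge joins two samples when the Pearson correlation
of their abundance profiles (over the proteins observed in both samples)
ranks among the strongest pairs.  Networks are built to a target density —
the fraction of possible edges retained — so modularity curves are
comparable across datasets of different size.  Modularity of a given
grouping (timepoint, severity, subject, ...) is Newman's Q on the
thresholded graph, with an optional correlation-weighted variant.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, SampleTable

__all__ = [
    "SampleNetwork",
    "ModularityCurve",
    "build_sample_network",
    "modularity",
    "modularity_curve",
    "pairwise_sample_correlations",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class SampleNetwork:
    graph: nx.Graph  # nodes = sample ids; edge attr "weight" = correlation
    density: float
    threshold: float

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclasses.dataclass
class ModularityCurve:
    grouping: str
    densities: list[float]
    q_values: list[float]


def pairwise_sample_correlations(m: AbundanceMatrix, min_shared: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation between samples.  Pairs with
    fewer than ``min_shared`` jointly observed proteins get -inf (they can
    never form an edge)."""
    data = m.data
    if data.isna().any().any():
        # pairwise-complete: fall back to per-pair computation via masked arrays
        X = np.ma.masked_invalid(data.to_numpy())
        corr = np.ma.corrcoef(X, rowvar=False)
        corr = np.asarray(corr.filled(np.nan), dtype=float)
        shared = (~np.isnan(data.to_numpy())).astype(int)
        counts = shared.T @ shared
        bad = counts < min_shared
        if bad[np.triu_indices_from(bad, k=1)].any():
            log.warning("%d sample pairs share <%d observed proteins; excluded from edges",
                        int(bad[np.triu_indices_from(bad, k=1)].sum()), min_shared)
        corr[bad] = -np.inf
        corr[np.isnan(corr)] = -np.inf
    else:
        corr = np.corrcoef(data.to_numpy(), rowvar=False)
    out = pd.DataFrame(corr, index=data.columns, columns=data.columns)
    np.fill_diagonal(out.values, np.nan)
    return out


def build_sample_network(m: AbundanceMatrix, target_density: float) -> SampleNetwork:
    """Threshold the sample-correlation matrix to the largest edge count
    not exceeding ``round(target_density * n(n-1)/2)``.  Ties at the
    threshold are broken by lexicographic sample-id order, so the network
    is deterministic."""
    n = m.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples to build a network")
    if not 0.0 < target_density <= 1.0:
        raise ValueError(f"target_density must be in (0, 1], got {target_density}")
    corr = pairwise_sample_correlations(m)
    ids = list(corr.index)
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            r = corr.iloc[i, j]
            if np.isfinite(r):
                pairs.append((r, ids[i], ids[j]))
    n_target = int(round(target_density * n * (n - 1) / 2))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    chosen = pairs[:n_target]
    threshold = chosen[-1][0] if chosen else np.inf
    g = nx.Graph()
    g.add_nodes_from(ids)
    g.add_weighted_edges_from((a, b, r) for r, a, b in chosen)
    density = len(chosen) / (n * (n - 1) / 2)
    return SampleNetwork(graph=g, density=density, threshold=threshold)


def modularity(net: SampleNetwork, membership: Mapping[str, object], weighted: bool = False) -> float:
    """Newman modularity Q of a fixed grouping on the thresholded graph.

    Binary by default (each retained edge counts 1); ``weighted`` uses the
    correlation weights as edge strengths.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        raise ValueError("modularity undefined on an empty edge set")
    missing = [v for v in g.nodes if v not in membership]
    if missing:
        raise ValueError(f"nodes without a group: {missing[:5]}")
    groups: dict[object, set] = {}
    for v in g.nodes:
        groups.setdefault(membership[v], set()).add(v)
    communities = list(groups.values())
    weight = "weight" if weighted else None
    return float(nx.community.modularity(g, communities, weight=weight))


def modularity_curve(
    m: AbundanceMatrix,
    samples: SampleTable,
    groupings: Sequence[str],
    densities: Sequence[float],
    weighted: bool = False,
    restrict_timepoints: Sequence[float] | None = None,
) -> list[ModularityCurve]:
    """Q as a function of network density, one curve per grouping column.

    ``restrict_timepoints`` first limits samples to the given shared
    timepoints (the cross-species variant).  Groupings with a single
    level are skipped with a warning.
    """
    densities = sorted(densities)
    if any(b <= a for a, b in zip(densities, densities[1:])):
        raise ValueError("densities must be strictly increasing")
    meta = samples.aligned(m.sample_ids).set_index("sample_id")
    if restrict_timepoints is not None:
        keep = meta["timepoint_h"].isin(restrict_timepoints)
        meta = meta.loc[keep]
        m = m.subset_samples(meta.index)
    nets = [build_sample_network(m, d) for d in densities]
    curves = []
    for col in groupings:
        member = meta[col].to_dict()
        if len(set(member.values())) < 2:
            log.warning("grouping %r has a single level; skipped", col)
            continue
        qs = [modularity(net, member, weighted=weighted) for net in nets]
        curves.append(ModularityCurve(grouping=col, densities=[net.density for net in nets], q_values=qs))
    return curves
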