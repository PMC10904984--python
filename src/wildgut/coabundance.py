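"""Co-abundance network analysis and keystone-taxon identification.

The abundance table is filtered to well-detected SGBs, pairwise Kendall
tau-b correlations are computed, SGBs are grouped by average-linkage
hierarchical clustering on ``1 - tau``, and a graph over
``|tau|``-thresholded edges supports centrality-based keystone calls: a
keystone taxon jointly shows high closeness, betweenness, degree and mean
abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .community import two_group_test
from .types import AbundanceTable, ValidationError

logger = logging.getLogger("wildgut")

__all__ = [
    "KeystoneCall",
    "abundance_filter",
    "kendall_tau_matrix",
    "cluster_sgbs",
    "build_graph",
    "centralities",
    "keystone_call",
    "cluster_cumulative_abundance",
]


@dataclass(frozen=True)
class KeystoneCall:
    sgb_id: str
    closeness: float
    betweenness: float
    degree: int
    mean_abundance: float
    is_keystone: bool


def abundance_filter(table: AbundanceTable, min_gcpm: float = 10.0,
                     min_samples: int = 2) -> AbundanceTable:
    """Keep SGBs with abundance >= ``min_gcpm`` in >= ``min_samples`` samples."""
    keep = (table.values >= min_gcpm).sum(axis=1) >= min_samples
    return AbundanceTable(
        [s for s, k in zip(table.sgb_ids, keep) if k],
        table.samples,
        table.values[keep],
    )


def kendall_tau_matrix(table: AbundanceTable) -> pd.DataFrame:
    """Pairwise Kendall tau-b (tie-corrected) between SGB abundance profiles.

    SGBs constant across samples have undefined tau; those entries are
    recorded as 0 with a warning.  The diagonal is 1.
    """
    if len(table.samples) < 3:
        raise ValidationError("Kendall correlation needs at least 3 samples")
    n = len(table.sgb_ids)
    constant = [i for i in range(n) if np.ptp(table.values[i]) == 0]
    if constant:
        logger.warning(
            "%d constant SGBs have undefined tau; recording 0", len(constant)
        )
    const = set(constant)
    tau = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if i in const or j in const:
                t = 0.0
            else:
                t = stats.kendalltau(table.values[i], table.values[j]).statistic
                if not np.isfinite(t):
                    t = 0.0
            tau[i, j] = tau[j, i] = t
    return pd.DataFrame(tau, index=table.sgb_ids, columns=table.sgb_ids)


def cluster_sgbs(tau: pd.DataFrame, n_clusters: int | None = 7,
                 cut_height: float | None = None) -> pd.Series:
    """Average-linkage hierarchical clustering of SGBs on distance 1 - tau.

    Cut either to ``n_clusters`` groups (default 7) or at ``cut_height``.
    Input order does not affect the partition: rows are sorted by SGB id
    before linkage so ties resolve deterministically.
    """
    if (n_clusters is None) == (cut_height is None):
        raise ValidationError("specify exactly one of n_clusters or cut_height")
    order = sorted(tau.index)
    t = tau.loc[order, order].to_numpy(float)
    dist = 1.0 - t
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    if len(order) == 1:
        return pd.Series([1], index=order, name="cluster")
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    if n_clusters is not None:
        labels = hierarchy.fcluster(z, t=min(n_clusters, len(order)),
                                    criterion="maxclust")
    else:
        labels = hierarchy.fcluster(z, t=cut_height, criterion="distance")
    # renumber clusters in order of first appearance for determinism
    remap: dict[int, int] = {}
    out = []
    for lbl in labels:
        if lbl not in remap:
            remap[lbl] = len(remap) + 1
        out.append(remap[lbl])
    return pd.Series(out, index=order, name="cluster")


def build_graph(tau: pd.DataFrame, abs_tau_min: float = 0.3) -> list[tuple[str, str, int]]:
    """Edges ``(i, j, sign)`` for SGB pairs with ``|tau| >= abs_tau_min``."""
    edges = []
    ids = list(tau.index)
    t = tau.to_numpy(float)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if abs(t[i, j]) >= abs_tau_min:
                edges.append((ids[i], ids[j], 1 if t[i, j] > 0 else -1))
    return edges


def centralities(edges, nodes) -> pd.DataFrame:
    """Closeness, betweenness and degree for each node of the co-abundance graph.

    Edge signs are ignored: topology uses the undirected |tau|-thresholded
    graph.  Closeness uses the Wasserman-Faust component-size correction
    ``(n_comp - 1) / (n - 1)``; betweenness is normalized by
    ``(n - 1)(n - 2) / 2``; isolated nodes get closeness 0.
    """
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from((a, b) for a, b, _sign in edges)
    clo = nx.closeness_centrality(g, wf_improved=True)
    bet = nx.betweenness_centrality(g, normalized=True)
    return pd.DataFrame(
        {
            "closeness": [clo[n] for n in nodes],
            "betweenness": [bet[n] for n in nodes],
            "degree": [g.degree(n) for n in nodes],
        },
        index=list(nodes),
    )


def keystone_call(cent: pd.DataFrame, table: AbundanceTable, c_min: float = 0.45,
                  b_min: float = 0.02, d_min: int = 20,
                  a_min: float = 50.0) -> list[KeystoneCall]:
    """Call keystone taxa from centralities plus an abundance gate.

    Keystone iff closeness >= ``c_min`` and betweenness >= ``b_min`` and
    degree >= ``d_min`` and mean abundance > ``a_min`` gcpm (the abundance
    gate is strict).
    """
    mean_ab = dict(zip(table.sgb_ids, table.values.mean(axis=1)))
    missing = [n for n in cent.index if n not in mean_ab]
    if missing:
        raise ValidationError(f"nodes missing from abundance table: {missing[:5]}")
    calls = []
    for sgb in cent.index:
        row = cent.loc[sgb]
        ab = float(mean_ab[sgb])
        calls.append(
            KeystoneCall(
                sgb_id=sgb,
                closeness=float(row["closeness"]),
                betweenness=float(row["betweenness"]),
                degree=int(row["degree"]),
                mean_abundance=ab,
                is_keystone=bool(
                    row["closeness"] >= c_min
                    and row["betweenness"] >= b_min
                    and row["degree"] >= d_min
                    and ab > a_min
                ),
            )
        )
    return calls


def cluster_cumulative_abundance(table: AbundanceTable, clusters: pd.Series):
    """Per-sample cumulative abundance of each SGB cluster plus group tests.

    Returns ``(sums, tests)`` where ``sums`` is a (cluster x sample)
    DataFrame of summed gcpm and ``tests`` holds pairwise two-group
    rank-test p-values per cluster.  Cluster sums conserve the per-sample
    total abundance.
    """
    if clusters.empty:
        raise ValidationError("empty cluster assignment")
    unknown = [s for s in clusters.index if s not in set(table.sgb_ids)]
    if unknown:
        raise ValidationError(f"cluster SGBs absent from table: {unknown[:5]}")
    frame = table.to_frame()
    sums = frame.loc[clusters.index].groupby(clusters).sum()
    if (sums.index.value_counts() == 0).any():
        raise ValidationError("empty cluster")
    group_cols = table.group_columns()
    group_names = sorted(group_cols)
    rows = []
    for cluster_id, row in sums.iterrows():
        vals = row.to_numpy(float)
        for i, g1 in enumerate(group_names):
            for g2 in group_names[i + 1:]:
                p = two_group_test(vals[group_cols[g1]], vals[group_cols[g2]])
                rows.append(
                    {"cluster": cluster_id, "group_a": g1, "group_b": g2, "p_value": p}
                )
    return sums, pd.DataFrame(rows)
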