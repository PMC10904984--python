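"""Community-level statistics: UniFrac, PCoA, PERMANOVA, per-SGB tests.

Distances between samples are phylogeny-aware UniFrac distances over the
SGB tree; ordination is classical principal-coordinates analysis; group
separation is tested with a permutational pseudo-F (PERMANOVA, Anderson's
formulation); per-SGB differential abundance uses Kruskal-Wallis with
Benjamini-Hochberg correction across SGBs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import AbundanceTable, DistanceMatrix, PhyloTree, ValidationError

logger = logging.getLogger("wildgut")

__all__ = [
    "OrdinationResult",
    "GroupTestResult",
    "unifrac",
    "pcoa",
    "permanova",
    "kruskal_wallis_per_sgb",
    "bh_adjust",
    "two_group_test",
]


@dataclass
class OrdinationResult:
    """Principal-coordinates embedding: samples x axes, eigenvalues per axis.

    ``eigenvalues`` includes the full spectrum (negative values reported);
    ``coordinates`` spans only the axes with positive eigenvalues, ordered
    by non-increasing eigenvalue, and is column-centered.
    """

    sample_ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def proportion_explained(self) -> np.ndarray:
        pos = self.eigenvalues[: self.n_axes]
        total = self.eigenvalues[self.eigenvalues > 0].sum()
        return pos / total if total > 0 else pos * 0.0


@dataclass(frozen=True)
class GroupTestResult:
    """Per-SGB group test: statistic, raw p, BH-adjusted q."""

    sgb_id: str
    statistic: float
    p_value: float
    q_value: float


def _edge_leaf_matrix(tree: PhyloTree, leaf_order: list[str]):
    """Branch lengths and leaf-membership indicators for every edge.

    Returns ``(lengths, membership)`` where ``membership[e, l]`` is 1 when
    leaf ``l`` descends through edge ``e``.
    """
    index = {name: i for i, name in enumerate(leaf_order)}
    lengths = []
    rows = []
    n = len(leaf_order)
    masks: dict[int, np.ndarray] = {}
    for node in tree.tree.postorder(include_self=True):
        if node.is_tip():
            mask = np.zeros(n, dtype=bool)
            mask[index[node.name]] = True
        else:
            mask = np.zeros(n, dtype=bool)
            for child in node.children:
                mask |= masks[id(child)]
        masks[id(node)] = mask
        if node.parent is not None:  # the root has no edge above it
            lengths.append(node.length)
            rows.append(mask)
    return np.asarray(lengths, dtype=float), np.asarray(rows)


def unifrac(table: AbundanceTable, tree: PhyloTree, weighted: bool = False) -> DistanceMatrix:
    """Pairwise UniFrac distances between samples.

    Unweighted: branch length unique to one sample's presence set divided by
    branch length covered by either sample.  Weighted (normalized variant):
    ``sum_b len(b) * |p_A(b) - p_B(b)| / sum_b len(b) * (p_A(b) + p_B(b))``
    with ``p`` the branch-subtended relative abundance, so both variants lie
    in [0, 1].
    """
    present = np.asarray(table.values).sum(axis=1) > 0
    leafset = set(tree.leaf_labels)
    abundant_missing = [
        s for s, keep in zip(table.sgb_ids, present) if keep and s not in leafset
    ]
    if abundant_missing:
        raise ValidationError(
            f"SGBs with nonzero abundance missing from tree: {abundant_missing[:5]}"
        )
    lengths, membership = _edge_leaf_matrix(tree, tree.leaf_labels)
    # map table rows onto the tree's leaf order; absent leaves get 0
    leaf_values = np.zeros((len(tree.leaf_labels), len(table.samples)))
    row_of = {s: i for i, s in enumerate(table.sgb_ids)}
    for i, name in enumerate(tree.leaf_labels):
        if name in row_of:
            leaf_values[i] = table.values[row_of[name]]

    n = len(table.samples)
    d = np.zeros((n, n))
    if weighted:
        totals = leaf_values.sum(axis=0)
        rel = np.divide(leaf_values, totals, where=totals > 0,
                        out=np.zeros_like(leaf_values))
        edge_w = membership.astype(float) @ rel  # branch-subtended proportions
        for a in range(n):
            for b in range(a + 1, n):
                num = float(lengths @ np.abs(edge_w[:, a] - edge_w[:, b]))
                den = float(lengths @ (edge_w[:, a] + edge_w[:, b]))
                d[a, b] = d[b, a] = num / den if den > 0 else 0.0
    else:
        edge_present = (membership @ (leaf_values > 0)) > 0
        for a in range(n):
            for b in range(a + 1, n):
                either = edge_present[:, a] | edge_present[:, b]
                unique = edge_present[:, a] ^ edge_present[:, b]
                den = float(lengths @ either)
                d[a, b] = d[b, a] = float(lengths @ unique) / den if den > 0 else 0.0
    return DistanceMatrix(table.sample_ids, d)


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical scaling (principal coordinates) of a distance matrix.

    Eigendecomposition of the double-centered squared-distance matrix;
    axes with non-positive eigenvalues are dropped from the coordinates but
    their eigenvalues are still reported.
    """
    dm = d.d
    n = dm.shape[0]
    sq = dm ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ sq @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(eigvals[0]), 1.0)) if n else 0.0
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    if n_axes is not None:
        if n_axes > coords.shape[1]:
            logger.warning(
                "requested %d axes but only %d have positive eigenvalues",
                n_axes, coords.shape[1],
            )
        coords = coords[:, :n_axes]
    return OrdinationResult(list(d.ids), coords, eigvals)


def _permanova_f(sq: np.ndarray, labels: np.ndarray, n_groups: int) -> float:
    """Pseudo-F from the squared distance matrix and integer group labels."""
    n = sq.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = sq[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.where(labels == g)[0]
        if len(idx) > 1:
            sub = sq[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        raise ValidationError("within-group sum of squares is zero; pseudo-F undefined")
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(d: DistanceMatrix, groups: list[str], n_perm: int = 999,
              seed: int = 0) -> tuple[float, float]:
    """Permutational pseudo-F test of group location differences.

    Returns ``(pseudo_F, p_value)`` with the +1-corrected permutation
    p-value ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``; at ``n_perm = 999``
    the smallest attainable p is 0.001.
    """
    if len(groups) != len(d.ids):
        raise ValidationError("one group label per sample required")
    uniq = sorted(set(groups))
    if len(uniq) < 2:
        raise ValidationError("PERMANOVA needs at least two groups")
    labels = np.asarray([uniq.index(g) for g in groups])
    counts = np.bincount(labels)
    if counts.min() < 2:
        raise ValidationError("every group needs at least two samples")
    sq = d.d ** 2
    f_obs = _permanova_f(sq, labels, len(uniq))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _permanova_f(sq, perm, len(uniq)) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return f_obs, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def kruskal_wallis_per_sgb(table: AbundanceTable) -> list[GroupTestResult]:
    """Kruskal-Wallis H test of each SGB's abundance across sample groups.

    Tie-corrected H with a chi-square p on k-1 degrees of freedom; SGBs
    constant across all samples get p = 1 by convention.  q-values are BH
    adjusted over all tested SGBs.  With exactly two groups the ranking is
    equivalent to a Wilcoxon rank-sum test.
    """
    group_cols = table.group_columns()
    if len(group_cols) < 2:
        raise ValidationError("need at least two groups")
    stats_p = []
    for row in table.values:
        samples = [row[idx] for idx in group_cols.values()]
        if np.ptp(row) == 0:
            stats_p.append((0.0, 1.0))
            continue
        h, p = stats.kruskal(*samples)
        stats_p.append((float(h), float(p)))
    q = bh_adjust([p for _, p in stats_p])
    return [
        GroupTestResult(sgb, h, p, float(qv))
        for sgb, (h, p), qv in zip(table.sgb_ids, stats_p, q)
    ]


def two_group_test(x, y) -> float:
    """Two-group rank test p-value (two-group Kruskal-Wallis with ties).

    Equivalent in ranking to the Wilcoxon rank-sum test; used for pairwise
    group comparisons of cluster and module cumulative abundances.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    return float(stats.kruskal(x, y).pvalue)
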