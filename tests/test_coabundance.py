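import itertools

import numpy as np
import pandas as pd
import pytest

from wildgut import (
    AbundanceTable,
    abundance_filter,
    build_graph,
    centralities,
    cluster_cumulative_abundance,
    cluster_sgbs,
    kendall_tau_matrix,
    keystone_call,
)
from wildgut.types import ValidationError
from conftest import make_samples, random_table


def tau_b_oracle(x, y):
    """Tie-corrected Kendall tau-b by direct pair counting."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            continue
        if dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2

    def pair_ties(v):
        return sum(
            c * (c - 1) / 2 for c in np.unique(v, return_counts=True)[1]
        )

    denom = np.sqrt((n0 - pair_ties(x)) * (n0 - pair_ties(y)))
    return (conc - disc) / denom if denom > 0 else 0.0


def brute_force_centralities(nodes, edges):
    """All-pairs shortest paths by simple-path enumeration (small graphs)."""
    adj = {n: set() for n in nodes}
    for a, b, _ in edges:
        adj[a].add(b)
        adj[b].add(a)

    def all_simple_paths(s, t):
        paths, stack = [], [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                paths.append(path)
                continue
            for w in adj[v]:
                if w not in path:
                    stack.append((w, path + [w]))
        return paths

    n = len(nodes)
    sp_len = {}
    sp_all = {}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_simple_paths(s, t)
        if paths:
            m = min(len(p) - 1 for p in paths)
            sp_len[(s, t)] = sp_len[(t, s)] = m
            shortest = [p for p in paths if len(p) - 1 == m]
            sp_all[(s, t)] = sp_all[(t, s)] = shortest
    out = {}
    for v in nodes:
        reach = [u for u in nodes if u != v and (v, u) in sp_len]
        if reach:
            total = sum(sp_len[(v, u)] for u in reach)
            clo = len(reach) / total * (len(reach) / (n - 1))
        else:
            clo = 0.0
        bet = 0.0
        for s, t in itertools.combinations([u for u in nodes if u != v], 2):
            if (s, t) not in sp_all:
                continue
            through = sum(1 for p in sp_all[(s, t)] if v in p)
            bet += through / len(sp_all[(s, t)])
        bet /= (n - 1) * (n - 2) / 2 if n > 2 else 1
        out[v] = (clo, bet, len(adj[v]))
    return out


class TestAbundanceFilter:
    def test_threshold_rule(self):
        table = AbundanceTable(
            ["keep", "drop"],
            make_samples(["g1", "g1", "g2"]),
            [[12.0, 11.0, 0.0], [12.0, 0.0, 0.0]],
        )
        out = abundance_filter(table)
        assert out.sgb_ids == ["keep"]

    def test_matches_direct_predicate_scan(self, rng):
        table = random_table(rng, 20, ["g1"] * 5 + ["g2"] * 5, zero_frac=0.5)
        out = abundance_filter(table, min_gcpm=10, min_samples=2)
        expected = [
            s for s, row in zip(table.sgb_ids, table.values)
            if (row >= 10).sum() >= 2
        ]
        assert out.sgb_ids == expected


class TestKendallTau:
    def test_perfect_agreement_and_reversal(self):
        table = AbundanceTable(
            ["a", "b", "c"],
            make_samples(["g1", "g1", "g2"]),
            [[1, 2, 3], [1, 2, 3], [3, 2, 1]],
        )
        tau = kendall_tau_matrix(table)
        assert tau.loc["a", "b"] == pytest.approx(1.0)
        assert tau.loc["a", "c"] == pytest.approx(-1.0)

    def test_one_discordant_pair(self):
        table = AbundanceTable(
            ["a", "b"], make_samples(["g1", "g1", "g2"]), [[1, 2, 3], [1, 3, 2]]
        )
        assert kendall_tau_matrix(table).loc["a", "b"] == pytest.approx(1 / 3)

    def test_constant_sgb_recorded_as_zero(self):
        table = AbundanceTable(
            ["a", "b"], make_samples(["g1", "g1", "g2"]), [[1, 2, 3], [5, 5, 5]]
        )
        assert kendall_tau_matrix(table).loc["a", "b"] == 0.0

    def test_matches_pair_counting_oracle_with_ties(self, rng):
        n = 10
        values = rng.integers(0, 5, size=(6, n)).astype(float)
        values[0] += rng.random(n)  # mix tied and untied profiles
        table = AbundanceTable(
            [f"s{i}" for i in range(6)], make_samples(["g"] * n), values
        )
        tau = kendall_tau_matrix(table)
        for i, j in itertools.combinations(range(6), 2):
            assert tau.iloc[i, j] == pytest.approx(
                tau_b_oracle(values[i], values[j]), abs=1e-12
            )


class TestClustering:
    def _block_table(self, rng):
        base1 = np.arange(1.0, 11.0)
        base2 = base1[::-1].copy()
        rows = [base1 + rng.normal(0, 0.01, 10) for _ in range(3)]
        rows += [base2 + rng.normal(0, 0.01, 10) for _ in range(3)]
        return AbundanceTable(
            [f"s{i}" for i in range(6)], make_samples(["g"] * 10), np.array(rows)
        )

    def test_planted_two_block_partition_recovered(self, rng):
        tau = kendall_tau_matrix(self._block_table(rng))
        clusters = cluster_sgbs(tau, n_clusters=2)
        assert set(clusters.iloc[:3]) != set(clusters.iloc[3:])
        assert clusters.iloc[:3].nunique() == 1 and clusters.iloc[3:].nunique() == 1

    def test_n_clusters_equal_n_gives_singletons(self, rng):
        tau = kendall_tau_matrix(self._block_table(rng))
        clusters = cluster_sgbs(tau, n_clusters=6)
        assert clusters.nunique() == 6

    def test_partition_invariant_to_input_order(self, rng):
        tau = kendall_tau_matrix(self._block_table(rng))
        perm = list(tau.index)[::-1]
        c1 = cluster_sgbs(tau, n_clusters=3)
        c2 = cluster_sgbs(tau.loc[perm, perm], n_clusters=3)
        # same partition up to cluster relabeling
        for a, b in itertools.combinations(tau.index, 2):
            assert (c1[a] == c1[b]) == (c2[a] == c2[b])


class TestGraphAndCentralities:
    def test_edge_thresholding(self):
        tau = pd.DataFrame(
            [[1.0, 0.6, -0.7, 0.1],
             [0.6, 1.0, 0.2, 0.0],
             [-0.7, 0.2, 1.0, 0.4],
             [0.1, 0.0, 0.4, 1.0]],
            index=list("abcd"), columns=list("abcd"),
        )
        assert build_graph(tau, 1.01) == []
        assert len(build_graph(tau, 0.0)) == 6
        assert build_graph(tau, 0.5) == [("a", "b", 1), ("a", "c", -1)]

    def test_star_graph_closed_form(self):
        edges = [("hub", "a", 1), ("hub", "b", 1), ("hub", "c", -1)]
        cent = centralities(edges, ["hub", "a", "b", "c"])
        assert cent.loc["hub", "degree"] == 3
        assert cent.loc["hub", "closeness"] == pytest.approx(1.0)
        assert cent.loc["hub", "betweenness"] == pytest.approx(1.0)

    def test_path_middle_node_betweenness(self):
        cent = centralities([("a", "m", 1), ("m", "b", 1)], ["a", "m", "b"])
        assert cent.loc["m", "betweenness"] == pytest.approx(1.0)

    def test_isolated_node_conventions(self):
        cent = centralities([("a", "b", 1)], ["a", "b", "lone"])
        assert cent.loc["lone", "degree"] == 0
        assert cent.loc["lone", "closeness"] == 0.0

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 9))
            nodes = [f"n{i}" for i in range(n)]
            edges = [
                (a, b, 1)
                for a, b in itertools.combinations(nodes, 2)
                if rng.random() < 0.4
            ]
            cent = centralities(edges, nodes)
            ref = brute_force_centralities(nodes, edges)
            for v in nodes:
                clo, bet, deg = ref[v]
                assert cent.loc[v, "closeness"] == pytest.approx(clo, abs=1e-9)
                assert cent.loc[v, "betweenness"] == pytest.approx(bet, abs=1e-9)
                assert cent.loc[v, "degree"] == deg


class TestKeystoneCall:
    def _table(self, abundances):
        sgbs = list(abundances)
        vals = np.array([[a, a] for a in abundances.values()], float)
        return AbundanceTable(sgbs, make_samples(["g1", "g2"]), vals)

    def test_reported_centrality_profile_is_keystone(self):
        # closeness 0.50, betweenness 0.03, degree 29, abundance 60
        cent = pd.DataFrame(
            {"closeness": [0.50], "betweenness": [0.03], "degree": [29]}, index=["k"]
        )
        (call,) = keystone_call(cent, self._table({"k": 60.0}),
                                c_min=0.45, b_min=0.02, d_min=20, a_min=50)
        assert call.is_keystone

    def test_low_abundance_fails_the_gate(self):
        cent = pd.DataFrame(
            {"closeness": [0.9], "betweenness": [0.9], "degree": [99]}, index=["k"]
        )
        (call,) = keystone_call(cent, self._table({"k": 10.0}))
        assert not call.is_keystone

    def test_zero_thresholds_make_every_abundant_node_keystone(self):
        cent = pd.DataFrame(
            {"closeness": [0.0, 0.2], "betweenness": [0.0, 0.1], "degree": [0, 1]},
            index=["a", "b"],
        )
        calls = keystone_call(cent, self._table({"a": 5.0, "b": 9.0}),
                              c_min=0, b_min=0, d_min=0, a_min=0)
        assert all(c.is_keystone for c in calls)


class TestClusterCumulativeAbundance:
    def test_single_cluster_conserves_column_totals(self, three_group_table):
        clusters = pd.Series(1, index=three_group_table.sgb_ids)
        sums, _ = cluster_cumulative_abundance(three_group_table, clusters)
        np.testing.assert_allclose(
            sums.loc[1].to_numpy(), three_group_table.values.sum(axis=0)
        )

    def test_cluster_sums_partition_total(self, three_group_table):
        clusters = pd.Series(
            [1 + i % 3 for i in range(len(three_group_table.sgb_ids))],
            index=three_group_table.sgb_ids,
        )
        sums, tests = cluster_cumulative_abundance(three_group_table, clusters)
        np.testing.assert_allclose(
            sums.sum(axis=0).to_numpy(), three_group_table.values.sum(axis=0)
        )
        assert set(tests.columns) == {"cluster", "group_a", "group_b", "p_value"}

    def test_planted_abundant_cluster_is_significant(self):
        rng = np.random.default_rng(0)
        groups = ["g1"] * 8 + ["g2"] * 8
        vals = rng.lognormal(1, 0.3, size=(6, 16))
        vals[:3, :8] *= 50  # cluster 1 strongly elevated in g1
        table = AbundanceTable(
            [f"s{i}" for i in range(6)], make_samples(groups), vals
        )
        clusters = pd.Series([1, 1, 1, 2, 2, 2], index=table.sgb_ids)
        _, tests = cluster_cumulative_abundance(table, clusters)
        p = tests[(tests.cluster == 1)].p_value.iloc[0]
        assert p < 0.01

    def test_empty_assignment_rejected(self, three_group_table):
        with pytest.raises(ValidationError):
            cluster_cumulative_abundance(three_group_table, pd.Series(dtype=int))
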