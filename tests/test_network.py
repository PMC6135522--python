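"""Network construction and the nine parameters against definitional oracles."""

import itertools

import numpy as np
import pytest

from flysoc.interaction import TouchInteraction
from flysoc.network import (
    SocialNetwork,
    betweenness_centrality,
    build_adjacency,
    clustering_coefficient,
    degrees,
    global_metrics,
    network_parameters,
    relabel_by_outgoing,
)


def _random_net(rng, n=6, density=0.5):
    # power-of-two counts keep 1/weight exactly representable, so
    # shortest-path ties are exact floats in both implementation and oracle
    counts = np.where(rng.random((n, n)) < density,
                      2 ** rng.integers(0, 4, (n, n)), 0)
    np.fill_diagonal(counts, 0)
    return SocialNetwork(counts.astype(int))


def _worked_example_net():
    """Sample network: X1 -> {X2..X6}; {X2, X3, X5} -> X1."""
    events = [TouchInteraction(1, j, 0, 20) for j in (2, 3, 4, 5, 6)]
    events += [TouchInteraction(i, 1, 100 * i, 100 * i + 20) for i in (2, 3, 5)]
    return build_adjacency(events, 6)


# ---------------------------------------------------------------------------
# brute-force oracles (independent definitional loops)
# ---------------------------------------------------------------------------

def oracle_clustering(net):
    w_hat = np.cbrt(net.weights)
    a = (net.counts > 0).astype(int)
    n = net.n
    out = np.zeros(n)
    for i in range(n):
        num = 0.0
        for j in range(n):
            for k in range(n):
                if len({i, j, k}) < 3:
                    continue
                num += (
                    (w_hat[i, j] + w_hat[j, i])
                    * (w_hat[j, k] + w_hat[k, j])
                    * (w_hat[k, i] + w_hat[i, k])
                )
        d_tot = a[:, i].sum() + a[i, :].sum()
        d_bi = sum(a[i, j] and a[j, i] for j in range(n))
        # num equals [(W-hat + W-hat^T)^3]_ii: terms with j or k equal to i
        # vanish because the symmetrized matrix has a zero diagonal
        denom = 2.0 * (d_tot * (d_tot - 1) - 2 * d_bi)
        out[i] = num / denom if denom > 0 else 0.0
    return out


def _all_simple_paths(n, s, t):
    others = [v for v in range(n) if v not in (s, t)]
    for k in range(len(others) + 1):
        for mid in itertools.permutations(others, k):
            yield (s, *mid, t)


def oracle_shortest_paths(net):
    """For each ordered pair: (min length, count of minimal paths,
    through-counts per interior node), by exhaustive path enumeration."""
    w = net.weights
    n = net.n
    res = {}
    for s, t in itertools.permutations(range(n), 2):
        best, paths = np.inf, []
        for path in _all_simple_paths(n, s, t):
            ln = 0.0
            for u, v in zip(path, path[1:]):
                if w[u, v] == 0:
                    ln = np.inf
                    break
                ln += 1.0 / w[u, v]
            if ln < best - 1e-12:
                best, paths = ln, [path]
            elif np.isfinite(ln) and abs(ln - best) <= 1e-12:
                paths.append(path)
        res[(s, t)] = (best, paths)
    return res


def oracle_betweenness(net):
    sp = oracle_shortest_paths(net)
    n = net.n
    bc = np.zeros(n)
    for (s, t), (best, paths) in sp.items():
        if not np.isfinite(best) or not paths:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(v in p for p in paths)
            bc[v] += through / len(paths)
    norm = (n - 1) * (n - 2)
    return bc / norm if norm > 0 else bc


def oracle_global_efficiency(net):
    sp = oracle_shortest_paths(net)
    n = net.n
    acc = sum(1.0 / best for best, _ in sp.values() if np.isfinite(best) and best > 0)
    return acc / (n * (n - 1))


def oracle_transitivity(net):
    a = (net.counts > 0).astype(int)
    n = net.n
    closed = 0.0
    for i, j, k in itertools.product(range(n), repeat=3):
        if len({i, j, k}) < 3:
            continue
        closed += (a[i, j] + a[j, i]) * (a[j, k] + a[k, j]) * (a[k, i] + a[i, k])
    closed /= 2.0
    total = 0.0
    for i in range(n):
        d_tot = a[:, i].sum() + a[i, :].sum()
        d_bi = sum(a[i, j] and a[j, i] for j in range(n))
        total += d_tot * (d_tot - 1) - 2 * d_bi
    return closed / total if total > 0 else 0.0


def oracle_assortativity(net):
    a = (net.counts > 0).astype(int)
    d_tot = a.sum(axis=0) + a.sum(axis=1)
    xs, ys = [], []
    for i, j in zip(*np.nonzero(a)):
        xs.append(d_tot[i])
        ys.append(d_tot[j])
    xs, ys = np.array(xs, float), np.array(ys, float)
    if len(xs) < 2 or xs.std() == 0 or ys.std() == 0:
        return np.nan
    return float(np.corrcoef(xs, ys)[0, 1])


# ---------------------------------------------------------------------------
# adjacency construction
# ---------------------------------------------------------------------------

class TestBuildAdjacency:
    def test_empty_event_list_zero_matrix(self):
        net = build_adjacency([], 5)
        assert net.counts.sum() == 0

    def test_repeat_interactions_accumulate(self):
        events = [TouchInteraction(1, 2, 0, 20), TouchInteraction(1, 2, 50, 70)]
        net = build_adjacency(events, 6)
        assert net.counts[0, 1] == 2

    def test_matches_direct_tally(self, rng):
        n = 6
        events = []
        for _ in range(60):
            i, j = rng.choice(n, 2, replace=False) + 1
            events.append(TouchInteraction(int(i), int(j), 0, 20))
        net = build_adjacency(events, n)
        tally = np.zeros((n, n), dtype=int)
        for ev in events:
            tally[ev.interactor_id - 1, ev.interacted_id - 1] += 1
        assert np.array_equal(net.counts, tally)

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            build_adjacency([TouchInteraction(2, 2, 0, 20)], 4)

    def test_out_of_range_id_rejected(self):
        with pytest.raises(ValueError):
            build_adjacency([TouchInteraction(1, 7, 0, 20)], 6)

    def test_nonzero_diagonal_rejected(self):
        counts = np.eye(3, dtype=int)
        with pytest.raises(ValueError):
            SocialNetwork(counts)


class TestDegrees:
    def test_worked_example_out_degree_5_in_degree_3(self):
        table = degrees(_worked_example_net()).set_index("fly_id")
        assert table.loc[1, "out_degree"] == 5
        assert table.loc[1, "in_degree"] == 3
        assert table.loc[1, "degree"] == 8

    def test_degree_is_in_plus_out(self, rng):
        for _ in range(10):
            table = degrees(_random_net(rng))
            assert (table["degree"] ==
                    table["in_degree"] + table["out_degree"]).all()

    def test_zero_matrix_all_zero(self):
        table = degrees(SocialNetwork(np.zeros((4, 4), dtype=int)))
        assert (table.drop(columns="fly_id") == 0).all().all()

    def test_weighted_degrees_use_normalized_weights(self):
        net = _worked_example_net()
        table = degrees(net).set_index("fly_id")
        w = net.weights
        assert table.loc[1, "weighted_out_degree"] == pytest.approx(w[0].sum())
        assert table.loc[1, "weighted_in_degree"] == pytest.approx(w[:, 0].sum())


class TestClustering:
    def test_complete_unit_digraph_all_one(self):
        n = 5
        counts = np.ones((n, n), dtype=int) - np.eye(n, dtype=int)
        c = clustering_coefficient(SocialNetwork(counts))
        assert np.allclose(c, 1.0)

    def test_three_cycle_matches_enumeration(self):
        counts = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]])
        net = SocialNetwork(counts)
        assert np.allclose(clustering_coefficient(net), oracle_clustering(net))

    def test_random_digraphs_match_oracle(self, rng):
        for _ in range(15):
            net = _random_net(rng)
            assert np.allclose(
                clustering_coefficient(net), oracle_clustering(net), atol=1e-10
            )


class TestBetweenness:
    def test_complete_digraph_all_zero(self):
        counts = np.ones((5, 5), dtype=int) - np.eye(5, dtype=int)
        assert np.allclose(betweenness_centrality(SocialNetwork(counts)), 0.0)

    def test_directed_path_middle_node(self):
        counts = np.array([[0, 1, 0], [0, 0, 1], [0, 0, 0]])
        bc = betweenness_centrality(SocialNetwork(counts))
        # only the (a, c) pair routes through b; 1 / ((n-1)(n-2)) = 0.5
        assert bc[1] == pytest.approx(0.5)
        assert bc[0] == bc[2] == 0.0

    def test_random_digraphs_match_enumeration(self, rng):
        for _ in range(8):
            net = _random_net(rng)
            assert np.allclose(
                betweenness_centrality(net), oracle_betweenness(net), atol=1e-10
            )


class TestGlobalMetrics:
    def test_complete_unit_digraph_closed_forms(self):
        counts = 3 * (np.ones((6, 6), dtype=int) - np.eye(6, dtype=int))
        m = global_metrics(SocialNetwork(counts))
        assert m["density"] == 1.0
        assert m["transitivity"] == pytest.approx(1.0)
        assert m["global_efficiency"] == pytest.approx(1.0)
        assert np.isnan(m["assortativity"])  # zero degree variance

    def test_zero_matrix(self):
        m = global_metrics(SocialNetwork(np.zeros((5, 5), dtype=int)))
        assert m["density"] == 0.0
        assert m["weighted_total_interaction"] == 0.0
        assert m["global_efficiency"] == 0.0

    def test_random_digraphs_match_oracles(self, rng):
        for _ in range(8):
            net = _random_net(rng)
            m = global_metrics(net)
            assert m["global_efficiency"] == pytest.approx(
                oracle_global_efficiency(net), abs=1e-10)
            assert m["transitivity"] == pytest.approx(
                oracle_transitivity(net), abs=1e-10)
            a = (net.counts > 0).sum()
            assert m["density"] == pytest.approx(a / (net.n * (net.n - 1)))
            assert m["weighted_total_interaction"] == pytest.approx(
                net.weights.sum())
            expected_assort = oracle_assortativity(net)
            if np.isnan(expected_assort):
                assert np.isnan(m["assortativity"])
            else:
                assert m["assortativity"] == pytest.approx(expected_assort,
                                                           abs=1e-10)
                assert -1.0 <= m["assortativity"] <= 1.0


class TestRelabel:
    def test_already_sorted_identity(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[1, 0] = 1
        counts[2, 0] = 1
        counts[2, 1] = 2            # ascending out-activity already
        _, perm = relabel_by_outgoing(SocialNetwork(counts))
        assert np.array_equal(perm, np.arange(3))

    def test_swapped_nodes_transposed(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 1] = 5            # node 0 most active
        counts[2, 0] = 1
        relabeled, perm = relabel_by_outgoing(SocialNetwork(counts))
        assert perm[-1] == 0        # most active becomes the last label
        w = relabeled.weights
        assert np.all(np.diff(w.sum(axis=1)) >= 0)

    def test_parameter_multisets_invariant_under_relabeling(self, rng):
        net = _random_net(rng)
        relabeled, perm = relabel_by_outgoing(net)
        per_a, glob_a = network_parameters(net)
        per_b, glob_b = network_parameters(relabeled)
        for col in per_a.columns.drop("fly_id"):
            assert np.allclose(
                np.sort(per_a[col].to_numpy()), np.sort(per_b[col].to_numpy())
            )
        for key, val in glob_a.items():
            if isinstance(val, float) and np.isnan(val):
                assert np.isnan(glob_b[key])
            else:
                assert glob_b[key] == pytest.approx(val)


def test_per_node_parameters_permutation_equivariant(rng):
    net = _random_net(rng)
    perm = rng.permutation(net.n)
    permuted = SocialNetwork(net.counts[np.ix_(perm, perm)])
    per_a, _ = network_parameters(net)
    per_b, _ = network_parameters(permuted)
    for col in per_a.columns.drop("fly_id"):
        assert np.allclose(per_a[col].to_numpy()[perm], per_b[col].to_numpy())
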