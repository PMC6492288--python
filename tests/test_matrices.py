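"""Unit and property tests for the matrix-based graph computations."""

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, strategies as st
from scipy.sparse.csgraph import connected_components as scipy_components

from nmaconnect import (
    EvidenceNetwork,
    InvalidNetworkError,
    RandomNetworkSpec,
    block_sort,
    build_adjacency,
    connected_components,
    cumulative_walks,
    distance_matrix,
    indicator,
    indirect_connection,
    is_connected,
    network_from_edges,
    network_from_studies,
    paper_network,
    random_network,
    summarize,
    walk_counts,
    StudyRecord,
)

import conftest as cf


def random_adjacency(seed: int, n: int, density: float):
    """Seeded Erdős–Rényi-style adjacency for oracle comparisons."""
    rng = np.random.default_rng(seed)
    a = np.zeros((n, n), dtype=np.int64)
    iu = np.triu_indices(n, k=1)
    mask = rng.random(len(iu[0])) < density
    a[iu[0][mask], iu[1][mask]] = 1
    a = a + a.T
    labels = tuple(f"t{i}" for i in range(n))
    pairs = [(labels[i], labels[j]) for i, j in zip(*iu) if a[i, j]]
    return build_adjacency(network_from_edges(pairs, labels=labels))


def nx_graph(adj):
    g = nx.Graph()
    g.add_nodes_from(adj.labels)
    i, j = np.nonzero(np.triu(adj.entries))
    g.add_edges_from((adj.labels[a], adj.labels[b]) for a, b in zip(i, j))
    return g


# ---------------------------------------------------------------------------
# adjacency construction
# ---------------------------------------------------------------------------

def test_adjacency_of_worked_example(figure2):
    adj = build_adjacency(figure2)
    np.testing.assert_array_equal(adj.entries, cf.FIG2_A)


def test_adjacency_no_edges_and_multiarm_clique():
    empty = build_adjacency(network_from_edges([], labels=["a", "b"]))
    np.testing.assert_array_equal(empty.entries, np.zeros((2, 2), dtype=int))

    three_arm = network_from_studies([StudyRecord("s1", ("A", "B", "C"))])
    adj = build_adjacency(three_arm)
    expected = np.ones((3, 3), dtype=int) - np.eye(3, dtype=int)
    np.testing.assert_array_equal(adj.entries, expected)
    assert three_arm.n_edges == 3


def test_duplicate_comparisons_collapse_to_single_edge():
    studies = [StudyRecord("s1", ("A", "B")), StudyRecord("s2", ("A", "B"))]
    adj = build_adjacency(network_from_studies(studies))
    assert adj.entries.max() == 1


def test_invalid_networks_rejected():
    with pytest.raises(InvalidNetworkError):
        EvidenceNetwork(("a", "a"), frozenset())
    with pytest.raises(InvalidNetworkError):
        EvidenceNetwork(("a", "b"), frozenset({frozenset(("a", "c"))}))
    with pytest.raises(InvalidNetworkError):
        network_from_edges([("a", "a")])
    with pytest.raises(InvalidNetworkError):
        StudyRecord("s", ("A", "A"))


# ---------------------------------------------------------------------------
# walk counts
# ---------------------------------------------------------------------------

def test_walk_counts_match_printed_powers(figure2):
    adj = build_adjacency(figure2)
    np.testing.assert_array_equal(walk_counts(adj, 1).entries.astype(int), cf.FIG2_A)
    a2 = walk_counts(adj, 2)
    np.testing.assert_array_equal(a2.entries.astype(int), cf.FIG2_A2)
    # treatment 2 loops back to itself along 2-1-2, 2-3-2 and 2-5-2
    assert a2.entries[1, 1] == 3
    np.testing.assert_array_equal(walk_counts(adj, 3).entries.astype(int), cf.FIG2_A3)


def test_walk_counts_path_graph_brute_force():
    # enumerate 2-walks on the path 1-2-3 by hand: 1-2-3 is the only
    # 2-walk between the ends; the middle vertex has 2 round trips
    adj = build_adjacency(network_from_edges([("1", "2"), ("2", "3")]))
    a2 = walk_counts(adj, 2).entries
    assert a2[0, 2] == 1 and a2[2, 0] == 1
    assert a2[1, 1] == 2


def test_walk_counts_exact_for_large_powers():
    # closed form for complete-graph walk counts: the number of k-walks
    # between two distinct vertices of K_m is ((m-1)^k - (-1)^k) / m
    m, k = 6, 40
    labels = [str(i) for i in range(m)]
    pairs = [(labels[i], labels[j]) for i in range(m) for j in range(i + 1, m)]
    adj = build_adjacency(network_from_edges(pairs, labels=labels))
    ak = walk_counts(adj, k).entries
    off = ((m - 1) ** k - (-1) ** k) // m
    diag = ((m - 1) ** k + (m - 1) * (-1) ** k) // m
    assert off > 2**63  # exceeds fixed-width integers: exactness matters
    assert all(ak[i, j] == off for i in range(m) for j in range(m) if i != j)
    assert all(ak[i, i] == diag for i in range(m))


def test_walk_counts_rejects_bad_power(figure2):
    adj = build_adjacency(figure2)
    with pytest.raises(ValueError):
        walk_counts(adj, 0)
    with pytest.raises(ValueError):
        cumulative_walks(adj, 0)


def test_cumulative_walks_single_edge():
    adj = build_adjacency(network_from_edges([("1", "2")]))
    c2 = cumulative_walks(adj, 2).entries
    np.testing.assert_array_equal(c2.astype(int), np.array([[1, 1], [1, 1]]))
    c1 = cumulative_walks(adj, 1).entries
    np.testing.assert_array_equal(c1.astype(int), adj.entries)


def test_indicator_operator(figure2):
    adj = build_adjacency(figure2)
    np.testing.assert_array_equal(indicator(cumulative_walks(adj, 3)), cf.FIG2_IC3)
    np.testing.assert_array_equal(indicator(cumulative_walks(adj, 7)), cf.FIG2_IC7)
    assert indicator(np.zeros((3, 3))).sum() == 0
    assert indicator(np.array([[0, 4020], [4020, 0]])).tolist() == [[0, 1], [1, 0]]


# ---------------------------------------------------------------------------
# reachability, components, connectedness
# ---------------------------------------------------------------------------

def test_indirect_connection_worked_example(figure2):
    icm = indirect_connection(build_adjacency(figure2))
    np.testing.assert_array_equal(icm.entries, cf.FIG2_IC7)


def test_indirect_connection_network1(network1):
    adj = build_adjacency(network1)
    np.testing.assert_array_equal(adj.entries, cf.NET1_A)
    np.testing.assert_array_equal(indirect_connection(adj).entries, cf.NET1_ICM)


def test_indirect_connection_complete_graph():
    labels = list("abcd")
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    icm = indirect_connection(build_adjacency(network_from_edges(pairs)))
    np.testing.assert_array_equal(icm.entries, np.ones((4, 4), dtype=int))


def test_isolated_vertex_diagonal_is_one():
    net = network_from_edges([("a", "b")], labels=["a", "b", "c"])
    icm = indirect_connection(build_adjacency(net))
    assert icm.entries[2, 2] == 1  # isolated treatment still "connected" to itself


@given(seed=st.integers(0, 10**6), n=st.integers(1, 12),
       density=st.sampled_from([0.0, 0.15, 0.4, 1.0]))
def test_power_sum_route_equals_boolean_recurrence(seed, n, density):
    """I(C_{n-1}) computed from exact integer powers equals the boolean route."""
    adj = random_adjacency(seed, n, density)
    icm = indirect_connection(adj).entries
    if n == 1:
        np.testing.assert_array_equal(icm, np.eye(1, dtype=int))
        return
    via_powers = indicator(cumulative_walks(adj, n - 1))
    np.fill_diagonal(via_powers, 1)
    np.testing.assert_array_equal(icm, via_powers)


@given(seed=st.integers(0, 10**6), n=st.integers(1, 12),
       density=st.sampled_from([0.0, 0.2, 0.5]))
def test_stabilization_beyond_n_minus_1(seed, n, density):
    """Cumulative walk indicators stop changing at l = n-1."""
    adj = random_adjacency(seed, n, density)
    if n == 1:
        return
    at_limit = indicator(cumulative_walks(adj, n - 1))
    np.fill_diagonal(at_limit, 1)  # closed walks appear only at even lengths
    for extra in (0, 1, 3):
        later = indicator(cumulative_walks(adj, n - 1 + extra))
        np.fill_diagonal(later, 1)
        np.testing.assert_array_equal(later, at_limit)


def test_is_connected(figure2, network1, network2):
    assert not is_connected(build_adjacency(figure2))
    assert not is_connected(build_adjacency(network1))
    assert is_connected(build_adjacency(network2))
    single = build_adjacency(network_from_edges([], labels=["only"]))
    assert is_connected(single)


def test_components_ordering(network1, network3):
    parts = connected_components(build_adjacency(network1))
    assert parts.groups == (("1", "3", "6", "7"), ("2", "4", "5"))

    parts3 = connected_components(build_adjacency(network3))
    assert parts3.n_components == 4
    assert parts3.groups[0] == ("1", "2", "4", "8")
    assert parts3.groups[2] == ("7", "20")
    assert parts3.groups[3] == ("9", "18")
    assert parts3.groups[1][0] == "3"

    isolated = connected_components(
        build_adjacency(network_from_edges([], labels=["x", "y", "z"]))
    )
    assert isolated.groups == (("x",), ("y",), ("z",))


@given(seed=st.integers(0, 10**6), n=st.integers(1, 12),
       density=st.sampled_from([0.0, 0.1, 0.3, 0.7, 1.0]))
def test_components_match_scipy_union(seed, n, density):
    """Component structure agrees with an independent sparse-graph routine."""
    adj = random_adjacency(seed, n, density)
    ours = connected_components(adj)
    n_comp, member = scipy_components(adj.entries, directed=False)
    assert ours.n_components == n_comp
    # same partition: two vertices share a group iff scipy agrees
    group_of = {lab: k for k, g in enumerate(ours.groups) for lab in g}
    for i in range(n):
        for j in range(n):
            assert (group_of[adj.labels[i]] == group_of[adj.labels[j]]) == (
                member[i] == member[j]
            )


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def test_distance_matrix_worked_example(figure2):
    d = distance_matrix(build_adjacency(figure2))
    np.testing.assert_array_equal(d.entries, cf.FIG2_D)
    labels = list(figure2.labels)
    assert d.entries[labels.index("1"), labels.index("4")] == 3
    assert d.entries[labels.index("1"), labels.index("3")] == 2


def test_distance_matrix_network1(network1):
    d = distance_matrix(build_adjacency(network1))
    labels = list(network1.labels)
    assert d.entries[labels.index("3"), labels.index("6")] == 2
    assert d.entries[labels.index("2"), labels.index("5")] == 2
    assert d.max_finite_distance() == 2


def test_distance_single_edge_and_n2_case():
    d = distance_matrix(build_adjacency(network_from_edges([("1", "2")])))
    np.testing.assert_array_equal(d.entries, np.array([[0, 1], [1, 0]]))


def test_distance_missing_code():
    net = network_from_edges([("a", "b")], labels=["a", "b", "c"])
    d = distance_matrix(build_adjacency(net), unconnected_code="missing")
    assert d.entries[0, 2] == -1 and d.entries[2, 0] == -1
    assert d.entries[0, 0] == 0 and d.entries[0, 1] == 1


@given(seed=st.integers(0, 10**6), n=st.integers(1, 12),
       density=st.sampled_from([0.0, 0.1, 0.25, 0.5, 1.0]))
def test_distance_matches_bfs_oracle(seed, n, density):
    """Shortest-path lengths agree with breadth-first search everywhere."""
    adj = random_adjacency(seed, n, density)
    d = distance_matrix(adj).entries
    g = nx_graph(adj)
    sp = dict(nx.all_pairs_shortest_path_length(g))
    for i, a in enumerate(adj.labels):
        for j, b in enumerate(adj.labels):
            assert d[i, j] == sp[a].get(b, 0)


@given(seed=st.integers(0, 10**6), n=st.integers(2, 12),
       density=st.sampled_from([0.2, 0.5, 1.0]))
def test_distance_invariants(seed, n, density):
    """Symmetry, zero diagonal, bound n-1, edge iff distance 1, triangles."""
    adj = random_adjacency(seed, n, density)
    d = distance_matrix(adj).entries
    np.testing.assert_array_equal(d, d.T)
    assert (np.diag(d) == 0).all()
    assert d.max() <= n - 1
    np.testing.assert_array_equal((d == 1), (adj.entries == 1))
    # triangle inequality within a component
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if len({i, j, k}) == 3 and d[i, j] and d[j, k] and d[i, k]:
                    assert d[i, k] <= d[i, j] + d[j, k]


@given(seed=st.integers(0, 10**6), perm_seed=st.integers(0, 10**6))
def test_permutation_equivariance(seed, perm_seed):
    """Relabeling vertices permutes A, I(C_{n-1}) and D accordingly."""
    net = random_network(RandomNetworkSpec(n=9, component_sizes=(5, 4),
                                           edge_density=0.3, seed=seed))
    rng = np.random.default_rng(perm_seed)
    perm = rng.permutation(9)
    reordered = net.relabel([net.labels[i] for i in perm])
    for op in (lambda a: a.entries,
               lambda a: indirect_connection(a).entries,
               lambda a: distance_matrix(a).entries):
        base = op(build_adjacency(net))
        moved = op(build_adjacency(reordered))
        np.testing.assert_array_equal(moved, base[np.ix_(perm, perm)])


def test_multiarm_study_distances_all_one():
    net = network_from_studies([StudyRecord("s", tuple("ABCDE"))])
    assert net.n_edges == 10
    d = distance_matrix(build_adjacency(net)).entries
    assert (d[~np.eye(5, dtype=bool)] == 1).all()


# ---------------------------------------------------------------------------
# block sorting and summaries
# ---------------------------------------------------------------------------

def test_block_sort_network1(network1):
    adj = build_adjacency(network1)
    ent, labels = block_sort(distance_matrix(adj), connected_components(adj))
    assert labels == cf.NET1_BLOCK_ORDER
    np.testing.assert_array_equal(ent, cf.NET1_D_BLOCKED)


def test_block_sort_connected_is_identity(network2):
    adj = build_adjacency(network2)
    d = distance_matrix(adj)
    parts = connected_components(adj)
    assert parts.permutation == tuple(range(23))
    ent, labels = block_sort(d, parts)
    np.testing.assert_array_equal(ent, d.entries)
    assert labels == network2.labels


def test_block_sort_properties(network3):
    adj = build_adjacency(network3)
    d = distance_matrix(adj)
    parts = connected_components(adj)
    ent, labels = block_sort(d, parts)
    # multiset of entries preserved
    assert sorted(ent.ravel()) == sorted(d.entries.ravel())
    # off-block entries carry the unconnected code (0)
    bounds = np.cumsum([0] + [len(g) for g in parts.groups])
    for a in range(len(bounds) - 1):
        for b in range(len(bounds) - 1):
            if a != b:
                blockslice = ent[bounds[a]:bounds[a + 1], bounds[b]:bounds[b + 1]]
                assert (blockslice == 0).all()
    # sorting an already-sorted matrix with its identity partition is a no-op
    from nmaconnect import DistanceMatrix, build_adjacency as _ba
    sorted_net = network3.relabel(labels)
    adj2 = _ba(sorted_net)
    parts2 = connected_components(adj2)
    ent2, labels2 = block_sort(distance_matrix(adj2), parts2)
    np.testing.assert_array_equal(ent2, ent)
    assert labels2 == labels


def test_block_sort_label_mismatch(network1, network2):
    with pytest.raises(ValueError):
        block_sort(
            distance_matrix(build_adjacency(network1)),
            connected_components(build_adjacency(network2)),
        )


def test_summarize(network2, network3):
    s2 = summarize(network2)
    assert (s2.n_treatments, s2.n_components) == (23, 1)
    assert s2.is_connected and s2.max_finite_distance == 9
    s3 = summarize(network3)
    assert (s3.n_treatments, s3.n_edges, s3.n_components) == (25, 22, 4)
    assert s3.max_finite_distance == 7
    assert ("3", "10") in s3.max_distance_pairs

    empty = summarize(EvidenceNetwork((), frozenset()))
    assert empty.n_treatments == 0 and empty.n_components == 0
    assert empty.max_finite_distance == 0 and empty.components == ()
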