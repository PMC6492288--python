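"""Built-in example networks and a seeded random-network generator.

Four example networks ship with the package so that every test and demo
runs without external data:

* ``figure2`` — 8 treatments, 6 two-arm trials, two components; the
  small worked example whose adjacency powers are easy to follow by hand.
* ``network1`` — 7 treatments, 6 comparisons, two components
  ({1,3,6,7} and {2,4,5}).
* ``network2`` — 23 treatments, connected but sparse; some comparisons
  need as many as 9 steps.
* ``network3`` — 25 treatments in four disconnected components; the
  longest finite comparison chain is 7 steps.

The two larger networks are stored as their published block-collected
distance tables (embedded below as TSV text); their edge lists are
recovered as the distance-1 cells, which is exact because a pair is at
distance 1 precisely when it was compared directly.  The tables double
as cell-for-cell reference surfaces in the test suite.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .network import EvidenceNetwork, network_from_edges

__all__ = [
    "PAPER_NETWORKS",
    "paper_network",
    "printed_distance_table",
    "RandomNetworkSpec",
    "random_network",
]

#: Block-collected distance table for network 2 (single block: connected).
NETWORK2_DISTANCE_TSV = '\t1\t2\t3\t4\t5\t6\t7\t8\t9\t10\t11\t12\t13\t14\t15\t16\t17\t18\t19\t20\t21\t22\t23\n1\t0\t3\t5\t7\t2\t4\t4\t5\t1\t3\t5\t6\t3\t4\t1\t4\t1\t2\t2\t6\t6\t1\t2\n2\t3\t0\t6\t8\t3\t5\t1\t6\t4\t4\t6\t7\t2\t5\t2\t3\t4\t1\t5\t7\t7\t4\t3\n3\t5\t6\t0\t2\t7\t3\t5\t3\t6\t2\t4\t2\t4\t1\t6\t5\t4\t7\t7\t4\t1\t6\t3\n4\t7\t8\t2\t0\t9\t4\t7\t3\t8\t4\t5\t2\t6\t3\t8\t7\t6\t9\t9\t4\t1\t8\t5\n5\t2\t3\t7\t9\t0\t6\t4\t7\t3\t5\t7\t8\t5\t6\t1\t6\t3\t2\t4\t8\t8\t3\t4\n6\t4\t5\t3\t4\t6\t0\t4\t1\t5\t1\t1\t2\t3\t2\t5\t4\t3\t6\t6\t2\t3\t5\t2\n7\t4\t1\t5\t7\t4\t4\t0\t5\t5\t3\t5\t6\t1\t4\t3\t2\t3\t2\t6\t6\t6\t5\t2\n8\t5\t6\t3\t3\t7\t1\t5\t0\t6\t2\t2\t1\t4\t3\t6\t5\t4\t7\t7\t1\t2\t6\t3\n9\t1\t4\t6\t8\t3\t5\t5\t6\t0\t4\t6\t7\t4\t5\t2\t5\t2\t3\t3\t7\t7\t2\t3\n10\t3\t4\t2\t4\t5\t1\t3\t2\t4\t0\t2\t3\t2\t1\t4\t3\t2\t5\t5\t3\t3\t4\t1\n11\t5\t6\t4\t5\t7\t1\t5\t2\t6\t2\t0\t3\t4\t3\t6\t5\t4\t7\t7\t3\t4\t6\t3\n12\t6\t7\t2\t2\t8\t2\t6\t1\t7\t3\t3\t0\t5\t3\t7\t6\t5\t8\t8\t2\t1\t7\t4\n13\t3\t2\t4\t6\t5\t3\t1\t4\t4\t2\t4\t5\t0\t3\t4\t1\t2\t3\t5\t5\t5\t4\t1\n14\t4\t5\t1\t3\t6\t2\t4\t3\t5\t1\t3\t3\t3\t0\t5\t4\t3\t6\t6\t4\t2\t5\t2\n15\t1\t2\t6\t8\t1\t5\t3\t6\t2\t4\t6\t7\t4\t5\t0\t5\t2\t1\t3\t7\t7\t2\t3\n16\t4\t3\t5\t7\t6\t4\t2\t5\t5\t3\t5\t6\t1\t4\t5\t0\t3\t4\t6\t6\t6\t5\t2\n17\t1\t4\t4\t6\t3\t3\t3\t4\t2\t2\t4\t5\t2\t3\t2\t3\t0\t3\t3\t5\t5\t2\t1\n18\t2\t1\t7\t9\t2\t6\t2\t7\t3\t5\t7\t8\t3\t6\t1\t4\t3\t0\t4\t8\t8\t3\t4\n19\t2\t5\t7\t9\t4\t6\t6\t7\t3\t5\t7\t8\t5\t6\t3\t6\t3\t4\t0\t8\t8\t1\t4\n20\t6\t7\t4\t4\t8\t2\t6\t1\t7\t3\t3\t2\t5\t4\t7\t6\t5\t8\t8\t0\t3\t7\t4\n21\t6\t7\t1\t1\t8\t3\t6\t2\t7\t3\t4\t1\t5\t2\t7\t6\t5\t8\t8\t3\t0\t7\t4\n22\t1\t4\t6\t8\t3\t5\t5\t6\t2\t4\t6\t7\t4\t5\t2\t5\t2\t3\t1\t7\t7\t0\t3\n23\t2\t3\t3\t5\t4\t2\t2\t3\t3\t1\t3\t4\t1\t2\t3\t2\t1\t4\t4\t4\t4\t3\t0\n'

#: Block-collected distance table for network 3 (four diagonal blocks;
#: blank cells are unconnected pairs).
NETWORK3_DISTANCE_TSV = '\t1\t2\t4\t8\t3\t5\t6\t10\t11\t12\t13\t14\t15\t16\t17\t19\t21\t22\t23\t24\t25\t7\t20\t9\t18\n1\t0\t3\t1\t2\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\n2\t3\t0\t2\t1\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\n4\t1\t2\t0\t1\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\n8\t2\t1\t1\t0\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\n3\t\t\t\t\t0\t3\t4\t7\t6\t5\t5\t2\t4\t4\t4\t1\t7\t6\t5\t4\t3\t\t\t\t\n5\t\t\t\t\t3\t0\t2\t4\t3\t3\t2\t1\t2\t2\t1\t2\t4\t3\t2\t1\t1\t\t\t\t\n6\t\t\t\t\t4\t2\t0\t6\t5\t1\t4\t2\t2\t2\t3\t3\t6\t5\t4\t3\t1\t\t\t\t\n10\t\t\t\t\t7\t4\t6\t0\t3\t7\t4\t5\t6\t6\t5\t6\t2\t1\t2\t3\t5\t\t\t\t\n11\t\t\t\t\t6\t3\t5\t3\t0\t6\t3\t4\t5\t5\t4\t5\t3\t2\t1\t2\t4\t\t\t\t\n12\t\t\t\t\t5\t3\t1\t7\t6\t0\t5\t3\t3\t3\t4\t4\t7\t6\t5\t4\t2\t\t\t\t\n13\t\t\t\t\t5\t2\t4\t4\t3\t5\t0\t3\t4\t4\t3\t4\t4\t3\t2\t1\t3\t\t\t\t\n14\t\t\t\t\t2\t1\t2\t5\t4\t3\t3\t0\t2\t2\t2\t1\t5\t4\t3\t2\t1\t\t\t\t\n15\t\t\t\t\t4\t2\t2\t6\t5\t3\t4\t2\t0\t2\t3\t3\t6\t5\t4\t3\t1\t\t\t\t\n16\t\t\t\t\t4\t2\t2\t6\t5\t3\t4\t2\t2\t0\t3\t3\t6\t5\t4\t3\t1\t\t\t\t\n17\t\t\t\t\t4\t1\t3\t5\t4\t4\t3\t2\t3\t3\t0\t3\t5\t4\t3\t2\t2\t\t\t\t\n19\t\t\t\t\t1\t2\t3\t6\t5\t4\t4\t1\t3\t3\t3\t0\t6\t5\t4\t3\t2\t\t\t\t\n21\t\t\t\t\t7\t4\t6\t2\t3\t7\t4\t5\t6\t6\t5\t6\t0\t1\t2\t3\t5\t\t\t\t\n22\t\t\t\t\t6\t3\t5\t1\t2\t6\t3\t4\t5\t5\t4\t5\t1\t0\t1\t2\t4\t\t\t\t\n23\t\t\t\t\t5\t2\t4\t2\t1\t5\t2\t3\t4\t4\t3\t4\t2\t1\t0\t1\t3\t\t\t\t\n24\t\t\t\t\t4\t1\t3\t3\t2\t4\t1\t2\t3\t3\t2\t3\t3\t2\t1\t0\t2\t\t\t\t\n25\t\t\t\t\t3\t1\t1\t5\t4\t2\t3\t1\t1\t1\t2\t2\t5\t4\t3\t2\t0\t\t\t\t\n7\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t0\t1\t\t\n20\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t1\t0\t\t\n9\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t0\t1\n18\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t\t1\t0\n'

PAPER_NETWORKS = ("figure2", "network1", "network2", "network3")

_FIGURE2_EDGES = [("1", "2"), ("2", "3"), ("2", "5"), ("4", "5"),
                  ("6", "7"), ("7", "8")]
_NETWORK1_EDGES = [("1", "3"), ("1", "6"), ("1", "7"), ("2", "4"),
                   ("4", "5"), ("6", "7")]


def _parse_distance_tsv(tsv: str) -> tuple[np.ndarray, tuple[str, ...]]:
    """Parse an embedded blocked distance table.

    Returns (entries, labels) in the table's printed (block) order, with
    blank cells coded 0, the unconnected convention of the tables.
    """
    lines = [l for l in tsv.splitlines() if l.strip()]
    labels = tuple(c.strip() for c in lines[0].split("\t")[1:])
    n = len(labels)
    entries = np.zeros((n, n), dtype=np.int64)
    for i, line in enumerate(lines[1:]):
        cells = line.split("\t")[1 : n + 1]
        for j, cell in enumerate(cells):
            if cell.strip():
                entries[i, j] = int(cell)
    return entries, labels


def printed_distance_table(name: str) -> tuple[np.ndarray, tuple[str, ...]]:
    """The published block-collected distance table for network2/network3."""
    if name == "network2":
        return _parse_distance_tsv(NETWORK2_DISTANCE_TSV)
    if name == "network3":
        return _parse_distance_tsv(NETWORK3_DISTANCE_TSV)
    raise ValueError(f"no printed distance table for {name!r}")


def _edges_from_distance_table(name: str) -> list[tuple[str, str]]:
    entries, labels = printed_distance_table(name)
    n = len(labels)
    return [
        (labels[i], labels[j])
        for i in range(n)
        for j in range(i + 1, n)
        if entries[i, j] == 1
    ]


def paper_network(name: str) -> EvidenceNetwork:
    """Return one of the built-in example networks by name."""
    if name == "figure2":
        return network_from_edges(_FIGURE2_EDGES, labels=[str(i) for i in range(1, 9)])
    if name == "network1":
        return network_from_edges(_NETWORK1_EDGES, labels=[str(i) for i in range(1, 8)])
    if name in ("network2", "network3"):
        edges = _edges_from_distance_table(name)
        n = 23 if name == "network2" else 25
        return network_from_edges(edges, labels=[str(i) for i in range(1, n + 1)])
    raise ValueError(f"unknown network {name!r}; choose one of {PAPER_NETWORKS}")


@dataclass(frozen=True)
class RandomNetworkSpec:
    """Recipe for a random evidence network with planted components.

    Each component gets a uniform random spanning tree (random Prüfer
    sequence), so it is connected by construction; every remaining
    within-component pair is then added independently with probability
    ``edge_density``.  No edges ever cross components, so the component
    structure is exactly ``component_sizes``.
    """

    n: int
    component_sizes: tuple[int, ...]
    edge_density: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.component_sizes) != self.n:
            raise ValueError("component sizes must sum to n")
        if any(s < 1 for s in self.component_sizes):
            raise ValueError("component sizes must be positive")
        if not 0.0 <= self.edge_density <= 1.0:
            raise ValueError("edge_density must lie in [0, 1]")


def _prufer_tree(members: list[int], rng: np.random.Generator) -> list[tuple[int, int]]:
    """Uniform random labelled spanning tree on ``members`` (Prüfer decode)."""
    m = len(members)
    if m < 2:
        return []
    if m == 2:
        return [(members[0], members[1])]
    seq = [int(x) for x in rng.integers(0, m, size=m - 2)]
    degree = [1] * m
    for s in seq:
        degree[s] += 1
    edges: list[tuple[int, int]] = []
    leaves = [i for i in range(m) if degree[i] == 1]
    heapq.heapify(leaves)
    for s in seq:
        leaf = heapq.heappop(leaves)
        edges.append((members[leaf], members[s]))
        degree[s] -= 1
        if degree[s] == 1:
            heapq.heappush(leaves, s)
    u, v = heapq.heappop(leaves), heapq.heappop(leaves)
    edges.append((members[u], members[v]))
    return edges


def random_network(spec: RandomNetworkSpec) -> EvidenceNetwork:
    """Draw a seeded random network matching ``spec`` exactly."""
    rng = np.random.default_rng(spec.seed)
    labels = [f"t{i + 1}" for i in range(spec.n)]
    edges: list[tuple[str, str]] = []
    start = 0
    for size in spec.component_sizes:
        members = list(range(start, start + size))
        tree = set(map(frozenset, _prufer_tree(members, rng)))
        for e in tree:
            i, j = sorted(e)
            edges.append((labels[i], labels[j]))
        for a in range(size):
            for b in range(a + 1, size):
                i, j = members[a], members[b]
                if frozenset((i, j)) in tree:
                    continue
                if rng.random() < spec.edge_density:
                    edges.append((labels[i], labels[j]))
        start += size
    return network_from_edges(edges, labels=labels)
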