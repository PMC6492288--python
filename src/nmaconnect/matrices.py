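"""Matrix-based connectedness and indirectness computations.

The toolkit follows the classical adjacency-power route: for an evidence
network on ``n`` treatments with adjacency matrix ``A``, the entry
``(A^k)_ij`` counts k-step walks between treatments ``i`` and ``j``, the
cumulative sum ``C_l = sum_{k=1..l} A^k`` counts walks of length at most
``l``, and the elementwise indicator ``I(C_{n-1})`` — the *indirect
connection matrix* — is 1 exactly where two treatments can be compared
through some chain of trials.  The *distance matrix* ``D`` holds the
shortest-walk length for each pair and quantifies how indirect each
comparison is: every extra step stacks further homogeneity assumptions
on the comparison.

Walk counts grow exponentially in ``k``, so the reachability operations
(``indirect_connection``, ``distance_matrix``, components) run on a
boolean recurrence ``R_1 = I(A)``, ``R_i = I(R_{i-1} + R_{i-1} A)`` that
equals ``I(C_i)`` without ever forming the large integer powers; the
integer power route is kept (exact, arbitrary precision) for inspection
and as a cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .network import EvidenceNetwork, InvalidNetworkError

UnconnectedCode = Literal["zero", "missing"]

__all__ = [
    "AdjacencyMatrix",
    "WalkCountMatrix",
    "IndirectConnectionMatrix",
    "DistanceMatrix",
    "ComponentPartition",
    "ConnectivitySummary",
    "build_adjacency",
    "walk_counts",
    "cumulative_walks",
    "indicator",
    "indirect_connection",
    "is_connected",
    "connected_components",
    "distance_matrix",
    "block_sort",
    "summarize",
]


def _check_square(entries: np.ndarray, labels: tuple[str, ...]) -> None:
    n = len(labels)
    if entries.shape != (n, n):
        raise ValueError(
            f"matrix shape {entries.shape} does not match {n} labels"
        )


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Symmetric 0/1 matrix A with zero diagonal; a_ij = 1 iff directly compared."""

    labels: tuple[str, ...]
    entries: np.ndarray

    def __post_init__(self) -> None:
        _check_square(self.entries, self.labels)

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class WalkCountMatrix:
    """Exact integer matrix of walk counts (A^k, or a cumulative sum C_l)."""

    labels: tuple[str, ...]
    power: int
    entries: np.ndarray  # object dtype holding Python ints: no overflow

    def __post_init__(self) -> None:
        _check_square(self.entries, self.labels)


@dataclass(frozen=True)
class IndirectConnectionMatrix:
    """0/1 matrix with ones on the diagonal; 1 iff two treatments are connected."""

    labels: tuple[str, ...]
    entries: np.ndarray

    def __post_init__(self) -> None:
        _check_square(self.entries, self.labels)


@dataclass(frozen=True)
class DistanceMatrix:
    """Shortest-walk lengths between treatments.

    The diagonal is zero; by default an unconnected pair is also coded 0
    (``unconnected_code="zero"``), matching the convention of the printed
    matrices this package reproduces.  ``unconnected_code="missing"``
    keeps -1 sentinels internally so downstream code can distinguish
    "self" from "not comparable".
    """

    labels: tuple[str, ...]
    entries: np.ndarray
    unconnected_code: UnconnectedCode = "zero"

    def __post_init__(self) -> None:
        _check_square(self.entries, self.labels)

    def finite_distances(self) -> np.ndarray:
        """Upper-triangle distances over connected pairs only."""
        n = len(self.labels)
        iu = np.triu_indices(n, k=1)
        vals = self.entries[iu]
        return vals[vals > 0]

    def max_finite_distance(self) -> int:
        """Largest shortest-path length over comparable pairs (0 if none)."""
        vals = self.finite_distances()
        return int(vals.max()) if vals.size else 0


@dataclass(frozen=True)
class ComponentPartition:
    """Connected components and the permutation that block-diagonalizes.

    Groups are ordered by the smallest original label index; within a
    group labels keep their original relative order, so applying
    ``permutation`` to rows and columns collects any of the derived
    matrices into block-diagonal form with one block per component.
    """

    labels: tuple[str, ...]
    groups: tuple[tuple[str, ...], ...]
    permutation: tuple[int, ...]

    @property
    def n_components(self) -> int:
        return len(self.groups)

    def block_label_order(self) -> tuple[str, ...]:
        return tuple(self.labels[i] for i in self.permutation)


@dataclass(frozen=True)
class ConnectivitySummary:
    """Aggregate connectivity report for one evidence network."""

    n_treatments: int
    n_edges: int
    n_components: int
    components: tuple[tuple[str, ...], ...]
    is_connected: bool
    max_finite_distance: int
    max_distance_pairs: tuple[tuple[str, str], ...]
    distances: DistanceMatrix = field(repr=False)


# ---------------------------------------------------------------------------
# construction and walk counting
# ---------------------------------------------------------------------------

def build_adjacency(network: EvidenceNetwork) -> AdjacencyMatrix:
    """Adjacency matrix of an evidence network.

    ``a_ij = 1`` if treatments i and j have been compared in at least one
    trial, else 0, with a zero diagonal.  Several studies comparing the
    same pair still give 1: connectedness depends only on whether a pair
    was compared, not how often.
    """
    n = network.n_treatments
    pos = {lab: k for k, lab in enumerate(network.labels)}
    a = np.zeros((n, n), dtype=np.int64)
    for edge in network.edges:
        i, j = (pos[lab] for lab in edge)
        a[i, j] = a[j, i] = 1
    return AdjacencyMatrix(network.labels, a)


def _as_object(entries: np.ndarray) -> np.ndarray:
    out = np.empty(entries.shape, dtype=object)
    for idx, v in np.ndenumerate(entries):
        out[idx] = int(v)
    return out


def walk_counts(adj: AdjacencyMatrix, k: int) -> WalkCountMatrix:
    """k-th power of the adjacency matrix: counts of k-step walks.

    Exact arbitrary-precision integers — entries grow exponentially with
    ``k`` and would silently wrap in fixed-width arithmetic.
    """
    if k < 1:
        raise ValueError(f"walk length k must be >= 1, got {k}")
    base = _as_object(adj.entries)
    power = base
    for _ in range(k - 1):
        power = np.dot(power, base)
    return WalkCountMatrix(adj.labels, k, power)


def cumulative_walks(adj: AdjacencyMatrix, l: int) -> WalkCountMatrix:
    """C_l = A + A^2 + ... + A^l: counts of walks of length at most ``l``."""
    if l < 1:
        raise ValueError(f"maximum walk length l must be >= 1, got {l}")
    base = _as_object(adj.entries)
    power = base.copy()
    total = base.copy()
    for _ in range(l - 1):
        power = np.dot(power, base)
        total = total + power
    return WalkCountMatrix(adj.labels, l, total)


def indicator(m: WalkCountMatrix | np.ndarray) -> np.ndarray:
    """Elementwise I() operator: 1 where an entry is nonzero, else 0."""
    entries = m.entries if isinstance(m, WalkCountMatrix) else m
    return (np.asarray(entries) != 0).astype(np.int64)


# ---------------------------------------------------------------------------
# reachability: the boolean recurrence
# ---------------------------------------------------------------------------

def _reachability_steps(adj: AdjacencyMatrix):
    """Yield (step i, I(C_i) as bool array) until stabilization.

    R_1 = I(A); R_i = I(R_{i-1} + R_{i-1} A).  Each R_i equals I(C_i)
    but is computed in boolean arithmetic, so no overflow at any n.
    Iteration stops at the first i with R_i == R_{i-1} (all later terms
    coincide), and never exceeds i = n - 1, the maximum path length.
    """
    a = adj.entries.astype(bool)
    r = a.copy()
    yield 1, r
    for i in range(2, adj.n):
        nxt = r | (r @ a)
        if np.array_equal(nxt, r):
            return
        r = nxt
        yield i, r


def indirect_connection(adj: AdjacencyMatrix) -> IndirectConnectionMatrix:
    """Indirect connection matrix I(C_{n-1}).

    Entry (i, j) is 1 iff i and j are joined by some walk of length at
    most n-1, i.e. iff they lie in the same connected component.  The
    diagonal is 1 for every treatment, including isolated ones.
    """
    n = adj.n
    reach = np.eye(n, dtype=bool)
    for _, r in _reachability_steps(adj):
        reach |= r
    return IndirectConnectionMatrix(adj.labels, reach.astype(np.int64))


def is_connected(adj: AdjacencyMatrix) -> bool:
    """True iff every off-diagonal entry of the indirect connection matrix is 1."""
    if adj.n == 0:
        warnings.warn("network has no treatments; vacuously connected")
        return True
    return bool(indirect_connection(adj).entries.all())


def connected_components(adj: AdjacencyMatrix) -> ComponentPartition:
    """Reachability equivalence classes, in block order.

    Components are sorted by the smallest original label index; within a
    component labels keep their original relative order.
    """
    icm = indirect_connection(adj).entries.astype(bool)
    n = adj.n
    assigned = np.zeros(n, dtype=bool)
    groups: list[tuple[str, ...]] = []
    perm: list[int] = []
    for i in range(n):
        if assigned[i]:
            continue
        members = np.flatnonzero(icm[i])
        assigned[members] = True
        groups.append(tuple(adj.labels[j] for j in members))
        perm.extend(int(j) for j in members)
    return ComponentPartition(adj.labels, tuple(groups), tuple(perm))


def distance_matrix(
    adj: AdjacencyMatrix, unconnected_code: UnconnectedCode = "zero"
) -> DistanceMatrix:
    """Shortest-walk length between every pair of treatments.

    Computed as D = A + sum_{i=2..n-1} i * (I(C_i) - I(C_{i-1})): a pair
    first appearing in I(C_i) lies at distance exactly i.  The running
    reachability is seeded with the identity (distance 0 to self), which
    keeps the diagonal at zero, and the iteration stops as soon as
    reachability stabilizes.  Unconnected pairs are coded 0 by default,
    or -1 with ``unconnected_code="missing"``.
    """
    n = adj.n
    d = adj.entries.astype(np.int64).copy()
    reach = np.eye(n, dtype=bool) | adj.entries.astype(bool)
    for i, r in _reachability_steps(adj):
        if i == 1:
            continue
        newly = r & ~reach
        d[newly] = i
        reach |= r
    if unconnected_code == "missing":
        d[~reach] = -1
    return DistanceMatrix(adj.labels, d, unconnected_code)


def block_sort(
    matrix: IndirectConnectionMatrix | DistanceMatrix | WalkCountMatrix,
    partition: ComponentPartition,
):
    """Permute a matrix into block-diagonal (component-collected) form.

    Returns ``(sorted_entries, sorted_labels)``.  Off-block entries are
    already the unconnected code (0, or the missing sentinel) because
    they relate treatments in different components; the permutation only
    gathers each component into a contiguous block.  Idempotent on an
    already-sorted matrix with the matching identity partition.
    """
    if tuple(matrix.labels) != tuple(partition.labels):
        raise ValueError("matrix labels do not match partition labels")
    perm = np.asarray(partition.permutation)
    sorted_entries = matrix.entries[np.ix_(perm, perm)]
    return sorted_entries, partition.block_label_order()


def summarize(network: EvidenceNetwork) -> ConnectivitySummary:
    """Connectivity report: counts, components, and indirectness extremes."""
    adj = build_adjacency(network)
    parts = connected_components(adj)
    dist = distance_matrix(adj)
    dmax = dist.max_finite_distance()
    pairs: list[tuple[str, str]] = []
    if dmax > 0:
        iu = np.triu_indices(adj.n, k=1)
        for i, j in zip(*iu):
            if dist.entries[i, j] == dmax:
                pairs.append((network.labels[i], network.labels[j]))
    return ConnectivitySummary(
        n_treatments=network.n_treatments,
        n_edges=network.n_edges,
        n_components=parts.n_components,
        components=parts.groups,
        is_connected=parts.n_components <= 1,
        max_finite_distance=dmax,
        max_distance_pairs=tuple(pairs),
        distances=dist,
    )
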