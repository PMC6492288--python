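"""Evidence-network container for network meta-analysis.

An evidence network is a graph whose vertices are treatments and whose
edges are head-to-head comparisons available from at least one randomized
trial.  A multi-arm study contributes a complete subgraph among its arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence


class InvalidNetworkError(ValueError):
    """Raised when labels/edges/studies violate the network invariants."""


@dataclass(frozen=True)
class StudyRecord:
    """One randomized trial: a study id and its ordered treatment arms."""

    study_id: str
    arms: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.arms) < 1:
            raise InvalidNetworkError(
                f"study {self.study_id!r} has no treatment arms"
            )
        if len(set(self.arms)) != len(self.arms):
            raise InvalidNetworkError(
                f"study {self.study_id!r} lists a treatment more than once"
            )


@dataclass(frozen=True)
class EvidenceNetwork:
    """Treatments and the direct comparisons available between them.

    Parameters
    ----------
    labels
        Ordered, unique treatment labels.  Labels are arbitrary strings
        (numeric codes stay strings, so ``"01"`` and ``"1"`` differ);
        the order fixes the row/column order of every derived matrix.
    edges
        Unordered pairs of distinct labels with at least one direct
        (head-to-head) comparison.
    studies
        Optional provenance: the trial records the edges came from.
    """

    labels: tuple[str, ...]
    edges: frozenset[frozenset[str]]
    studies: tuple[StudyRecord, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({x for x in self.labels if self.labels.count(x) > 1})
            raise InvalidNetworkError(f"duplicate treatment labels: {dupes}")
        known = set(self.labels)
        for edge in self.edges:
            if len(edge) != 2:
                raise InvalidNetworkError(
                    f"self-comparison edge {set(edge)} is not allowed"
                )
            missing = edge - known
            if missing:
                raise InvalidNetworkError(
                    f"edge endpoint(s) {sorted(missing)} not among treatment labels"
                )

    @property
    def n_treatments(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_pairs(self) -> list[tuple[str, str]]:
        """Edges as (i, j) label pairs ordered by position in ``labels``."""
        pos = {lab: k for k, lab in enumerate(self.labels)}
        pairs = [tuple(sorted(e, key=pos.__getitem__)) for e in self.edges]
        return sorted(pairs, key=lambda p: (pos[p[0]], pos[p[1]]))

    def relabel(self, order: Sequence[str]) -> "EvidenceNetwork":
        """Return the same network with rows/columns in ``order``."""
        if set(order) != set(self.labels) or len(order) != len(self.labels):
            raise InvalidNetworkError("new order must be a permutation of labels")
        return EvidenceNetwork(tuple(order), self.edges, self.studies)


def network_from_edges(
    pairs: Iterable[tuple[str, str]],
    labels: Sequence[str] | None = None,
) -> EvidenceNetwork:
    """Build a network from explicit comparison pairs.

    Duplicate pairs collapse to a single edge; self-pairs are rejected.
    Labels default to first-appearance order over the pairs.
    """
    seen: list[str] = list(labels) if labels is not None else []
    seen_set = set(seen)
    edges: set[frozenset[str]] = set()
    for a, b in pairs:
        a, b = str(a), str(b)
        if a == b:
            raise InvalidNetworkError(
                f"self-comparison ({a!r}, {b!r}) is not a valid edge"
            )
        for lab in (a, b):
            if lab not in seen_set:
                if labels is not None:
                    raise InvalidNetworkError(
                        f"edge endpoint {lab!r} not among supplied labels"
                    )
                seen.append(lab)
                seen_set.add(lab)
        edges.add(frozenset((a, b)))
    return EvidenceNetwork(tuple(seen), frozenset(edges))


def network_from_studies(
    studies: Iterable[StudyRecord],
    labels: Sequence[str] | None = None,
) -> EvidenceNetwork:
    """Build a network from trial records.

    Each k-arm study contributes all k(k-1)/2 pairwise edges; repeated
    comparisons across studies collapse to a single edge, so the
    adjacency matrix stays 0/1.  Single-arm studies contribute a vertex
    but no edges.
    """
    studies = tuple(studies)
    seen: list[str] = list(labels) if labels is not None else []
    seen_set = set(seen)
    edges: set[frozenset[str]] = set()
    for st in studies:
        for lab in st.arms:
            if lab not in seen_set:
                if labels is not None:
                    raise InvalidNetworkError(
                        f"study {st.study_id!r} arm {lab!r} not among supplied labels"
                    )
                seen.append(lab)
                seen_set.add(lab)
        for a, b in combinations(st.arms, 2):
            edges.add(frozenset((a, b)))
    return EvidenceNetwork(tuple(seen), frozenset(edges), studies)
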