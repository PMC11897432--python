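"""Copy-number-event trees: representation, genotypes, validity.

A CNA event tree is a rooted tree whose non-root nodes each carry a set of
signed integer copy-number changes on genome segments.  A cell attached at a
node has the genotype obtained by accumulating every event on the path from
the root down to that node, starting from the root ploidy.  Two biological
constraints restrict the space of admissible (tree, events) pairs: a segment
whose copy number has reached zero can never be regained in a descendant, and
no two nodes may encode the same genotype (the smaller tree would explain the
data equally well, so the redundant one is forbidden).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Event",
    "CNATree",
    "compute_genotypes",
    "validate_tree",
    "genotype_set",
    "tree_to_json",
    "tree_from_json",
    "tree_to_dot",
]

#: validity reason codes
VALID = "valid"
NEGATIVE_STATE = "negative_state"
REGAIN_AFTER_ZERO = "regain_after_zero"
DUPLICATE_GENOTYPE = "duplicate_genotype"


class Event(dict):
    """Net copy-number changes of one tree node: ``{segment_index: delta}``.

    Deltas are non-zero signed integers; segment indices are 0-based.  An
    event touching a segment more than once is stored as its net change, so
    a zero net change on a segment is simply absent.
    """

    def __init__(self, deltas: Mapping[int, int] = ()):
        super().__init__()
        items = deltas.items() if isinstance(deltas, Mapping) else deltas
        for seg, delta in items:
            if delta != 0:
                self[int(seg)] = int(delta)
        if not self:
            raise ValueError("an event must change at least one segment")

    def __repr__(self) -> str:  # S1-based rendering, matching field convention
        parts = []
        for seg in sorted(self):
            d = self[seg]
            sign = "+" if d > 0 else "-"
            mag = abs(d)
            parts.append(f"{sign}{mag if mag > 1 else ''}S{seg + 1}")
        return "".join(parts)


@dataclass(frozen=True)
class CNATree:
    """Event tree stored as a parent vector.

    Nodes are indexed ``1..n``; index ``0`` is the root, which carries no
    event.  ``parents[i-1]`` is the parent of node ``i``.  ``events[i-1]`` is
    the event of node ``i``.  ``root_ploidy`` gives the baseline copy number
    per segment (a vector, so e.g. sex chromosomes may differ from autosomes).
    """

    parents: tuple[int, ...]
    events: tuple[Event, ...]
    root_ploidy: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "parents", tuple(int(p) for p in self.parents))
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(
            self, "root_ploidy", tuple(int(c) for c in self.root_ploidy)
        )
        n = self.n
        if len(self.events) != n:
            raise ValueError("need one event per non-root node")
        if any(c < 0 for c in self.root_ploidy):
            raise ValueError("root ploidy must be non-negative")
        for i, p in enumerate(self.parents, start=1):
            if not 0 <= p <= n or p == i:
                raise ValueError(f"parent of node {i} out of range: {p}")
        # reachability from the root == acyclicity for a parent vector;
        # cache the traversal order and child lists (used in hot loops)
        kids: list[list[int]] = [[] for _ in range(n + 1)]
        for j, p in enumerate(self.parents, start=1):
            kids[p].append(j)
        order, frontier = [], [0]
        while frontier:
            nxt = []
            for u in frontier:
                for v in kids[u]:
                    order.append(v)
                    nxt.append(v)
            frontier = nxt
        if len(order) != n:
            raise ValueError("parent vector contains a cycle")
        object.__setattr__(self, "_topo", tuple(order))
        object.__setattr__(self, "_children", tuple(tuple(k) for k in kids))

    @property
    def n(self) -> int:
        """Number of event nodes (root excluded)."""
        return len(self.parents)

    @property
    def n_segments(self) -> int:
        return len(self.root_ploidy)

    def parent(self, i: int) -> int:
        return self.parents[i - 1]

    def children(self, i: int) -> list[int]:
        return list(self._children[i])

    def topological_order(self) -> list[int]:
        """Node indices in root-to-leaf (BFS) order, root excluded."""
        return list(self._topo)

    def subtree(self, i: int) -> set[int]:
        """Node ``i`` and all of its descendants."""
        out = {i}
        frontier = [i]
        while frontier:
            u = frontier.pop()
            for v in self._children[u]:
                out.add(v)
                frontier.append(v)
        return out

    def __iter__(self) -> Iterator[int]:
        return iter(range(1, self.n + 1))


def compute_genotypes(tree: CNATree, n_segments: int | None = None) -> np.ndarray:
    """Accumulate events from the root to give every node's genotype.

    Returns an ``(n+1) x K`` integer matrix; row 0 is the root ploidy and row
    ``i`` is row ``parent(i)`` plus node ``i``'s deltas.  Negative entries are
    returned as-is — validity is a separate check.
    """
    K = tree.n_segments if n_segments is None else n_segments
    if K != tree.n_segments:
        raise ValueError("segment count does not match root ploidy length")
    for ev in tree.events:
        if any(not 0 <= seg < K for seg in ev):
            raise ValueError("event references a segment index out of range")
    C = np.empty((tree.n + 1, K), dtype=np.int64)
    C[0] = tree.root_ploidy
    for i in tree.topological_order():
        C[i] = C[tree.parent(i)]
        for seg, delta in tree.events[i - 1].items():
            C[i, seg] += delta
    return C


def validate_tree(
    tree: CNATree, genotypes: np.ndarray | None = None
) -> tuple[bool, str]:
    """Check the biological validity constraints.

    Returns ``(True, "valid")`` or ``(False, reason)`` with reason one of
    ``negative_state``, ``regain_after_zero``, ``duplicate_genotype``.
    """
    C = compute_genotypes(tree) if genotypes is None else genotypes
    if (C < 0).any():
        return False, NEGATIVE_STATE
    # a segment at state 0 must never be increased in a descendant
    for i in tree.topological_order():
        p = tree.parent(i)
        for seg, delta in tree.events[i - 1].items():
            if delta > 0 and C[p, seg] == 0:
                return False, REGAIN_AFTER_ZERO
    rows = {tuple(row) for row in C}
    if len(rows) != tree.n + 1:
        return False, DUPLICATE_GENOTYPE
    return True, VALID


def genotype_set(tree: CNATree) -> frozenset[tuple[int, ...]]:
    """The set of distinct genotype rows of a valid tree (size ``n+1``)."""
    C = compute_genotypes(tree)
    return frozenset(tuple(row) for row in C)


# --- serialization -----------------------------------------------------------


def tree_to_json(tree: CNATree) -> str:
    payload = {
        "n": tree.n,
        "parents": list(tree.parents),
        "events": [
            [{"segment": seg, "delta": d} for seg, d in sorted(ev.items())]
            for ev in tree.events
        ],
        "root_ploidy": list(tree.root_ploidy),
    }
    return json.dumps(payload, indent=1)


def tree_from_json(text: str) -> CNATree:
    payload = json.loads(text)
    events = tuple(
        Event({e["segment"]: e["delta"] for e in ev}) for ev in payload["events"]
    )
    return CNATree(tuple(payload["parents"]), events, tuple(payload["root_ploidy"]))


def tree_to_dot(tree: CNATree, cell_counts: Sequence[int] | None = None) -> str:
    """Graphviz DOT rendering with event labels and attached-cell counts."""
    lines = ["digraph cnatree {", "  node [shape=box];"]
    counts = list(cell_counts) if cell_counts is not None else None

    def label(i: int) -> str:
        base = "root" if i == 0 else repr(tree.events[i - 1])
        if counts is not None:
            base += f"\\n{counts[i]} cells"
        return base

    for i in range(tree.n + 1):
        lines.append(f'  n{i} [label="{label(i)}"];')
    for i in tree:
        lines.append(f"  n{tree.parent(i)} -> n{i};")
    lines.append("}")
    return "\n".join(lines)
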