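"""Evaluation metrics for copy-number calls and event trees.

Two quantities summarize reconstruction quality: the per-bin RMSE ``delta``
between true and inferred copy-number profiles, and the tree distance ``tau``
— the RMS difference between the two trees' cell-pair distance matrices,
where the distance between two cells on an annotated tree accumulates, bin by
bin, the absolute state changes along the path between their attachment nodes
through the most recent common ancestor, scaled by ``n_segments / n_bins`` so
one typical (single-segment, single-copy) event has unit weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .breakpoints import SegmentMap
from .data_model import CNATree

__all__ = [
    "TreeWithAttachments",
    "delta_rmse",
    "cell_pair_distance",
    "cell_distance_matrix",
    "tree_distance",
    "convergence_summary",
]


@dataclass
class TreeWithAttachments:
    tree: CNATree
    segmap: SegmentMap
    sigma: np.ndarray

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=int)
        if self.sigma.min(initial=0) < 0 or self.sigma.max(initial=0) > self.tree.n:
            raise ValueError("attachments out of node range")


def delta_rmse(true_profiles: np.ndarray, inferred_profiles: np.ndarray) -> float:
    """Root mean squared difference over all cells and bins."""
    a = np.asarray(true_profiles, dtype=float)
    b = np.asarray(inferred_profiles, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profile matrices must have equal shapes")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _node_edge_weights(tree: CNATree, segmap: SegmentMap) -> np.ndarray:
    """Per-node total |delta| x segment size (bin-weighted event size)."""
    sizes = segmap.sizes
    w = np.zeros(tree.n + 1)
    for i in tree:
        w[i] = sum(abs(d) * sizes[k] for k, d in tree.events[i - 1].items())
    return w


def _path_weights(tree: CNATree, segmap: SegmentMap) -> tuple[np.ndarray, list[set[int]]]:
    """Cumulative root-path edge weight and ancestor set per node."""
    w = _node_edge_weights(tree, segmap)
    depth = np.zeros(tree.n + 1)
    ancestors: list[set[int]] = [set() for _ in range(tree.n + 1)]
    ancestors[0] = {0}
    for i in tree.topological_order():
        p = tree.parent(i)
        depth[i] = depth[p] + w[i]
        ancestors[i] = ancestors[p] | {i}
    return depth, ancestors


def cell_pair_distance(annot: TreeWithAttachments, i: int, j: int) -> float:
    """Bin-weighted event path length between cells i and j, normalized."""
    return float(cell_distance_matrix(annot)[i, j])


def cell_distance_matrix(annot: TreeWithAttachments) -> np.ndarray:
    """All pairwise cell distances d_ij on one annotated tree.

    d(u, v) between attachment nodes decomposes as depth(u) + depth(v)
    - 2 depth(mrca(u, v)) in cumulative edge weight, then scales by
    n_segments / n_bins.
    """
    tree, segmap = annot.tree, annot.segmap
    depth, ancestors = _path_weights(tree, segmap)
    n = tree.n
    mrca_depth = np.zeros((n + 1, n + 1))
    for u in range(n + 1):
        for v in range(u, n + 1):
            common = ancestors[u] & ancestors[v]
            d = max((depth[a] for a in common), default=0.0)
            mrca_depth[u, v] = mrca_depth[v, u] = d
    node_dist = depth[:, None] + depth[None, :] - 2 * mrca_depth
    scale = segmap.n_segments / segmap.n_bins
    return scale * node_dist[np.ix_(annot.sigma, annot.sigma)]


def tree_distance(annot_a: TreeWithAttachments, annot_b: TreeWithAttachments) -> float:
    """RMS difference of the two upper-triangular cell distance matrices."""
    da = cell_distance_matrix(annot_a)
    db = cell_distance_matrix(annot_b)
    if da.shape != db.shape:
        raise ValueError("annotated trees must cover the same cells")
    m = da.shape[0]
    iu = np.triu_indices(m, k=1)
    return float(np.sqrt(np.mean((da[iu] - db[iu]) ** 2)))


def convergence_summary(
    scores: np.ndarray, annots: list[TreeWithAttachments]
) -> dict[str, float]:
    """Agreement of the best half of a set of chains.

    Keeps the ceil(half) of chains with the highest scores and reports their
    mean pairwise tau and mean log-score gap to the best chain.
    """
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores)
    keep = order[: max(1, (len(scores) + 1) // 2)]
    best = scores[keep[0]]
    gaps = best - scores[keep]
    taus = [
        tree_distance(annots[a], annots[b])
        for ai, a in enumerate(keep)
        for b in keep[ai + 1 :]
    ]
    return {
        "mean_pairwise_tau": float(np.mean(taus)) if taus else 0.0,
        "mean_score_gap": float(np.mean(gaps)),
        "n_kept": int(len(keep)),
    }
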