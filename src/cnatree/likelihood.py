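"""Per-cell attachment likelihoods under a Dirichlet-multinomial read model.

Reads of a cell fall into genome segments with probabilities proportional to
(copy number x segment size).  Overdispersion of shallow single-cell coverage
is captured by a Dirichlet-multinomial with concentration ``nu`` (large nu
recovers the plain multinomial).  Segments at copy number zero keep a small
residual rate ``eta`` so that stray mapped reads do not zero out the
likelihood.  Likelihoods for all attachment nodes of all cells are computed
relative to the root by a single tree traversal that only touches the terms
of segments changed by each event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp  # noqa: F401  (logsumexp re-exported)

from .breakpoints import SegmentCounts
from .data_model import CNATree, compute_genotypes

__all__ = [
    "LikelihoodParams",
    "AttachmentTable",
    "segment_probabilities",
    "dm_cell_loglik",
    "multinomial_cell_loglik",
    "root_loglik",
    "attachment_table",
]


@dataclass(frozen=True)
class LikelihoodParams:
    """Observation-model parameters.

    nu : Dirichlet-multinomial concentration (inverse overdispersion), > 0.
    eta : floor substituted for copy-number state 0, 0 < eta << 1.
    use_multinomial : use the large-nu multinomial limit instead of the DM.
    """

    nu: float = 1.0
    eta: float = 1e-4
    use_multinomial: bool = False

    def __post_init__(self):
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        if not 0 < self.eta < 1:
            raise ValueError("eta must lie in (0, 1)")


@dataclass
class AttachmentTable:
    """Log-likelihood of every (cell, attachment node) pair, relative to root.

    ``loglik[j, s]`` is ``log L_j(sigma=s) - log L_j(sigma=0)`` (column 0 is
    identically zero); ``root_loglik[j]`` is the absolute root score, the only
    part that depends on nu alone and so is cached across tree moves.
    """

    loglik: np.ndarray
    root_loglik: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.loglik.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.loglik.shape[1] - 1


def _floored(genotype_row: np.ndarray, eta: float) -> np.ndarray:
    return np.maximum(np.asarray(genotype_row, dtype=float), eta)


def segment_probabilities(
    genotype_row: np.ndarray, sizes: np.ndarray, eta: float = 1e-4
) -> np.ndarray:
    """Read probabilities p_k = c_k s_k / Z for one genotype, eta-floored."""
    c = _floored(genotype_row, eta)
    mass = c * np.asarray(sizes, dtype=float)
    return mass / mass.sum()


def _check_counts(D_row: np.ndarray) -> np.ndarray:
    D_row = np.asarray(D_row, dtype=float)
    if (D_row < 0).any() or np.isnan(D_row).any():
        raise ValueError("counts must be non-negative and finite")
    return D_row


def dm_cell_loglik(
    D_row: np.ndarray,
    genotype_row: np.ndarray,
    sizes: np.ndarray,
    params: LikelihoodParams,
) -> float:
    """Dirichlet-multinomial log-likelihood of one cell at one genotype.

    The multinomial coefficient is omitted throughout: it depends on the data
    only and cancels from every attachment and tree comparison.
    """
    D = _check_counts(D_row)
    alpha = params.nu * _floored(genotype_row, params.eta) * np.asarray(sizes, float)
    Z = alpha.sum()
    N = D.sum()
    return float(
        gammaln(Z) - gammaln(N + Z) + np.sum(gammaln(D + alpha) - gammaln(alpha))
    )


def multinomial_cell_loglik(
    D_row: np.ndarray,
    genotype_row: np.ndarray,
    sizes: np.ndarray,
    eta: float = 1e-4,
) -> float:
    """Multinomial (large-nu limit) log-likelihood, coefficient omitted."""
    D = _check_counts(D_row)
    mass = _floored(genotype_row, eta) * np.asarray(sizes, dtype=float)
    return float(-D.sum() * np.log(mass.sum()) + np.dot(D, np.log(mass)))


def root_loglik(
    counts: SegmentCounts,
    root_ploidy: np.ndarray,
    params: LikelihoodParams,
) -> np.ndarray:
    """Absolute log-likelihood of every cell attached at the root.

    Vectorized over cells.  For constant root ploidy the multinomial form
    reduces to ``(sum s)^-N * prod s^D`` — the ploidy cancels — while the DM
    form keeps the nu-dependence and is recomputed only when nu changes.
    """
    D = np.asarray(counts.D, dtype=float)
    sizes = np.asarray(counts.sizes, dtype=float)
    N = D.sum(axis=1)
    if params.use_multinomial:
        mass = _floored(root_ploidy, params.eta) * sizes
        return -N * np.log(mass.sum()) + D @ np.log(mass)
    alpha = params.nu * _floored(root_ploidy, params.eta) * sizes
    Z = alpha.sum()
    return gammaln(Z) - gammaln(N + Z) + (gammaln(D + alpha) - gammaln(alpha)).sum(axis=1)


def attachment_table(
    tree: CNATree,
    counts: SegmentCounts,
    params: LikelihoodParams,
    genotypes: np.ndarray | None = None,
    cached_root: np.ndarray | None = None,
) -> AttachmentTable:
    """Relative log-likelihoods of all cells at all nodes via tree traversal.

    Walking the tree root-to-leaf, a child differs from its parent only in
    the segments of its event, so only those product terms (and, for the DM,
    the two normalizer terms through Z) are updated.  Cost is
    O(m * (n + total event entries)) rather than O(m * n * K).
    """
    C = compute_genotypes(tree) if genotypes is None else genotypes
    D = np.asarray(counts.D, dtype=float)
    sizes = np.asarray(counts.sizes, dtype=float)
    m, n = D.shape[0], tree.n
    N = D.sum(axis=1)
    eta, nu = params.eta, params.nu

    floored = np.maximum(C.astype(float), eta)  # (n+1) x K
    Zs = (floored * sizes).sum(axis=1)  # per-node total mass

    rel = np.zeros((m, n + 1))
    if n > 0:
        # flatten all (node, segment) event entries in traversal order so the
        # expensive special-function evaluations happen in single array calls
        topo = tree.topological_order()
        node_of, seg_flat = [], []
        for i in topo:
            for seg in tree.events[i - 1]:
                node_of.append(i)
                seg_flat.append(seg)
        seg_flat = np.asarray(seg_flat, dtype=int)
        node_flat = np.asarray(node_of, dtype=int)
        parent_flat = np.asarray([tree.parent(i) for i in node_flat])
        cs_child = floored[node_flat, seg_flat] * sizes[seg_flat]
        cs_parent = floored[parent_flat, seg_flat] * sizes[seg_flat]
        sizes_per_node = np.asarray([len(tree.events[i - 1]) for i in topo])
        offsets = np.concatenate([[0], np.cumsum(sizes_per_node)[:-1]])
        Dflat = D[:, seg_flat]
        if params.use_multinomial:
            per_entry = Dflat * (np.log(cs_child) - np.log(cs_parent))
            grouped = np.add.reduceat(per_entry, offsets, axis=1)
            logZ = np.log(Zs)
            for j, i in enumerate(topo):
                p = tree.parent(i)
                rel[:, i] = rel[:, p] + grouped[:, j] - N * (logZ[i] - logZ[p])
        else:
            ac, ap = nu * cs_child, nu * cs_parent
            per_entry = gammaln(Dflat + ac) - gammaln(ac) - gammaln(Dflat + ap) + gammaln(ap)
            grouped = np.add.reduceat(per_entry, offsets, axis=1)
            glZ = gammaln(nu * Zs)
            glNZ = gammaln(N[:, None] + nu * Zs[None, :])  # m x (n+1)
            for j, i in enumerate(topo):
                p = tree.parent(i)
                rel[:, i] = (
                    rel[:, p]
                    + grouped[:, j]
                    + (glZ[i] - glZ[p])
                    - (glNZ[:, i] - glNZ[:, p])
                )

    root = cached_root if cached_root is not None else root_loglik(
        counts, np.asarray(tree.root_ploidy), params
    )
    return AttachmentTable(rel, root)
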