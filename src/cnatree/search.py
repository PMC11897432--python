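"""Staged search for the best-scoring event tree and per-cell calls.

The full joint space of trees and events is large, so inference proceeds in
two stages.  Stage one clusters the cells, averages their counts per cluster
(each cluster row weighted by its size), builds a starting tree from the
rounded normalized cluster profiles via Ward's method with unanimity-based
ancestral states, and runs a bank of MCMC chains until at least half agree
to within a score window.  Stage two re-runs the chains on the full
single-cell data, seeded from the cluster tree, after first learning the
overdispersion nu with the tree held fixed; it stops when either the score
window or a mean pairwise tree-distance criterion is met.  The winning tree
plus the per-cell maximum-likelihood attachments yield integer copy-number
calls per cell and bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import calinski_harabasz_score

from .breakpoints import SegmentCounts, SegmentMap
from .data_model import CNATree, Event, compute_genotypes, validate_tree
from .likelihood import LikelihoodParams, attachment_table
from .mcmc import ChainResult, MoveConfig, run_chain
from .metrics import TreeWithAttachments, convergence_summary
from .scoring import PriorParams, best_attachments

__all__ = [
    "SearchConfig",
    "InferenceResult",
    "cluster_cells",
    "cluster_matrix",
    "normalized_profiles",
    "initial_tree",
    "robust_infer",
    "call_copy_numbers",
    "compare_root_ploidies",
]


@dataclass(frozen=True)
class SearchConfig:
    n_chains: int = 10
    chain_length_factor: int = 4000  # iterations per event node
    score_window: float = 5.0  # log-units for the score agreement criterion
    distance_threshold: float = 0.02  # mean pairwise tau of the best half
    max_rounds: int = 3
    max_clusters: int = 20
    nu_init: float = 1.0
    nu_learn_iterations: int = 1000
    seed: int = 0


@dataclass
class InferenceResult:
    tree: CNATree
    nu: float
    sigma: np.ndarray
    copy_numbers: np.ndarray  # cells x bins
    score: float
    robust: bool
    diagnostics: dict = field(default_factory=dict)


def _cell_features(counts: SegmentCounts) -> np.ndarray:
    """Per-cell segment rates normalized to unit mean (depth removed)."""
    rates = counts.D / counts.sizes
    mean = rates.mean(axis=1, keepdims=True)
    mean[mean == 0] = 1.0
    return rates / mean


def cluster_cells(counts: SegmentCounts, max_clusters: int = 20) -> np.ndarray:
    """Ward hierarchical clustering with Calinski-Harabasz model selection.

    Returns integer labels in ``0..C-1``.  Candidate cluster counts run from
    2 to ``max_clusters``; if no split beats a single cluster (e.g. all rows
    identical), one cluster is returned.  Fully deterministic.
    """
    X = _cell_features(counts)
    m = X.shape[0]
    if m < 2 or np.allclose(X, X[0]):
        return np.zeros(m, dtype=int)
    Z = linkage(X, method="ward")
    best_labels, best_score = np.zeros(m, dtype=int), -np.inf
    for c in range(2, min(max_clusters, m - 1) + 1):
        labels = fcluster(Z, t=c, criterion="maxclust") - 1
        if len(np.unique(labels)) < 2:
            continue
        score = calinski_harabasz_score(X, labels)
        if score > best_score:
            best_labels, best_score = labels, score
    return best_labels


def cluster_matrix(
    counts: SegmentCounts, labels: np.ndarray
) -> tuple[SegmentCounts, np.ndarray]:
    """Average counts per cluster; weights are the member counts.

    A cluster row scored with weight w contributes w times its cell
    log-likelihood, standing in for its members during stage-one search.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    D = np.vstack([counts.D[labels == c].mean(axis=0) for c in ids])
    weights = np.array([(labels == c).sum() for c in ids], dtype=float)
    return SegmentCounts(D, counts.sizes.copy()), weights


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    cum = np.cumsum(weights[order])
    return float(values[order][np.searchsorted(cum, 0.5 * cum[-1])])


def normalized_profiles(
    counts: SegmentCounts, baseline: int = 2
) -> np.ndarray:
    """Integer copy-number guesses: rates centred so the median state is the baseline."""
    rates = counts.D / counts.sizes
    out = np.empty_like(rates)
    for j, row in enumerate(rates):
        med = _weighted_median(row, counts.sizes.astype(float))
        scale = baseline / med if med > 0 else 0.0
        out[j] = row * scale
    return np.maximum(np.rint(out), 0).astype(np.int64)


def initial_tree(profiles: np.ndarray, root_ploidy: np.ndarray) -> CNATree:
    """Starting tree from integer profiles via Ward + unanimity ancestors.

    A dendrogram over the profiles is annotated top-down: each internal node
    takes, per segment, the value shared by all its leaves if unanimous, else
    its parent's value; a segment at zero in the parent stays zero (no
    regains).  Edges with zero net change are contracted and duplicate
    genotypes merged, so the result always satisfies the validity
    constraints.
    """
    profiles = np.asarray(profiles, dtype=np.int64)
    root_ploidy = np.asarray(root_ploidy, dtype=np.int64)
    C, K = profiles.shape
    if C == 1:
        genos = [profiles[0]]
        dendro_parent = [-1]
    else:
        Z = linkage(profiles, method="ward")
        n_nodes = 2 * C - 1
        dendro_parent = [-1] * n_nodes
        children: list[tuple[int, int] | None] = [None] * n_nodes
        for idx, (a, b, _, _) in enumerate(Z):
            node = C + idx
            dendro_parent[int(a)] = node
            dendro_parent[int(b)] = node
            children[node] = (int(a), int(b))

        leafsets: list[set[int]] = [set() for _ in range(n_nodes)]
        for leaf in range(C):
            leafsets[leaf] = {leaf}
        for node in range(C, n_nodes):
            a, b = children[node]
            leafsets[node] = leafsets[a] | leafsets[b]

        genos_arr = np.zeros((n_nodes, K), dtype=np.int64)
        for node in range(n_nodes - 1, -1, -1):  # root of dendrogram first
            parent = dendro_parent[node]
            parent_geno = root_ploidy if parent == -1 else genos_arr[parent]
            leaves = profiles[sorted(leafsets[node])]
            unanimous = (leaves == leaves[0]).all(axis=0)
            geno = np.where(unanimous, leaves[0], parent_geno)
            geno = np.where(parent_geno == 0, 0, geno)  # forbid regains
            genos_arr[node] = geno
        genos = list(genos_arr)
        # re-order traversal: process dendrogram root-down when building tree
    # Build a parent-vector tree keeping only nodes that change the genotype.
    order = (
        [0]
        if C == 1
        else sorted(range(2 * C - 1), key=lambda v: -v)  # root (largest) first
    )
    cna_parent_of: dict[int, int] = {}  # dendrogram node -> CNA tree node id
    parents: list[int] = []
    events: list[Event] = []
    genotypes: list[np.ndarray] = [root_ploidy]
    for node in order:
        parent = dendro_parent[node]
        attach = 0 if parent == -1 else cna_parent_of[parent]
        diff = genos[node] - genotypes[attach]
        if diff.any():
            events.append(Event({k: int(d) for k, d in enumerate(diff) if d != 0}))
            parents.append(attach)
            genotypes.append(np.asarray(genos[node]))
            cna_parent_of[node] = len(parents)
        else:
            cna_parent_of[node] = attach
    tree = CNATree(parents, events, tuple(int(c) for c in root_ploidy))
    return _merge_duplicates(tree)


def _merge_duplicates(tree: CNATree) -> CNATree:
    """Repeatedly merge nodes with identical genotypes until the tree is valid."""
    while True:
        G = compute_genotypes(tree)
        seen: dict[tuple, int] = {}
        dup = None
        for i in range(tree.n + 1):
            key = tuple(G[i])
            if key in seen:
                dup = (seen[key], i)
                break
            seen[key] = i
        if dup is None:
            return tree
        keep, drop = dup
        parents = []
        events = []
        for j in range(1, tree.n + 1):
            if j == drop:
                continue
            p = tree.parents[j - 1]
            if p == drop:
                p = keep
            parents.append(p - 1 if p > drop else p)
            events.append(tree.events[j - 1])
        # children re-pointed to the kept twin keep their events (same genotype)
        tree = CNATree(parents, events, tree.root_ploidy)


def _run_chain_bank(
    tree: CNATree,
    counts: SegmentCounts,
    iterations: int,
    n_chains: int,
    seeds,
    *,
    nu: float,
    lik_params: LikelihoodParams,
    prior: PriorParams,
    score_mode: str,
    weights=None,
    move_config: MoveConfig | None = None,
) -> list[ChainResult]:
    return [
        run_chain(
            tree,
            counts,
            iterations,
            nu=nu,
            lik_params=lik_params,
            prior=prior,
            score_mode=score_mode,
            weights=weights,
            move_config=move_config,
            rng=np.random.default_rng(seed),
        )
        for seed in seeds[:n_chains]
    ]


def _score_window_ok(scores: np.ndarray, window: float) -> bool:
    best = scores.max()
    return int((scores >= best - window).sum()) * 2 >= len(scores)


def robust_infer(
    counts: SegmentCounts,
    segmap: SegmentMap,
    config: SearchConfig | None = None,
    *,
    score_mode: str = "max",
    root_ploidy: np.ndarray | int = 2,
    lik_params: LikelihoodParams | None = None,
    prior: PriorParams | None = None,
) -> InferenceResult:
    """Cluster-first staged tree search with robustness checks."""
    config = config or SearchConfig()
    prior = prior or PriorParams()
    lik_params = lik_params or LikelihoodParams()
    K = counts.D.shape[1]
    if np.isscalar(root_ploidy):
        root_ploidy = np.full(K, int(root_ploidy), dtype=np.int64)
    root_ploidy = np.asarray(root_ploidy, dtype=np.int64)

    ss = np.random.SeedSequence(config.seed)
    seed_iter = iter(ss.generate_state(10_000, dtype=np.uint32).tolist())

    def seeds(k: int) -> list[int]:
        return [next(seed_iter) for _ in range(k)]

    # ---- stage 1: clustered data -------------------------------------------
    labels = cluster_cells(counts, config.max_clusters)
    ccounts, weights = cluster_matrix(counts, labels)
    profiles = normalized_profiles(ccounts, baseline=int(round(root_ploidy.mean())))
    tree = initial_tree(profiles, root_ploidy)
    nu = config.nu_init

    diagnostics: dict = {"n_clusters": int(weights.size), "stage1_rounds": 0}
    best_tree, best_nu, best_score = tree, nu, -np.inf
    for round_ in range(config.max_rounds):
        iters = config.chain_length_factor * max(best_tree.n, 1)
        results = _run_chain_bank(
            best_tree, ccounts, iters, config.n_chains, seeds(config.n_chains),
            nu=nu, lik_params=lik_params, prior=prior,
            score_mode=score_mode, weights=weights,
        )
        scores = np.array([r.best.score.total for r in results])
        top = results[int(scores.argmax())]
        if top.best.score.total > best_score:
            best_tree, best_nu, best_score = top.best.tree, top.best.nu, top.best.score.total
        diagnostics["stage1_rounds"] = round_ + 1
        diagnostics["stage1_scores"] = scores.tolist()
        if _score_window_ok(scores, config.score_window):
            break

    # ---- stage 2: full data ------------------------------------------------
    # learn nu on the full data with the cluster tree fixed
    nu_only = MoveConfig(weights={"nu_walk": 1.0})
    nu_res = run_chain(
        best_tree, counts, config.nu_learn_iterations,
        nu=best_nu, lik_params=lik_params, prior=prior, score_mode=score_mode,
        move_config=nu_only, rng=np.random.default_rng(seeds(1)[0]),
    )
    nu = nu_res.best.nu

    best_tree2, best_nu2, best_score2 = best_tree, nu, -np.inf
    robust = False
    for round_ in range(config.max_rounds):
        iters = config.chain_length_factor * max(best_tree2.n, 1)
        results = _run_chain_bank(
            best_tree2, counts, iters, config.n_chains, seeds(config.n_chains),
            nu=best_nu2, lik_params=lik_params, prior=prior, score_mode=score_mode,
        )
        scores = np.array([r.best.score.total for r in results])
        top = results[int(scores.argmax())]
        if top.best.score.total > best_score2:
            best_tree2, best_nu2, best_score2 = (
                top.best.tree, top.best.nu, top.best.score.total,
            )
        annots = [
            TreeWithAttachments(
                r.best.tree, segmap, best_attachments(r.best.table)
            )
            for r in results
        ]
        summary = convergence_summary(scores, annots)
        diagnostics["stage2_rounds"] = round_ + 1
        diagnostics["stage2_scores"] = scores.tolist()
        diagnostics["stage2_convergence"] = summary
        if _score_window_ok(scores, config.score_window) or (
            summary["mean_pairwise_tau"] < config.distance_threshold
        ):
            robust = True
            break

    params = LikelihoodParams(
        nu=best_nu2, eta=lik_params.eta, use_multinomial=lik_params.use_multinomial
    )
    table = attachment_table(best_tree2, counts, params)
    sigma = best_attachments(table)
    cnvs = call_copy_numbers(best_tree2, sigma, segmap)
    return InferenceResult(
        best_tree2, best_nu2, sigma, cnvs, best_score2, robust, diagnostics
    )


def call_copy_numbers(
    tree: CNATree, sigma: np.ndarray, segmap: SegmentMap
) -> np.ndarray:
    """Expand each cell's attached genotype over bins: cells x bins integers."""
    genotypes = compute_genotypes(tree)
    return segmap.expand(genotypes[np.asarray(sigma, dtype=int)])


def compare_root_ploidies(
    counts: SegmentCounts,
    segmap: SegmentMap,
    ploidies=(2, 4),
    config: SearchConfig | None = None,
    **kwargs,
) -> dict[int, InferenceResult]:
    """Run the full search per candidate root ploidy; report scores side by side.

    No automatic decision is made: e.g. comparing a diploid root against a
    tetraploid one (whole-genome duplication) is left to the score gap.
    """
    return {
        int(p): robust_infer(counts, segmap, config, root_ploidy=p, **kwargs)
        for p in ploidies
    }
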