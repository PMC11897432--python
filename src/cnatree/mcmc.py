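"""Metropolis-Hastings sampling over (tree, events, overdispersion).

The chain moves through the joint space of tree structures, per-node event
vectors and the concentration parameter nu with seven move types: five
structural moves (prune & reattach, label swap, single-copy event change,
node addition/removal, node condense/split), a genotype-preserving prune &
reattach that rewrites the pruned node's event so every genotype in the tree
is unchanged, and a Gaussian random walk on log(nu).  Every proposal carries
an exact Hastings correction; proposals that violate the biological validity
constraints are rejected outright.

Node relabelling subtlety: moves that change the node count insert the new
node at a uniformly random label (shifting higher labels up) and delete by
label (shifting down).  The two 1/(labels) factors cancel in the add/remove
ratio pair, keeping the chain exactly reversible on labelled trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from .data_model import CNATree, Event, compute_genotypes, validate_tree
from .likelihood import AttachmentTable, LikelihoodParams, attachment_table, root_loglik
from .scoring import (
    PriorParams,
    ScoreBreakdown,
    event_log_prior,
    max_log_score,
    poisson_logpmf,
    sum_log_score,
)

__all__ = ["MoveConfig", "ChainState", "ChainResult", "run_chain", "MOVE_NAMES"]

LOG_HALF = math.log(0.5)

MOVE_NAMES = (
    "prune_reattach",
    "label_swap",
    "event_change",
    "add_remove_node",
    "condense_split",
    "genotype_preserving",
    "nu_walk",
)


@dataclass(frozen=True)
class MoveConfig:
    """Relative move weights and the nu random-walk step.

    All structural moves have weight 1 except the genotype-preserving prune &
    reattach at 0.4 (it scores its whole neighbourhood, so it is dearer per
    call); the nu walk is a seventh move of weight 1.
    """

    weights: dict[str, float] = field(
        default_factory=lambda: {
            "prune_reattach": 1.0,
            "label_swap": 1.0,
            "event_change": 1.0,
            "add_remove_node": 1.0,
            "condense_split": 1.0,
            "genotype_preserving": 0.4,
            "nu_walk": 1.0,
        }
    )
    nu_walk_sd: float = 0.1
    nu_bounds: tuple[float, float] = (1e-2, 1e6)

    def probabilities(self) -> np.ndarray:
        w = np.array([max(self.weights.get(name, 0.0), 0.0) for name in MOVE_NAMES])
        if w.sum() <= 0:
            raise ValueError("at least one move weight must be positive")
        return w / w.sum()


@dataclass
class ChainState:
    tree: CNATree
    nu: float
    genotypes: np.ndarray
    table: AttachmentTable
    score: ScoreBreakdown
    iteration: int = 0


@dataclass
class ChainResult:
    best: ChainState
    final: ChainState
    improvements: list[tuple[int, str, float]]
    accepted: int
    iterations: int

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / max(self.iterations, 1)


# --- tree surgery helpers ----------------------------------------------------


def _relabel_up(idx: int, label: int) -> int:
    """Shift a node index up by one if at/above a freshly inserted label."""
    return idx + 1 if idx >= label else idx


def _insert_node(
    tree: CNATree, parent: int, event: Event, adopted: set[int], label: int
) -> CNATree:
    """Insert a node at ``label`` under ``parent``, adopting ``adopted``."""
    parents = list(tree.parents)
    events = list(tree.events)
    new_parents = [_relabel_up(p, label) for p in parents]
    new_parents.insert(label - 1, _relabel_up(parent, label))
    events.insert(label - 1, event)
    for child in adopted:
        new_parents[_relabel_up(child, label) - 1] = label
    return CNATree(new_parents, events, tree.root_ploidy)


def _remove_node(tree: CNATree, i: int) -> CNATree:
    """Delete node ``i``; its children move to its parent; labels shift down."""
    p = tree.parent(i)
    parents = []
    events = []
    for j in range(1, tree.n + 1):
        if j == i:
            continue
        pj = tree.parents[j - 1]
        if pj == i:
            pj = p
        parents.append(pj - 1 if pj > i else pj)
        events.append(tree.events[j - 1])
    return CNATree(parents, events, tree.root_ploidy)


@lru_cache(maxsize=128)
def _log_trunc(K: int, lam: float) -> float:
    """log P(Poisson(lam) <= K-1), the truncation normalizer."""
    return math.log(sum(math.exp(poisson_logpmf(j, lam)) for j in range(K)))


def _sample_event(
    rng: np.random.Generator, K: int, prior: PriorParams
) -> tuple[Event, float]:
    """Draw an event from the shifted-Poisson prior; return it and log density.

    The segment count is truncated at K (rejection), so the density carries
    the CDF normalizer; the segment set is uniform without replacement.
    """
    while True:
        k = int(rng.poisson(prior.lambda_s)) + 1
        if k <= K:
            break
    segs = rng.choice(K, size=k, replace=False)
    deltas = {}
    logq = (
        poisson_logpmf(k - 1, prior.lambda_s)
        - _log_trunc(K, prior.lambda_s)
        - _log_comb(K, k)
    )
    for seg in segs:
        mag = int(rng.poisson(prior.lambda_c)) + 1
        sign = 1 if rng.random() < 0.5 else -1
        deltas[int(seg)] = sign * mag
        logq += poisson_logpmf(mag - 1, prior.lambda_c) + LOG_HALF
    return Event(deltas), float(logq)


def _event_log_density(event: Event, K: int, prior: PriorParams) -> float:
    """Log density of ``event`` under the proposal used by ``_sample_event``."""
    k = len(event)
    if k > K:
        return -np.inf
    logq = (
        poisson_logpmf(k - 1, prior.lambda_s)
        - _log_trunc(K, prior.lambda_s)
        - _log_comb(K, k)
    )
    for delta in event.values():
        logq += poisson_logpmf(abs(delta) - 1, prior.lambda_c) + LOG_HALF
    return float(logq)


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


# --- structural proposals ----------------------------------------------------
# Each returns (new_tree, log_hastings_ratio) or None when the move cannot
# fire from the current state (treated as an immediate rejection).


def propose_prune_reattach(tree: CNATree, rng) -> tuple[CNATree, float] | None:
    if tree.n == 0:
        return None
    i = int(rng.integers(1, tree.n + 1))
    sub = tree.subtree(i)
    targets = [t for t in range(tree.n + 1) if t not in sub]
    t = targets[int(rng.integers(len(targets)))]
    parents = list(tree.parents)
    parents[i - 1] = t
    # the subtree (hence the target count) is the same in both directions
    return CNATree(parents, tree.events, tree.root_ploidy), 0.0


def propose_label_swap(tree: CNATree, rng) -> tuple[CNATree, float] | None:
    if tree.n < 2:
        return None
    i, j = rng.choice(tree.n, size=2, replace=False) + 1
    events = list(tree.events)
    events[i - 1], events[j - 1] = events[j - 1], events[i - 1]
    return CNATree(tree.parents, events, tree.root_ploidy), 0.0


def propose_event_change(tree: CNATree, rng) -> tuple[CNATree, float] | None:
    """Step one copy on a uniformly chosen (node, segment, direction).

    A +-1 step on a uniform triple is its own reverse with equal probability,
    so the Hastings ratio is 1.  A step that empties a node's event proposes
    a zero-effect node, which the validity gate rejects downstream.
    """
    if tree.n == 0:
        return None
    K = tree.n_segments
    i = int(rng.integers(1, tree.n + 1))
    seg = int(rng.integers(K))
    step = 1 if rng.random() < 0.5 else -1
    deltas = dict(tree.events[i - 1])
    new_delta = deltas.get(seg, 0) + step
    if new_delta == 0:
        deltas.pop(seg)
    else:
        deltas[seg] = new_delta
    if not deltas:
        return None  # empty node: equivalent to a duplicate-genotype rejection
    events = list(tree.events)
    events[i - 1] = Event(deltas)
    return CNATree(tree.parents, events, tree.root_ploidy), 0.0


def propose_add_remove_node(
    tree: CNATree, rng, prior: PriorParams
) -> tuple[CNATree, float] | None:
    n, K = tree.n, tree.n_segments
    if rng.random() < 0.5:  # add
        p = int(rng.integers(n + 1))  # uniform over root..n
        event, logq = _sample_event(rng, K, prior)
        children = tree.children(p)
        adopted = {c for c in children if rng.random() < 0.5}
        label = int(rng.integers(1, n + 2))
        new = _insert_node(tree, p, event, adopted, label)
        # forward: 1/(n+1) parent x q(E) x (1/2)^children x 1/(n+1) label;
        # reverse remove: 1/(n+1) node choice
        log_ratio = -logq - len(children) * LOG_HALF + math.log(n + 1)
        return new, log_ratio
    if n == 0:
        return None
    i = int(rng.integers(1, n + 1))
    event = tree.events[i - 1]
    p = tree.parent(i)
    new = _remove_node(tree, i)
    # forward: 1/n node choice; reverse add: 1/n parent x q(E) x
    # (1/2)^children x 1/n label
    c_after = len(tree.children(p)) - 1 + len(tree.children(i))
    log_ratio = (
        _event_log_density(event, K, prior) + c_after * LOG_HALF - math.log(n)
    )
    return new, log_ratio


def _condensable_edges(tree: CNATree) -> list[int]:
    return [i for i in tree if tree.parent(i) != 0]


def _splittable_nodes(tree: CNATree) -> list[int]:
    return [i for i in tree if len(tree.events[i - 1]) >= 2]


def propose_condense_split(
    tree: CNATree, rng
) -> tuple[CNATree, float] | None:
    """Merge a parent-child edge into one node, or split a node in two.

    Split partitions a node's event entries into two non-empty groups
    (uniform over ordered assignments) and hands each former child to either
    side with probability 1/2.  Condense is only reversible when the two
    event sets touch disjoint segments; otherwise the reverse probability is
    zero and the proposal is rejected.
    """
    n = tree.n
    if rng.random() < 0.5:  # condense
        edges = _condensable_edges(tree)
        if not edges:
            return None
        i = edges[int(rng.integers(len(edges)))]
        p = tree.parent(i)
        ev_p, ev_i = tree.events[p - 1], tree.events[i - 1]
        if set(ev_p) & set(ev_i):
            return None  # a split cannot reconstruct overlapping deltas
        merged = Event({**ev_p, **ev_i})
        new = _remove_node(tree, i)
        new_label_p = p - 1 if p > i else p
        events = list(new.events)
        events[new_label_p - 1] = merged
        new = CNATree(new.parents, events, new.root_ploidy)
        k = len(merged)
        c_merged = len(new.children(new_label_p))
        s_new = len(_splittable_nodes(new))
        log_ratio = (
            -math.log(s_new)
            - math.log(2**k - 2)
            + c_merged * LOG_HALF
            - math.log(n)  # label choice of the re-inserted node
            + math.log(len(edges))
        )
        return new, log_ratio
    nodes = _splittable_nodes(tree)
    if not nodes:
        return None
    i = nodes[int(rng.integers(len(nodes)))]
    entries = sorted(tree.events[i - 1].items())
    k = len(entries)
    while True:
        mask = rng.integers(0, 2, size=k)
        if 0 < mask.sum() < k:
            break
    keep = Event({s: d for (s, d), m in zip(entries, mask) if m == 0})
    move = Event({s: d for (s, d), m in zip(entries, mask) if m == 1})
    children = tree.children(i)
    adopted = {c for c in children if rng.random() < 0.5}
    label = int(rng.integers(1, n + 2))
    events = list(tree.events)
    events[i - 1] = keep
    base = CNATree(tree.parents, events, tree.root_ploidy)
    new = _insert_node(base, i, move, adopted, label)
    edges_new = len(_condensable_edges(new))
    log_ratio = (
        -math.log(edges_new)
        + math.log(len(nodes))
        + math.log(2**k - 2)
        - len(children) * LOG_HALF
        + math.log(n + 1)  # reverse of the label choice
    )
    return new, log_ratio


def _pairwise_event_log_prior(C: np.ndarray, prior: PriorParams) -> np.ndarray:
    """Log event prior of the rewrite C_i - C_t for every (node i, target t).

    Entry (i, t) is the shifted-Poisson prior of the event whose deltas are
    the genotype difference row i minus row t (vectorized with array lgamma).
    Pairs with zero difference or a regain of a zero-state segment in the
    target get -inf (they are not genotype-preserving-valid).
    """
    from scipy.special import gammaln

    diff = C[:, None, :] - C[None, :, :]  # (n+1, n+1, K)
    nz = diff != 0
    k = nz.sum(axis=2)
    mag = np.abs(diff)
    ls, lc = prior.lambda_s, prior.lambda_c
    # sum over entries of poisson_logpmf(|d|-1, lc) + log(1/2)
    per_entry = np.where(
        nz, (mag - 1) * np.log(lc) - lc - gammaln(mag) + LOG_HALF, 0.0
    ) if lc > 0 else np.where(nz & (mag != 1), -np.inf, np.where(nz, LOG_HALF, 0.0))
    lp = per_entry.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp += np.where(k > 0, (k - 1) * np.log(ls) - ls - gammaln(k), -np.inf) \
            if ls > 0 else np.where(k == 1, -0.0, -np.inf)
    regain = ((diff > 0) & (C[None, :, :] == 0)).any(axis=2)
    lp[regain] = -np.inf
    lp[k == 0] = -np.inf
    return lp


def _descendant_mask(tree: CNATree) -> np.ndarray:
    """Boolean (n+1, n+1) matrix: entry (i, t) true iff t is in subtree(i)."""
    n = tree.n
    mask = np.eye(n + 1, dtype=bool)
    for i in reversed(tree.topological_order()):  # leaves first
        mask[tree.parent(i)] |= mask[i]
    return mask


def _gp_weights(
    tree: CNATree, pair_lp: np.ndarray, old_lp: np.ndarray
) -> np.ndarray:
    """Unnormalized log-weights of the genotype-preserving neighbourhood.

    Row i, column t holds the event-prior change of pruning node i and
    reattaching it under t with the rewritten event; -inf marks pairs outside
    the neighbourhood (t inside subtree(i), t the current parent, or an
    invalid rewrite).
    """
    n = tree.n
    w = pair_lp[1:, :] - old_lp[:, None]  # rows: node 1..n
    desc = _descendant_mask(tree)
    w[desc[1:, :]] = -np.inf
    w[np.arange(n), list(tree.parents)] = -np.inf
    return w


def propose_genotype_preserving(
    tree: CNATree, C: np.ndarray, rng, prior: PriorParams
) -> tuple[CNATree, float] | None:
    """Sample from the genotype-preserving neighbourhood, prior-weighted.

    Reattaching node i under target t with the rewritten event C_i - C_t
    leaves every node genotype unchanged, so only the event-vector prior
    moves; the whole neighbourhood is enumerated and a member drawn with
    probability proportional to exp(prior change), with the reverse
    neighbourhood's normalizer supplying the Hastings correction.
    """
    n = tree.n
    if n == 0:
        return None
    pair_lp = _pairwise_event_log_prior(C, prior)
    old_lp = np.array([event_log_prior(ev, prior) for ev in tree.events])
    w = _gp_weights(tree, pair_lp, old_lp)
    flat = w.ravel()
    finite = np.isfinite(flat)
    if not finite.any():
        return None
    top = flat[finite].max()
    probs = np.where(finite, np.exp(np.where(finite, flat, -np.inf) - top), 0.0)
    probs /= probs.sum()
    pick = int(rng.choice(flat.size, p=probs))
    i, t = pick // (n + 1) + 1, pick % (n + 1)
    diff = C[i] - C[t]
    event = Event({k: int(d) for k, d in enumerate(diff) if d != 0})
    parents = list(tree.parents)
    parents[i - 1] = t
    events = list(tree.events)
    events[i - 1] = event
    new = CNATree(parents, events, tree.root_ploidy)
    log_fwd = float(np.log(probs[pick]))
    # reverse: same genotype matrix; only node i's own event prior changed
    old_lp_rev = old_lp.copy()
    old_lp_rev[i - 1] = pair_lp[i, t]
    w_rev = _gp_weights(new, pair_lp, old_lp_rev)
    flat_rev = w_rev.ravel()
    finite_rev = np.isfinite(flat_rev)
    top_rev = flat_rev[finite_rev].max()
    probs_rev = np.where(finite_rev, np.exp(np.where(finite_rev, flat_rev, -np.inf) - top_rev), 0.0)
    probs_rev /= probs_rev.sum()
    idx_rev = (i - 1) * (n + 1) + tree.parent(i)
    log_rev = float(np.log(probs_rev[idx_rev]))
    return new, log_rev - log_fwd


# --- the chain ---------------------------------------------------------------


def _evaluate(
    tree: CNATree,
    nu: float,
    counts,
    lik_base: LikelihoodParams,
    prior: PriorParams,
    score_mode: str,
    weights,
    root_cache: dict,
) -> tuple[np.ndarray, AttachmentTable | None, ScoreBreakdown]:
    C = compute_genotypes(tree)
    ok = validate_tree(tree, C)
    if not ok[0]:
        return C, None, ScoreBreakdown.invalid(score_mode)
    params = replace(lik_base, nu=nu)
    key = (nu, tuple(tree.root_ploidy))
    if key not in root_cache:
        root_cache.clear()  # the walk only ever needs the current nu
        root_cache[key] = root_loglik(counts, np.asarray(tree.root_ploidy), params)
    table = attachment_table(tree, counts, params, genotypes=C, cached_root=root_cache[key])
    scorer = max_log_score if score_mode == "max" else sum_log_score
    score = scorer(tree, table, prior, weights=weights, valid=ok)
    return C, table, score


def run_chain(
    tree: CNATree,
    counts,
    iterations: int,
    *,
    nu: float = 1.0,
    lik_params: LikelihoodParams | None = None,
    prior: PriorParams | None = None,
    move_config: MoveConfig | None = None,
    score_mode: str = "max",
    weights: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    callback=None,
    state_filter=None,
) -> ChainResult:
    """Run a Metropolis-Hastings chain and track the best state seen.

    ``counts`` is a :class:`~cnatree.breakpoints.SegmentCounts`; ``weights``
    optionally gives per-row multiplicities (cluster sizes).  ``callback``,
    if given, is invoked with the current :class:`ChainState` after every
    iteration (accepted or not) — useful for visit-frequency diagnostics.
    Fully deterministic for a fixed integer seed.
    """
    rng = np.random.default_rng(rng)
    lik_base = lik_params or LikelihoodParams()
    prior = prior or PriorParams()
    cfg = move_config or MoveConfig()
    probs = cfg.probabilities()
    root_cache: dict = {}

    C, table, score = _evaluate(
        tree, nu, counts, lik_base, prior, score_mode, weights, root_cache
    )
    if table is None:
        raise ValueError("initial tree is invalid")
    state = ChainState(tree, nu, C, table, score)
    best = state
    improvements: list[tuple[int, str, float]] = [(0, "init", score.total)]
    accepted = 0

    lo, hi = cfg.nu_bounds
    for it in range(1, iterations + 1):
        move = MOVE_NAMES[int(rng.choice(len(MOVE_NAMES), p=probs))]
        proposal = None
        new_nu = state.nu
        if move == "prune_reattach":
            proposal = propose_prune_reattach(state.tree, rng)
        elif move == "label_swap":
            proposal = propose_label_swap(state.tree, rng)
        elif move == "event_change":
            proposal = propose_event_change(state.tree, rng)
        elif move == "add_remove_node":
            proposal = propose_add_remove_node(state.tree, rng, prior)
        elif move == "condense_split":
            proposal = propose_condense_split(state.tree, rng)
        elif move == "genotype_preserving":
            proposal = propose_genotype_preserving(state.tree, state.genotypes, rng, prior)
        else:  # nu_walk
            cand = math.exp(math.log(state.nu) + rng.normal(0.0, cfg.nu_walk_sd))
            if cfg.nu_walk_sd == 0:
                cand = state.nu
            if lo <= cand <= hi:
                proposal = (state.tree, 0.0)
                new_nu = cand

        if proposal is not None and state_filter is not None:
            if not state_filter(proposal[0]):
                proposal = None  # out-of-bounds proposals are plain rejections
        if proposal is not None:
            new_tree, log_ratio = proposal
            C2, table2, score2 = _evaluate(
                new_tree, new_nu, counts, lik_base, prior, score_mode, weights, root_cache
            )
            if table2 is not None:
                log_alpha = score2.total - state.score.total + log_ratio
                if log_alpha >= 0 or rng.random() < math.exp(log_alpha):
                    state = ChainState(new_tree, new_nu, C2, table2, score2, it)
                    accepted += 1
                    if score2.total > best.score.total:
                        best = state
                        improvements.append((it, move, score2.total))
        if callback is not None:
            callback(state)
    return ChainResult(best, state, improvements, accepted, iterations)
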