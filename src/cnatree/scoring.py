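"""Tree-level posterior scores.

Two scores rank candidate (tree, events) pairs: the marginal ("sum") score
averages every cell over all attachment nodes, while the maximized ("max")
score places each cell at its best node.  Both are gated by the biological
validity constraints (an invalid tree scores -inf) and weighted by a prior on
the event vector plus, for the sum score, an explicit penalty on tree size
that counters the combinatorial growth of larger trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
from scipy.special import logsumexp

from .data_model import CNATree, validate_tree
from .likelihood import AttachmentTable

__all__ = [
    "PriorParams",
    "ScoreBreakdown",
    "event_vector_log_prior",
    "tree_log_penalty",
    "sum_log_score",
    "max_log_score",
    "best_attachments",
]


@dataclass(frozen=True)
class PriorParams:
    """Event-vector prior and tree-size penalty parameters.

    The prior mirrors the generative process for events: a node touches
    ``1 + Poisson(lambda_s)`` segments, each changed by ``1 +
    Poisson(lambda_c)`` copies with a uniform sign.  ``kappa`` is the rate of
    the exponential tree-size penalty exp(-kappa * n).
    """

    lambda_s: float = 0.1
    lambda_c: float = 0.2
    kappa: float = 1.0

    def __post_init__(self):
        if min(self.lambda_s, self.lambda_c, self.kappa) < 0:
            raise ValueError("prior parameters must be non-negative")


@dataclass
class ScoreBreakdown:
    """Additive decomposition of a tree score (all terms in log space)."""

    log_event_prior: float
    log_tree_penalty: float
    log_attachment_term: float
    mode: str  # "sum" | "max"

    @property
    def total(self) -> float:
        return self.log_event_prior + self.log_tree_penalty + self.log_attachment_term

    @classmethod
    def invalid(cls, mode: str) -> "ScoreBreakdown":
        return cls(-np.inf, 0.0, 0.0, mode)


def poisson_logpmf(k: int, lam: float) -> float:
    """Closed-form Poisson log-PMF (scipy's dispatch is too slow in hot loops)."""
    if lam == 0.0:
        return 0.0 if k == 0 else -math.inf
    return k * math.log(lam) - lam - math.lgamma(k + 1)


_LOG_HALF = math.log(0.5)


def event_log_prior(event, params: PriorParams) -> float:
    """Log prior of a single node's event under the shifted-Poisson model."""
    lp = poisson_logpmf(len(event) - 1, params.lambda_s)
    for delta in event.values():
        lp += poisson_logpmf(abs(delta) - 1, params.lambda_c) + _LOG_HALF
    return lp


def event_vector_log_prior(tree: CNATree, params: PriorParams) -> float:
    """Sum of per-node event log priors (0 for the root-only tree)."""
    return sum(event_log_prior(ev, params) for ev in tree.events)


def tree_log_penalty(n: int, params: PriorParams) -> float:
    """log P'(T) = -kappa * n, discouraging needlessly large trees."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return -params.kappa * n


def _weighted(values: np.ndarray, weights: np.ndarray | None) -> float:
    return float(values.sum() if weights is None else np.dot(weights, values))


def sum_log_score(
    tree: CNATree,
    table: AttachmentTable,
    params: PriorParams,
    weights: np.ndarray | None = None,
    valid: tuple[bool, str] | None = None,
) -> ScoreBreakdown:
    """Marginal log posterior: cells averaged over all attachment nodes.

    ``weights`` (cluster sizes) multiply each row's contribution, so a row of
    averaged cluster counts stands in for its members.  Invalid trees score
    -inf.
    """
    n = tree.n
    if table.n_nodes != n:
        raise ValueError("attachment table does not match tree")
    if (valid or validate_tree(tree))[0] is False:
        return ScoreBreakdown.invalid("sum")
    per_cell = table.root_loglik + logsumexp(table.loglik, axis=1)
    attach = _weighted(per_cell, weights)
    m = table.n_cells if weights is None else float(np.sum(weights))
    attach -= (n - 1 + m) * np.log(n + 1)
    return ScoreBreakdown(
        event_vector_log_prior(tree, params), tree_log_penalty(n, params), attach, "sum"
    )


def max_log_score(
    tree: CNATree,
    table: AttachmentTable,
    params: PriorParams,
    weights: np.ndarray | None = None,
    valid: tuple[bool, str] | None = None,
) -> ScoreBreakdown:
    """Maximized log score: each cell at its best node; no size penalty term."""
    n = tree.n
    if table.n_nodes != n:
        raise ValueError("attachment table does not match tree")
    if (valid or validate_tree(tree))[0] is False:
        return ScoreBreakdown.invalid("max")
    per_cell = table.root_loglik + table.loglik.max(axis=1)
    attach = _weighted(per_cell, weights) - (n - 1) * np.log(n + 1)
    return ScoreBreakdown(event_vector_log_prior(tree, params), 0.0, attach, "max")


def best_attachments(table: AttachmentTable) -> np.ndarray:
    """Per-cell argmax attachment node (ties go to the lowest index)."""
    return table.loglik.argmax(axis=1)
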