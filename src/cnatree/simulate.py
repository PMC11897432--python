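"""Generative model for synthetic single-cell CNA datasets.

The generator draws a random event tree, attaches cells to its nodes
uniformly, expands node genotypes into per-bin copy-number profiles, and
samples overdispersed read counts per cell from a Dirichlet-multinomial.
Defaults reflect a shallow whole-genome study design: a genome of 10 000
bins split into 40 segments, trees of 20 event nodes, 400 cells with 2-8
reads per bin on average, concentration nu = 4.  Per-node events touch
``1 + Poisson(0.1)`` segments, each changed by ``1 + Poisson(0.2)`` copies
with a uniform sign; trees violating the validity constraints are rejected
and resampled.  Ground truth (tree, attachments, profiles) is retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .breakpoints import BinCountMatrix, SegmentMap
from .data_model import CNATree, Event, compute_genotypes, validate_tree

__all__ = [
    "SimSettings",
    "SimulationTruth",
    "sample_segments",
    "sample_tree",
    "attach_and_profile",
    "sample_counts",
    "generate_dataset",
]


@dataclass(frozen=True)
class SimSettings:
    n_bins: int = 10_000
    n_nodes: int = 20
    n_segments: int = 40
    reads_per_bin: float = 4.0
    n_cells: int = 400
    lambda_s: float = 0.1
    lambda_c: float = 0.2
    nu_sim: float = 4.0
    eta: float = 1e-4
    root_ploidy: int = 2
    seed: int | None = None

    def __post_init__(self):
        if self.n_segments > self.n_bins:
            raise ValueError("cannot have more segments than bins")
        if min(self.n_bins, self.n_nodes, self.n_segments, self.n_cells) <= 0:
            raise ValueError("sizes must be positive")


@dataclass
class SimulationTruth:
    tree: CNATree
    segmap: SegmentMap
    sigma: np.ndarray  # true attachment node per cell
    profiles: np.ndarray  # cells x bins integer copy numbers
    counts: BinCountMatrix
    settings: SimSettings


def sample_segments(n_bins: int, n_segments: int, rng: np.random.Generator) -> SegmentMap:
    """Uniform composition of ``n_bins`` into ``n_segments`` parts >= 1."""
    if n_segments == n_bins:
        edges = np.arange(n_bins + 1)
    else:
        cuts = np.sort(rng.choice(n_bins - 1, size=n_segments - 1, replace=False)) + 1
        edges = np.concatenate([[0], cuts, [n_bins]])
    return SegmentMap(edges[:-1], edges[1:])


def _sample_event(rng: np.random.Generator, K: int, lambda_s: float, lambda_c: float) -> Event:
    while True:
        k = int(rng.poisson(lambda_s)) + 1
        if k <= K:
            break
    segs = rng.choice(K, size=k, replace=False)
    deltas = {}
    for seg in segs:
        mag = int(rng.poisson(lambda_c)) + 1
        deltas[int(seg)] = mag if rng.random() < 0.5 else -mag
    return Event(deltas)


def sample_tree(settings: SimSettings, rng: np.random.Generator) -> CNATree:
    """Random labelled tree with prior-distributed events, rejection-validated.

    The parent of node ``i`` is uniform over the root and earlier nodes
    (uniform over increasing-labelled rooted trees).  Invalid draws are fully
    resampled.
    """
    K = settings.n_segments
    ploidy = (settings.root_ploidy,) * K
    while True:
        parents = [int(rng.integers(i)) for i in range(1, settings.n_nodes + 1)]
        events = tuple(
            _sample_event(rng, K, settings.lambda_s, settings.lambda_c)
            for _ in range(settings.n_nodes)
        )
        tree = CNATree(parents, events, ploidy)
        if validate_tree(tree)[0]:
            return tree


def attach_and_profile(
    tree: CNATree, segmap: SegmentMap, n_cells: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform attachments and per-bin integer copy-number profiles."""
    sigma = rng.integers(0, tree.n + 1, size=n_cells)
    genotypes = compute_genotypes(tree)
    profiles = segmap.expand(genotypes[sigma])
    return sigma, profiles


def sample_counts(
    profiles: np.ndarray, settings: SimSettings, rng: np.random.Generator
) -> BinCountMatrix:
    """Dirichlet-multinomial reads per cell over bins.

    Per cell, bin probabilities are a Dirichlet draw with parameters
    ``nu_sim * state`` (eta-floored) and the total read count is exactly
    ``reads_per_bin * n_bins``.
    """
    n_cells, n_bins = profiles.shape
    total = int(round(settings.reads_per_bin * n_bins))
    counts = np.empty((n_cells, n_bins))
    alpha = settings.nu_sim * np.maximum(profiles.astype(float), settings.eta)
    for j in range(n_cells):
        p = rng.dirichlet(alpha[j])
        counts[j] = rng.multinomial(total, p)
    return BinCountMatrix(counts)


def generate_dataset(settings: SimSettings, rng=None) -> SimulationTruth:
    """Full generative pipeline; reproducible from ``settings.seed``."""
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    segmap = sample_segments(settings.n_bins, settings.n_segments, rng)
    tree = sample_tree(settings, rng)
    sigma, profiles = attach_and_profile(tree, segmap, settings.n_cells, rng)
    counts = sample_counts(profiles, settings, rng)
    return SimulationTruth(tree, segmap, sigma, profiles, counts, settings)
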