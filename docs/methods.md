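# Methods

## Data model

The input is an m × B matrix of corrected read counts (cells × bins).
Counts are kept real-valued throughout: GC/mappability correction generally
produces non-integer values, and every likelihood below is a product of
gamma-function ratios that accepts non-negative reals. Correction itself is
out of scope; the package consumes corrected counts.

A CNA event tree stores n event nodes as a parent vector (root = 0, nodes
1..n) plus one event per node: a map from segment index to a non-zero net
integer copy change. An event touching a segment twice is normalized to its
net change. The root ploidy is a per-segment vector, so sex chromosomes or
a whole-genome-duplicated baseline (tetraploid root) are expressed directly.
Node genotypes accumulate events from the root down. Two constraints define
validity: a segment at copy number 0 can never be increased in a descendant
(deleted DNA cannot be regained), and no two nodes — root included — may
share a genotype (the duplicate adds nothing the data could distinguish, so
the smaller tree is preferred by fiat).

## Breakpoint detection

Copy-number changes are shared across subsets of cells, so evidence is
pooled. For each bin boundary and each cell, a step model (separate mean
rates in the w bins left and right of the boundary) is compared against a
constant model (one mean over both windows) by maximized log-likelihood
ratio under a negative-binomial observation model with mean μ and shape
ν_bp (variance μ + μ²/ν_bp). Data-dependent lgamma terms cancel between the
nested models, so the statistic needs only window sums; prefix sums give
the whole scan in O(m·B). Per-cell counts are scaled to a common mean first
(read proportions, not depth, carry the signal), per-cell statistics are
rectified at zero and summed over cells, and boundaries whose combined
signal exceeds median + t·MAD are selected greedily in decreasing order,
each claiming a ±min_separation exclusion zone (ties to the lower index).

Parameter defaults and rationale:

* `window` w = 10 bins — events spanning ≥ 10 bins are the design target;
  wider windows (e.g. 100 bins for 20 kb bins) trade resolution for power
  and are exposed as a flag.
* `nu_bp` = 1.0 — a deliberately heavy-tailed per-cell null; single noisy
  cells then contribute little, and discrimination comes from the sum over
  cells. A consequence worth knowing: a single cell's statistic does not
  separate a 2× step from Poisson noise maxima; the combined signal does.
* `threshold_sd` = 6 — chosen from the measured separation between null
  signal peaks (≤ ~5.5 MAD units even at deep coverage) and true-boundary
  signal (≥ ~11 MAD units in the weakest regime we target: a one-copy step
  in 20 % of cells at 8 reads/bin).
* Boundaries whose truncated window holds fewer than 2 bins are set to zero:
  a one-bin window cannot average noise at all.
* Boundary b means the new state starts at bin b (0-based, half-open
  segments); k breakpoints give k+1 segments.

## Likelihood

With segment sizes s_k and a genotype row c, reads fall into segments with
probability c̃_k s_k / Z (Z = Σ c̃_k s_k), where c̃ = max(c, η) and
η = 10⁻⁴ keeps a residual rate for fully deleted segments (mapping errors
produce stray reads). Counts are Dirichlet-multinomial with concentration
ν·Z; the multinomial coefficient is omitted everywhere because it cancels
from every attachment and tree comparison. The large-ν limit is the plain
multinomial, available as a flag.

Attachment log-likelihoods for all cells at all nodes are computed relative
to the root in a single breadth-first traversal: a child differs from its
parent only in its event's segments, so only those product terms — plus the
two normalizer terms through Z for the DM — are updated, giving
O(m·(n + Σ|events|)) instead of O(m·n·K). All per-entry special-function
evaluations are batched into single array calls. The absolute root
log-likelihood depends only on ν and the root ploidy, and is cached and
reused across tree moves; it is recomputed only when the ν walk moves.

## Scores and priors

The event-vector prior mirrors the generative process used for synthetic
data: a node touches 1 + Poisson(λ_s) segments (λ_s = 0.1), each changed by
1 + Poisson(λ_c) copies (λ_c = 0.2) with a uniform sign; segment sets are
unordered and unconstrained by adjacency. Making the inference prior equal
to the simulator keeps the two consistent. The tree-size penalty is
P′(T) = exp(−κ·n) with κ = 1.0 — the simplest monotone penalty for the
combinatorial growth of larger trees, exposed as configuration and used by
the sum score only.

The sum score marginalizes each cell over all n+1 attachments with the
(n+1)^(n−1+m) normalizer; the max score places each cell at its best node
and drops the size penalty. Invalid trees score −∞ in both. The default
search score is max, which recovers per-cell profiles better in our
simulations (and supports the cluster-weighted likelihood: a cluster row
scored with weight w contributes exactly like w identical cells, an
identity the tests assert).

## MCMC

Seven moves, sampled with fixed weights (structural moves 1, the
genotype-preserving reattachment 0.4, the ν walk 1):

1. **Prune & reattach** — a uniform non-root node's subtree moves under a
   uniform target outside the subtree. The subtree, and hence the target
   count, is identical in both directions, so the Hastings ratio is 1.
2. **Label swap** — two nodes exchange events; symmetric.
3. **Event change** — one copy is added or removed on a uniformly chosen
   (node, segment, sign) triple. This single ±1 step covers adding a new
   segment, growing, shrinking and deleting an entry; it is its own reverse
   at equal probability, so the ratio is 1. Emptying a node's only entry
   proposes a zero-effect node, which the validity gate rejects.
4. **Add/remove node** — add: a new node with a prior-drawn event is
   inserted under a uniform parent at a uniform label, adopting each
   existing child with probability ½; remove: a uniform node is deleted,
   children re-parented, events discarded. The ratio combines the event
   proposal density (with its Poisson-truncation normalizer), the
   child-adoption factors and the label-choice factors — the latter cancel
   between the paired directions but not within one, and both are included.
5. **Condense/split** — an edge between two event nodes merges (summed
   deltas), or a node with ≥ 2 entries splits into parent + child with the
   entries partitioned uniformly over ordered non-empty assignments and
   each former child re-assigned with probability ½. A condense whose two
   event sets share a segment has no reconstructing split, so its reverse
   probability is zero and the proposal is rejected — reversibility is kept
   at the cost of some rejections.
6. **Genotype-preserving prune & reattach** — node i reattaches under
   target t with its event rewritten to C_i − C_t, which preserves every
   genotype in the tree (plain reattachment never can, because distinct
   nodes have distinct genotypes). Only the event prior changes, so the
   whole neighbourhood is enumerated (vectorized over the genotype matrix)
   and a member sampled proportionally to exp(prior change); the reverse
   neighbourhood's normalizer enters the ratio.
7. **ν walk** — Gaussian step on log ν (sd 0.1), flat prior within
   [10⁻², 10⁶]; out-of-bounds proposals are rejected.

Proposals producing invalid trees are rejected rather than resampled. The
chain records the best state ever visited and is bit-reproducible given a
seed. Exactness of the stationary distribution is asserted by a test that
compares 200 000-iteration visit frequencies against the fully enumerated
posterior of a small state space (total variation < 0.05); this check is
what caught a missing label-choice factor during development, so it is kept
as a permanent guard.

## Staged search

Stage one clusters cells (Ward linkage on depth-normalized segment rates,
cluster count chosen by the Calinski–Harabasz index, 2..20 candidates) and
averages counts per cluster, weighting each row by its size. The starting
tree comes from the rounded normalized cluster profiles (each row scaled so
its size-weighted median state equals the root baseline): a Ward dendrogram
is annotated top-down with unanimity ancestral states — a segment's value is
the one all descendant leaves share, else the parent's value, and a segment
at zero in the parent stays zero — then zero-change edges are contracted and
duplicate genotypes merged, so the initial tree is always valid. A bank of
chains runs until at least half score within 5 log-units of the best
(repeating from the best tree so far, bounded by max_rounds).

Stage two moves to the full single-cell data: ν is first learned by a
ν-only chain with the stage-one tree fixed, then full chains run from that
tree; the stop criterion is the score window or a mean pairwise tree
distance below 0.02 among the best half of chains. The distance is the τ
metric below, which is already normalized per cell pair (RMS) and per event
(n_s/n_b) — we use it directly rather than rescaling by a separate offset
unit. The final tree plus per-cell maximum-likelihood attachments give the
m × B integer copy-number matrix by expanding genotypes over segments.

## Synthetic data

The generator emulates a shallow whole-genome single-cell study: 10 000
bins partitioned into 40 (or 80) segments by a uniform composition, a
20-node tree with uniform-parent structure (each node's parent uniform over
the root and earlier nodes — uniform over increasing-labelled rooted trees,
not all labelled trees), events drawn from the shifted-Poisson model above,
rejection-resampling until valid, 400 cells attached uniformly, and reads
per bin Dirichlet-multinomial with ν = 4 at 2–8 reads per bin (total reads
fixed at reads_per_bin × n_bins per cell). What it does not emulate:
residual GC/mappability bias, outlier bins, doublets or cycling cells, and
segment-level breakpoint misplacement within bins — so passing recovery
tests demonstrate correctness of the inference machinery under the model's
own assumptions, not robustness to artefacts of real data.

## Evaluation metrics

Δ is the RMSE between true and inferred per-cell per-bin copy numbers. The
cell-pair distance d_ij accumulates, bin by bin, the absolute state changes
along the tree path between two cells' attachment nodes (each event
weighted by the bins it spans), scaled by n_s/n_b so one single-copy,
single-segment event of typical size has unit weight; τ is the RMS
difference between two trees' upper-triangular distance matrices.
Convergence diagnostics keep the best half of a chain bank and report mean
pairwise τ and mean log-score gap to the best chain.

## Problem sizes used in the checks

The recovery check runs ten cohorts at 1 000 bins, 20 segments, 10 nodes,
50 cells, 4 reads/bin and ν = 4 — the same generative law as the full
design at reduced dimension — with 3 chains of 400·n iterations and at most
two robustness rounds per stage. These sizes are the package's validation
conditions; the defaults in `SearchConfig` (10 chains, 4 000·n) match the
full-scale protocol.

## Known limitations

* The exponential tree-size penalty is a stand-in for a combinatorial
  correction; under the max score (no penalty) trees can acquire extra
  nodes that absorb sampling noise at moderate depth. Copy-number calls are
  largely insensitive to this, tree-size estimates less so.
* Root-ploidy comparison is reported, not decided: a diploid genome and a
  tetraploid genome with doubled states induce identical read proportions,
  so only the event prior (smaller events win) separates them; odd states
  are what make genome doubling detectable.
* Breakpoints are fixed before tree inference; segmentation errors
  propagate downstream.
* Allele-specific states and per-locus likelihoods are out of scope.
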