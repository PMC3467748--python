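"""Partition the unlabeled gene set by distance filtering and label propagation.

The unlabeled set U is split into four disjoint subsets graded by how
likely each gene is to be a hidden disease gene:

1. *Reliable negatives* (RN): genes whose Euclidean distance to the
   positive representative vector (the normalised sum of all positive
   vectors) exceeds the mean distance of U to that vector.
2. The remaining genes are scored by random-walk label propagation over a
   sparse gene similarity network: positives carry prior +1, reliable
   negatives carry prior -|P|/|RN| (so both sides contribute equal total
   mass), and the iteration ``G_r = alpha * S @ G_{r-1} + (1-alpha) * G_0``
   with the symmetrically normalised adjacency ``S = D^{-1/2} W D^{-1/2}``
   is run to a fixed point.
3. Genes with positive steady-state score become *likely positives* (LP);
   non-positive scores are split at their mean into *likely negatives*
   (LN, at or below the mean) and *weak negatives* (WN, the rest).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


@dataclass
class SimilarityNetwork:
    """Sparse symmetric gene similarity graph over P ∪ U."""

    nodes: list[str]
    weights: sp.csr_matrix  # symmetric, zero diagonal
    q: int
    sigma: float

    @property
    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.nodes)}


@dataclass
class PartitionResult:
    """The five labeled sets plus per-gene propagation scores."""

    positives: set[str]
    reliable_negative: set[str]
    likely_positive: set[str]
    likely_negative: set[str]
    weak_negative: set[str]
    scores: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    iterations: int = 0

    def set_of(self, gene: str) -> str:
        for name, members in self.as_dict().items():
            if gene in members:
                return name
        raise KeyError(gene)

    def as_dict(self) -> dict[str, set[str]]:
        return {
            "P": self.positives,
            "RN": self.reliable_negative,
            "LP": self.likely_positive,
            "LN": self.likely_negative,
            "WN": self.weak_negative,
        }


def positive_representative(p_matrix: np.ndarray, mode: str = "mean") -> np.ndarray:
    """Normalised component-wise sum of the positive vectors.

    ``mode="mean"`` (default) divides the sum by |P|, yielding the class
    centroid on the same scale as the gene vectors, so Euclidean distance
    to it measures dissimilarity from a typical positive.  ``mode="unit"``
    scales the sum to unit Euclidean norm instead; distances to a
    unit-norm representative are dominated by each gene's own norm when
    feature counts vary, which makes the reliable-negative filter
    uninformative, hence the centroid default.
    """
    p_matrix = np.atleast_2d(np.asarray(p_matrix, dtype=float))
    if p_matrix.shape[0] == 0:
        raise ValueError("positive set is empty")
    total = p_matrix.sum(axis=0)
    norm = np.linalg.norm(total)
    if norm == 0.0:
        raise ValueError("positive representative has zero norm")
    if mode == "mean":
        return total / p_matrix.shape[0]
    if mode == "unit":
        return total / norm
    raise ValueError(f"unknown normalisation mode {mode!r}")


def extract_reliable_negatives(
    pr: np.ndarray, u_matrix: np.ndarray, u_ids: list[str]
) -> set[str]:
    """Unlabeled genes strictly farther from the positive representative
    than the average unlabeled gene."""
    u_matrix = np.atleast_2d(np.asarray(u_matrix, dtype=float))
    dist = np.linalg.norm(u_matrix - pr, axis=1)
    ave = dist.mean()
    return {g for g, d in zip(u_ids, dist) if d > ave}


def build_similarity_network(
    gene_ids: list[str],
    vectors: np.ndarray,
    q: int = 10,
    sigma: float | None = None,
) -> SimilarityNetwork:
    """Gaussian-kernel similarity graph sparsified to each node's top Q
    neighbours (union-symmetrised).

    ``W_ij = exp(-||v_i - v_j||^2 / (2 sigma^2))`` with the bandwidth
    defaulting to the median nonzero pairwise distance.
    """
    n = len(gene_ids)
    if n < 2:
        raise ValueError("need at least two genes to build a network")
    if q < 1:
        raise ValueError("q must be >= 1")
    if q >= n:
        logger.warning("q=%d >= %d nodes; network is complete", q, n)
        q = n - 1

    dist = squareform(pdist(np.asarray(vectors, dtype=float)))
    if sigma is None:
        nonzero = dist[np.triu_indices(n, k=1)]
        nonzero = nonzero[nonzero > 0]
        sigma = float(np.median(nonzero)) if nonzero.size else 1.0
    w = np.exp(-(dist**2) / (2.0 * sigma**2))
    np.fill_diagonal(w, 0.0)

    # per-node top-Q by weight; stable tie-break on index via stable argsort
    keep = np.zeros_like(w, dtype=bool)
    order = np.argsort(-w, axis=1, kind="stable")
    rows = np.repeat(np.arange(n), q)
    keep[rows, order[:, :q].ravel()] = True
    keep |= keep.T  # union symmetrisation
    w = np.where(keep, w, 0.0)

    return SimilarityNetwork(list(gene_ids), sp.csr_matrix(w), q, sigma)


def init_priors(
    nodes: list[str], positives: set[str], reliable_negatives: set[str]
) -> np.ndarray:
    """Prior vector: +1 on P, -|P|/|RN| on RN, 0 elsewhere; sums to zero."""
    if not reliable_negatives:
        raise ValueError(
            "reliable negative set is empty; the distance filter kept nothing "
            "— loosen the reliable-negative threshold or check the features"
        )
    if not positives:
        raise ValueError("positive set is empty")
    g0 = np.zeros(len(nodes))
    neg_value = -len(positives) / len(reliable_negatives)
    for i, gene in enumerate(nodes):
        if gene in positives:
            g0[i] = 1.0
        elif gene in reliable_negatives:
            g0[i] = neg_value
    return g0


def _normalised_adjacency(weights: sp.spmatrix) -> sp.csr_matrix:
    """Symmetric normalisation D^{-1/2} W D^{-1/2}; isolated nodes get
    all-zero rows."""
    degree = np.asarray(weights.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        inv_sqrt = 1.0 / np.sqrt(degree)
    inv_sqrt[~np.isfinite(inv_sqrt)] = 0.0
    d_half = sp.diags(inv_sqrt)
    return (d_half @ weights @ d_half).tocsr()


def propagate(
    net: SimilarityNetwork,
    g0: np.ndarray,
    alpha: float = 0.8,
    epsilon: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, int, bool]:
    """Iterate the propagation update to its steady state.

    Returns ``(scores, iterations, converged)``; convergence is declared
    when the L1 change between consecutive iterates drops below
    ``epsilon``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    s = _normalised_adjacency(net.weights)
    g = g0.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g_next = alpha * (s @ g) + (1.0 - alpha) * g0
        if np.abs(g_next - g).sum() < epsilon:
            g = g_next
            converged = True
            break
        g = g_next
    if not converged:
        logger.warning("propagation did not converge in %d iterations", max_iter)
    return g, it, converged


def propagate_direct(net: SimilarityNetwork, g0: np.ndarray, alpha: float = 0.8) -> np.ndarray:
    """Closed-form steady state ``(1-alpha)(I - alpha S)^{-1} G_0``."""
    s = _normalised_adjacency(net.weights).toarray()
    n = s.shape[0]
    return (1.0 - alpha) * np.linalg.solve(np.eye(n) - alpha * s, g0)


def partition_unlabeled(scores: dict[str, float]) -> tuple[set[str], set[str], set[str]]:
    """Split U−RN by propagation score into (LP, LN, WN).

    Positive scores are likely positives; non-positive scores split at
    their mean — at or below the mean is likely negative, above it (but
    still non-positive) is weak negative.
    """
    lp = {g for g, s in scores.items() if s > 0}
    rest = {g: s for g, s in scores.items() if s <= 0}
    if not rest:
        return lp, set(), set()
    mean_rest = float(np.mean(list(rest.values())))
    ln = {g for g, s in rest.items() if s <= mean_rest}
    wn = set(rest) - ln
    return lp, ln, wn


def partition_genes(
    p_ids: list[str],
    u_ids: list[str],
    p_matrix: np.ndarray,
    u_matrix: np.ndarray,
    q: int = 10,
    alpha: float = 0.8,
    epsilon: float = 1e-6,
    max_iter: int = 1000,
    sigma: float | None = None,
    pr_mode: str = "mean",
) -> PartitionResult:
    """Full partition of U into RN / LP / LN / WN.

    Distance filtering extracts RN, then label propagation over the joint
    similarity network scores the remaining unlabeled genes.
    """
    pr = positive_representative(p_matrix, mode=pr_mode)
    rn = extract_reliable_negatives(pr, u_matrix, u_ids)

    nodes = list(p_ids) + list(u_ids)
    vectors = np.vstack([np.atleast_2d(p_matrix), np.atleast_2d(u_matrix)])
    net = build_similarity_network(nodes, vectors, q=q, sigma=sigma)
    g0 = init_priors(nodes, set(p_ids), rn)
    steady, iterations, converged = propagate(net, g0, alpha, epsilon, max_iter)

    score_map = dict(zip(nodes, steady.tolist()))
    remaining = {g: score_map[g] for g in u_ids if g not in rn}
    lp, ln, wn = partition_unlabeled(remaining)

    return PartitionResult(
        positives=set(p_ids),
        reliable_negative=rn,
        likely_positive=lp,
        likely_negative=ln,
        weak_negative=wn,
        scores={g: score_map[g] for g in u_ids},
        converged=converged,
        iterations=iterations,
    )
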