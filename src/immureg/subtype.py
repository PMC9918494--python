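"""Immune-subtype discovery by NMF consensus clustering.

Samples are clustered on immune-related gene expression with non-negative
matrix factorization (multiplicative Frobenius updates, monotone objective).
Stability over repeated seeded runs is summarized in a samples x samples
consensus matrix; the factorization rank is chosen where the cophenetic
correlation coefficient of the consensus dendrogram starts its sustained
decline, and silhouette width quantifies cluster robustness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

logger = logging.getLogger("immureg")

_EPS = 1e-12


@dataclass
class NMFResult:
    W: np.ndarray  # genes x rank
    H: np.ndarray  # rank x samples
    rank: int
    reconstruction_error: float  # Frobenius norm of X - WH
    seed: int
    objective_trajectory: np.ndarray  # per-iteration Frobenius error


@dataclass
class ConsensusResult:
    consensus: np.ndarray  # samples x samples in [0, 1]
    cophenetic: float
    silhouette: float
    labels: np.ndarray  # 1..rank per sample
    rank: int


def shift_nonnegative(X: np.ndarray) -> np.ndarray:
    """Shift by the global minimum so NMF's non-negativity holds.

    Quantile-normalized expression can be negative; the shift preserves all
    between-sample structure.
    """
    X = np.asarray(X, dtype=float)
    lo = X.min()
    return X - lo if lo < 0 else X.copy()


def nmf_factorize(
    X: np.ndarray,
    rank: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> NMFResult:
    """Multiplicative-update NMF minimizing ||X - WH||_F.

    Iterates until the relative change of the objective drops below ``tol``
    or ``max_iter`` is reached; the objective is non-increasing across
    iterations (standard Lee-Seung updates).
    """
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("X must be non-negative (see shift_nonnegative)")
    if not X.any():
        raise ValueError("X is all zeros")
    if rank < 1 or rank >= min(X.shape):
        raise ValueError(f"rank must be in [1, {min(X.shape) - 1}]")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.mean() / rank)
    W = rng.uniform(0.0, 1.0, size=(X.shape[0], rank)) * scale + _EPS
    H = rng.uniform(0.0, 1.0, size=(rank, X.shape[1])) * scale + _EPS

    errors = []
    prev = np.inf
    for _ in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        err = float(np.linalg.norm(X - W @ H))
        errors.append(err)
        if prev - err < tol * max(prev, 1.0):
            break
        prev = err
    return NMFResult(
        W=W, H=H, rank=rank, reconstruction_error=errors[-1], seed=seed,
        objective_trajectory=np.array(errors),
    )


def _run_labels(res: NMFResult) -> np.ndarray:
    """Per-run hard assignment: argmax row of H, clusters 1..rank."""
    return res.H.argmax(axis=0) + 1


def consensus_cluster(
    X: np.ndarray,
    rank: int,
    n_runs: int = 50,
    base_seed: int = 20210101,
    max_iter: int = 500,
    tol: float = 1e-6,
    sample_fraction: float = 0.8,
    feature_fraction: float = 1.0,
) -> ConsensusResult:
    """Co-clustering frequency over ``n_runs`` seeded NMF restarts.

    Each run factorizes a random ``sample_fraction`` subset of the samples
    on a random ``feature_fraction`` subset of the genes (Monti-style
    resampling, as in consensus clustering practice: with random restarts
    alone, a fully converged NMF can be identical across runs at every rank
    and stability would never discriminate ranks; perturbing the cohort
    makes over-fitted splits flicker). consensus[i, j] is the fraction of co-sampled runs assigning
    samples i and j to the same factor. Final labels come from
    average-linkage hierarchical clustering of 1 - consensus cut at ``rank``
    clusters; the cophenetic coefficient is the Pearson correlation between
    those distances and the dendrogram's cophenetic distances. Runs with an
    empty cluster are kept (the consensus stays well defined) but logged.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if not 0 < sample_fraction <= 1 or not 0 < feature_fraction <= 1:
        raise ValueError("sample_fraction/feature_fraction must be in (0, 1]")
    n = X.shape[1]
    n_feat = X.shape[0]
    co_cluster = np.zeros((n, n))
    co_sampled = np.zeros((n, n))
    for run in range(n_runs):
        rng = np.random.default_rng(base_seed + run)
        if sample_fraction < 1:
            cols = np.sort(rng.choice(n, max(int(sample_fraction * n), rank + 1),
                                      replace=False))
        else:
            cols = np.arange(n)
        if feature_fraction < 1:
            rows = np.sort(rng.choice(n_feat, max(int(feature_fraction * n_feat), 2),
                                      replace=False))
        else:
            rows = np.arange(n_feat)
        res = nmf_factorize(X[np.ix_(rows, cols)], rank, seed=base_seed + run,
                            max_iter=max_iter, tol=tol)
        labels = _run_labels(res)
        if len(np.unique(labels)) < rank:
            logger.warning("NMF run %d left %d cluster(s) empty",
                           run, rank - len(np.unique(labels)))
        co_cluster[np.ix_(cols, cols)] += labels[:, None] == labels[None, :]
        co_sampled[np.ix_(cols, cols)] += 1
    with np.errstate(invalid="ignore"):
        consensus = np.where(co_sampled > 0, co_cluster / np.maximum(co_sampled, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    labels = hierarchy.fcluster(Z, t=rank, criterion="maxclust")
    if condensed.std() == 0:
        cophenetic = 1.0  # perfectly consistent runs: all distances equal
    else:
        cophenetic, _ = hierarchy.cophenet(Z, condensed)
        cophenetic = float(cophenetic)
    if len(np.unique(labels)) < 2:
        silhouette = 0.0
    else:
        silhouette = float(silhouette_score(dist, labels, metric="precomputed"))
    return ConsensusResult(
        consensus=consensus, cophenetic=cophenetic, silhouette=silhouette,
        labels=labels, rank=rank,
    )


def pick_rank_from_profile(
    ranks: list[int], cophenetics: list[float], delta: float = 0.005
) -> tuple[int, bool]:
    """The rank at which the cophenetic profile starts decreasing.

    That is the profile's peak: the profile rises (or holds) up to the
    optimal rank and declines beyond it, so the peak rank is returned, with
    ties broken toward the larger rank. ``declined`` reports whether any
    later rank actually falls more than ``delta`` below the peak; when the
    peak is the final candidate no decline was observed and the caller is
    warned that the range may be too narrow.
    """
    c = np.asarray(cophenetics, dtype=float)
    peak = len(c) - 1 - int(np.argmax(c[::-1]))  # argmax, last on exact ties
    declined = peak < len(c) - 1 and bool((c[peak + 1:] < c[peak] - delta).any())
    return ranks[peak], declined


def select_rank(
    X: np.ndarray,
    ranks: range | list[int] = range(2, 7),
    n_runs: int = 50,
    base_seed: int = 20210101,
    delta: float = 0.005,
    max_iter: int = 500,
    tol: float = 1e-6,
    sample_fraction: float = 0.8,
    feature_fraction: float = 1.0,
) -> tuple[int, dict[int, ConsensusResult]]:
    """Consensus-cluster every rank and apply the cophenetic-decline rule."""
    ranks = list(ranks)
    if len(ranks) < 2:
        raise ValueError("need at least 2 candidate ranks")
    if any(b - a != 1 for a, b in zip(ranks, ranks[1:])):
        raise ValueError("ranks must be contiguous ascending")
    results = {
        r: consensus_cluster(X, r, n_runs=n_runs, base_seed=base_seed,
                             max_iter=max_iter, tol=tol,
                             sample_fraction=sample_fraction,
                             feature_fraction=feature_fraction)
        for r in ranks
    }
    best, declined = pick_rank_from_profile(
        ranks, [results[r].cophenetic for r in ranks], delta=delta
    )
    if not declined:
        logger.warning("cophenetic profile never declines; returning max rank %d", best)
    return best, results
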