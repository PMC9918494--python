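"""Population-level network inference by L0-penalized (best-subset) regression.

For each immune-related target gene, within each tumor subtype, the expression
vector y is regressed on a candidate TF expression matrix X by minimizing

    (1/2n) * ||y - X beta||^2  +  gamma * ||beta||_0

with cyclic coordinate descent (hard-thresholding updates) followed by a
local combinatorial search over single add / drop / swap moves, each
candidate support evaluated by its exact OLS refit. gamma is chosen by
K-fold cross-validation over a log-spaced grid with warm starts. The selected
support is refit by OLS to obtain signed coefficients, per-TF p-values, and
the "TF regulatory value" R^2 (the variance fraction of the target explained
by its selected TFs; values clamped to [0, 1]).

The same module computes the per-cluster CNV correlation value: the Spearman
correlation between a gene's expression and its gene-level copy number.

Standardization contract: X columns are z-scored (population sd) and y is
centered before fitting; coefficients are reported on the standardized scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .immucycreg import RegulatoryEdge, spearman

logger = logging.getLogger("immureg")


@dataclass
class L0Fit:
    """Selected TF support for one target gene in one cluster."""

    target: str
    cluster_id: int | str
    support: list[str]
    beta: dict[str, float]
    gamma: float
    r_squared: float
    tf_p_values: dict[str, float]


@dataclass(frozen=True)
class CNVCorrelation:
    gene_id: str
    cluster_id: int | str
    rho: float
    p_value: float


# ---------------------------------------------------------------------------
# core solver


def _check_design(y: np.ndarray, X: np.ndarray) -> None:
    n = len(y)
    if n < 3:
        raise ValueError("need n >= 3 observations")
    if X.shape[0] != n:
        raise ValueError("X and y have incompatible shapes")
    if abs(float(np.mean(y))) > 1e-6 * max(1.0, float(np.std(y))):
        raise ValueError("y must be centered")
    col_mean = X.mean(axis=0)
    col_sd = X.std(axis=0)
    if not (np.abs(col_mean) < 1e-6).all() or not (np.abs(col_sd - 1.0) < 1e-4).all():
        raise ValueError("X columns must be standardized (mean 0, unit variance)")


class _GramProblem:
    """Sufficient statistics (Gram form) for the penalized least squares.

    All OLS refits on small supports become O(|S|^3) solves independent of
    the sample size: G = X'X/n, c = X'y/n, yy = y'y/n.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray):
        self.n, self.p = X.shape
        self.G = X.T @ X / self.n
        self.c = X.T @ y / self.n
        self.yy = float(np.dot(y, y)) / self.n

    def refit(self, support: tuple[int, ...], gamma: float) -> tuple[float, np.ndarray]:
        """(objective, OLS coefficients) of the refit on a support."""
        if not support:
            return 0.5 * self.yy, np.zeros(0)
        idx = list(support)
        Gs = self.G[np.ix_(idx, idx)]
        cs = self.c[idx]
        try:
            beta = np.linalg.solve(Gs, cs)
        except np.linalg.LinAlgError:
            beta = np.linalg.pinv(Gs) @ cs
        rss_n = max(self.yy - float(cs @ beta), 0.0)
        return 0.5 * rss_n + gamma * len(support), beta


def _coordinate_descent_gram(
    prob: _GramProblem, gamma: float, beta0: np.ndarray,
    max_iter: int = 200, tol: float = 1e-12,
) -> np.ndarray:
    """Cyclic hard-thresholding updates; each update is non-increasing.

    For unit-variance columns the coordinate minimizer keeps
    beta_j = z_j (the partial-residual OLS value) iff z_j^2 > 2*gamma.
    """
    beta = beta0.copy()
    # partial residual correlations maintained through the Gram matrix
    Gb = prob.G @ beta
    thresh = 2.0 * gamma
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(prob.p):
            z = beta[j] + prob.c[j] - Gb[j]
            new = z if z * z > thresh else 0.0
            if new != beta[j]:
                Gb += prob.G[:, j] * (new - beta[j])
                max_delta = max(max_delta, abs(new - beta[j]))
                beta[j] = new
        if max_delta < tol:
            break
    return beta


def _local_search(
    prob: _GramProblem, gamma: float, support: tuple[int, ...],
    swap_rounds: int, screen: int,
) -> tuple[float, np.ndarray, tuple[int, ...]]:
    """Best-improving add / drop / swap moves, each support refit exactly.

    When the complement is large, add/swap partners are screened to the
    ``screen`` coordinates most correlated with the current residual
    (exhaustive when the complement fits inside the screen budget).
    """
    best_obj, best_beta = prob.refit(support, gamma)
    best_support = support
    for _ in range(swap_rounds):
        S = set(best_support)
        comp = np.array([k for k in range(prob.p) if k not in S], dtype=int)
        if len(comp) > screen:
            # residual correlation: c_k - G[k, S] beta_S
            if best_support:
                resid_corr = prob.c[comp] - prob.G[np.ix_(comp, list(best_support))] @ best_beta
            else:
                resid_corr = prob.c[comp]
            comp = comp[np.argsort(-np.abs(resid_corr))[:screen]]
        candidates: list[tuple[int, ...]] = []
        for k in comp:  # add
            candidates.append(tuple(sorted(S | {int(k)})))
        for j in best_support:  # drop
            candidates.append(tuple(sorted(S - {j})))
        for j in best_support:  # swap
            for k in comp:
                candidates.append(tuple(sorted((S - {j}) | {int(k)})))
        improved = False
        for cand in candidates:
            obj, b = prob.refit(cand, gamma)
            if obj < best_obj - 1e-12:
                best_obj, best_beta, best_support = obj, b, cand
                improved = True
        if not improved:
            break
    return best_obj, best_beta, best_support


def l0_fit(
    y: np.ndarray,
    X: np.ndarray,
    gamma: float,
    beta0: np.ndarray | None = None,
    swap_rounds: int = 100,
    screen: int = 10,
    _prob: _GramProblem | None = None,
) -> np.ndarray:
    """Solve the L0-penalized least-squares problem for one gamma.

    Coordinate descent to a fixed point, then a local combinatorial search:
    single add / drop / swap moves between the support and its complement,
    each evaluated by exact OLS refit, accepted only when they lower the
    objective. The returned coefficients are the OLS refit on the final
    support, so the objective matches exhaustive best-subset enumeration
    whenever the search reaches the global optimum.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if _prob is None:
        _check_design(y, X)
        _prob = _GramProblem(y, X)
    prob = _prob
    if beta0 is None:
        beta0 = np.zeros(prob.p)
    beta = _coordinate_descent_gram(prob, gamma, beta0)
    support = tuple(np.flatnonzero(beta))
    screen_eff = max(screen, prob.p if prob.p <= 12 else screen)
    best_obj, best_beta, best_support = _local_search(
        prob, gamma, support, swap_rounds, screen_eff
    )
    # second start: hard-thresholded full-OLS coefficients (escapes local
    # optima where several correlated predictors only help jointly); only
    # tried while the thresholded support is small enough to search cheaply
    _, ols = prob.refit(tuple(range(prob.p)), 0.0)
    alt = tuple(int(j) for j in np.flatnonzero(ols * ols > 2.0 * gamma))
    if len(alt) <= 12 and alt != best_support:
        obj2, beta2, sup2 = _local_search(prob, gamma, alt, swap_rounds, screen_eff)
        if obj2 < best_obj:
            best_obj, best_beta, best_support = obj2, beta2, sup2
    out = np.zeros(prob.p)
    out[list(best_support)] = best_beta
    return out


def l0_objective(y: np.ndarray, X: np.ndarray, beta: np.ndarray, gamma: float) -> float:
    n = len(y)
    resid = y - X @ beta
    return float(0.5 * np.dot(resid, resid) / n + gamma * np.count_nonzero(beta))


def default_gamma_grid(y: np.ndarray, X: np.ndarray, n_gammas: int = 50) -> np.ndarray:
    """Descending log-spaced grid from the all-zero threshold downward."""
    n = X.shape[0]
    z = X.T @ y / n
    gamma_max = float(np.max(z * z) / 2.0) * 1.001
    if gamma_max <= 0:
        gamma_max = 1.0
    return np.geomspace(gamma_max, gamma_max * 1e-3, n_gammas)


def l0_path_select(
    y: np.ndarray,
    X: np.ndarray,
    feature_names: Sequence[str],
    gamma_grid: np.ndarray | None = None,
    k_folds: int = 5,
    seed: int = 0,
    target: str = "",
    cluster_id: int | str = "",
    swap_rounds: int = 20,
) -> L0Fit:
    """Fit the gamma path with warm starts and pick gamma by K-fold CV.

    The winning gamma is the largest (sparsest) one whose mean out-of-fold
    squared error lies within one standard error of the minimum (the
    one-standard-error rule; plain CV-min systematically keeps spurious TFs
    on null data). The selected support is refit by OLS on the full data for
    signed coefficients, t-test p-values, and the R^2 regulatory value
    (clamped to [0, 1]).
    """
    from sklearn.model_selection import KFold

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_design(y, X)
    n, p = X.shape
    if gamma_grid is None:
        gamma_grid = default_gamma_grid(y, X)
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    if gamma_grid.size == 0:
        raise ValueError("empty gamma grid")
    if np.any(np.diff(gamma_grid) > 0):
        raise ValueError("gamma grid must be descending")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")

    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_mse = np.zeros((k_folds, len(gamma_grid)))
    for fi, (train_idx, test_idx) in enumerate(kf.split(X)):
        ytr, Xtr = y[train_idx], X[train_idx]
        # re-standardize inside the fold so the solver contract holds
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        ytr_c = ytr - ytr.mean()
        Xtr_s = (Xtr - mu) / sd
        Xte_s = (X[test_idx] - mu) / sd
        prob = _GramProblem(ytr_c, Xtr_s)
        beta = np.zeros(p)
        for gi, gamma in enumerate(gamma_grid):
            beta = l0_fit(ytr_c, Xtr_s, gamma, beta0=beta,
                          swap_rounds=swap_rounds, _prob=prob)
            pred = Xte_s @ beta + ytr.mean()
            fold_mse[fi, gi] = float(np.mean((y[test_idx] - pred) ** 2))
    mean_mse = fold_mse.mean(axis=0)
    se_mse = fold_mse.std(axis=0, ddof=1) / np.sqrt(k_folds)
    gi_min = int(np.argmin(mean_mse))
    within = np.flatnonzero(mean_mse <= mean_mse[gi_min] + se_mse[gi_min])
    best_gi = int(within[0])  # grid is descending: first index = sparsest
    gamma = float(gamma_grid[best_gi])

    # warm-started path on the full data down to the selected gamma
    prob = _GramProblem(y, X)
    beta = np.zeros(p)
    for g in gamma_grid[: best_gi + 1]:
        beta = l0_fit(y, X, g, beta0=beta, swap_rounds=swap_rounds, _prob=prob)
    support_idx = list(np.flatnonzero(beta))
    if len(support_idx) >= n:
        order = np.argsort(-np.abs(beta[support_idx]))
        support_idx = [support_idx[i] for i in order[: n - 1]]
        logger.warning("support size >= n; truncated to the %d largest |beta|", n - 1)

    beta_refit, pvals, r2 = _ols_refit(y, X, support_idx)
    return L0Fit(
        target=target,
        cluster_id=cluster_id,
        support=[feature_names[j] for j in support_idx],
        beta={feature_names[j]: float(b) for j, b in zip(support_idx, beta_refit)},
        gamma=gamma,
        r_squared=r2,
        tf_p_values={feature_names[j]: float(pv) for j, pv in zip(support_idx, pvals)},
    )


def _ols_refit(
    y: np.ndarray, X: np.ndarray, support_idx: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS on the support: coefficients, two-sided t-test p-values, R^2."""
    import statsmodels.api as sm

    tss = float(np.dot(y, y))
    if not support_idx:
        return np.zeros(0), np.zeros(0), 0.0
    if tss == 0:
        return np.zeros(len(support_idx)), np.ones(len(support_idx)), 0.0
    res = sm.OLS(y, X[:, list(support_idx)]).fit()
    r2 = 1.0 - float(res.ssr) / tss
    return np.asarray(res.params), np.asarray(res.pvalues), float(np.clip(r2, 0.0, 1.0))


def enumerate_best_subset(
    y: np.ndarray, X: np.ndarray, gamma: float, max_p: int = 12
) -> tuple[float, tuple[int, ...]]:
    """Exhaustive best-subset reference: OLS refit over all supports.

    Brute-force oracle for small p; O(2^p) and refused beyond ``max_p``.
    """
    n, p = X.shape
    if p > max_p:
        raise ValueError(f"enumeration limited to p <= {max_p}")

    def refit_obj(support: tuple[int, ...]) -> float:
        if not support:
            return float(0.5 * np.dot(y, y) / n)
        Xs = X[:, list(support)]
        beta, *_ = np.linalg.lstsq(Xs, y, rcond=None)
        resid = y - Xs @ beta
        return float(0.5 * np.dot(resid, resid) / n + gamma * len(support))

    best_obj, best_support = refit_obj(()), ()
    for k in range(1, p + 1):
        for support in combinations(range(p), k):
            obj = refit_obj(support)
            if obj < best_obj:
                best_obj, best_support = obj, support
    return best_obj, best_support


# ---------------------------------------------------------------------------
# cluster-level network


def infer_cluster_network(
    expr,  # ExpressionMatrix restricted by cluster labels in sample_meta
    targets: Iterable[str],
    tf_pool: Mapping[str, Sequence[str]],
    gamma_grid: np.ndarray | None = None,
    k_folds: int = 5,
    seed: int = 0,
    clusters: Iterable[int] | None = None,
) -> tuple[list[RegulatoryEdge], list[L0Fit]]:
    """One L0 path fit per (target, cluster); edges from the refit support.

    Edge sign is the sign of the refit coefficient, weight its magnitude
    (standardized scale), p-value the refit t-test. Targets with zero
    variance inside a cluster are skipped with a warning.
    """
    labels = expr.cluster_labels()
    if not labels:
        raise ValueError("expression matrix carries no cluster labels")
    all_clusters = sorted(set(labels.values())) if clusters is None else sorted(clusters)
    edges: list[RegulatoryEdge] = []
    fits: list[L0Fit] = []
    for cluster in all_clusters:
        samples = [s for s, c in labels.items() if c == cluster]
        if len(samples) < 4:
            logger.warning("cluster %s has fewer than 4 samples; skipped", cluster)
            continue
        sub = expr.values[samples]
        for target in targets:
            pool = [t for t in tf_pool.get(target, ()) if t in expr.gene_ids]
            if not pool:
                continue
            yv = sub.loc[target].to_numpy(dtype=float)
            if yv.std() == 0:
                logger.warning("target %s constant in cluster %s; skipped", target, cluster)
                continue
            Xv = sub.loc[pool].to_numpy(dtype=float).T
            sd = Xv.std(axis=0)
            keep = sd > 0
            if not keep.any():
                continue
            pool = [t for t, k in zip(pool, keep) if k]
            Xv = Xv[:, keep]
            Xs = (Xv - Xv.mean(axis=0)) / Xv.std(axis=0)
            yc = yv - yv.mean()
            fit = l0_path_select(
                yc, Xs, pool, gamma_grid=gamma_grid, k_folds=k_folds,
                seed=seed, target=target, cluster_id=cluster,
            )
            fits.append(fit)
            for tf in fit.support:
                coef = fit.beta[tf]
                edges.append(
                    RegulatoryEdge(
                        scope=f"cluster{cluster}",
                        tf_name=tf,
                        target=target,
                        sign="+" if coef > 0 else "-",
                        weight=abs(coef),
                        p_value=fit.tf_p_values[tf],
                    )
                )
    return edges, fits


# ---------------------------------------------------------------------------
# CNV correlation


def cnv_expression_correlation(
    expr, cnv, labels: Mapping[str, int] | None = None, min_samples: int = 4
) -> list[CNVCorrelation]:
    """Per-(gene, cluster) Spearman correlation between expression and CNV."""
    if labels is None:
        labels = expr.cluster_labels()
    genes = expr.gene_ids.intersection(cnv.values.index)
    out: list[CNVCorrelation] = []
    for cluster in sorted(set(labels.values())):
        samples = [
            s for s, c in labels.items()
            if c == cluster and s in cnv.values.columns and s in expr.sample_ids
        ]
        if len(samples) < min_samples:
            logger.warning(
                "cluster %s: only %d shared expression/CNV samples; skipped",
                cluster, len(samples),
            )
            continue
        for gene in genes:
            rho, p = spearman(
                expr.values.loc[gene, samples].to_numpy(),
                cnv.values.loc[gene, samples].to_numpy(),
            )
            out.append(CNVCorrelation(gene_id=gene, cluster_id=cluster, rho=rho, p_value=p))
    return out
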