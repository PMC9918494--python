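"""Prognostic risk scoring: L1-penalized Cox selection and survival evaluation.

Candidate features (immune-related genes and the TFs selected for the
cluster) enter an L1-penalized Cox proportional-hazards model (Breslow ties,
glmnet-style coordinate descent via scikit-survival's Coxnet) on a 7:3
train/validation split; the penalty is chosen by K-fold cross-validated
partial-likelihood. The fitted model defines the linear risk score

    Risk Score = sum_i  zeta_i * Exp_i

over the selected features. Patients are stratified 1:1 at the median score
and the groups are compared by Kaplan-Meier curves, the log-rank test, and
IPCW cumulative/dynamic time-dependent AUC.

Features are z-scored on the training split before penalization; ``zeta``
is reported back on the input expression scale (``zeta_std`` keeps the
standardized-scale coefficients).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .io_formats import SurvivalTable

logger = logging.getLogger("immureg")

_COEF_CAP = 50.0


@dataclass
class RiskModel:
    """Selected features and their Cox coefficients (Risk Score weights)."""

    features: list[str]
    zeta: dict[str, float]  # input expression scale
    zeta_std: dict[str, float]  # standardized scale
    lambda_: float
    train_fraction: float
    seed: int
    train_samples: list[str] = field(default_factory=list)
    test_samples: list[str] = field(default_factory=list)


@dataclass
class SurvivalFit:
    """Product-limit estimate at the observed event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


# ---------------------------------------------------------------------------
# Breslow partial log-likelihood (used for cross-validated penalty choice)


def breslow_partial_loglik(
    eta: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Cox partial log-likelihood with Breslow handling of tied event times."""
    order = np.argsort(time, kind="stable")
    eta, time, event = eta[order], time[order], event[order]
    # suffix log-sum-exp of eta: log sum over the risk set {j : t_j >= t_i}
    rev = eta[::-1]
    suffix = np.logaddexp.accumulate(rev)[::-1]
    # ties: every sample with the same time belongs to the risk set
    first_idx = np.zeros(len(time), dtype=int)
    i = 0
    while i < len(time):
        j = i
        while j < len(time) and time[j] == time[i]:
            j += 1
        first_idx[i:j] = i
        i = j
    lse = suffix[first_idx]
    mask = event.astype(bool)
    return float(np.sum(eta[mask] - lse[mask]))


# ---------------------------------------------------------------------------
# model fitting


def fit_lasso_cox(
    features: pd.DataFrame,  # samples x features
    survival: SurvivalTable,
    lambda_grid: Sequence[float] | None = None,
    k_folds: int = 10,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> RiskModel:
    """L1-penalized Cox fit with CV-selected penalty on a 7:3 split.

    The penalty path is glmnet-style (Coxnet, l1_ratio=1); lambda is the
    sparsest value whose mean held-out per-event Breslow partial
    log-likelihood lies within one standard error of the best (the
    lambda.1se convention). Features with nonzero coefficients at that
    lambda form the model.
    """
    from sklearn.model_selection import KFold
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    shared = features.index.intersection(survival.sample_ids)
    if len(shared) < 10:
        raise ValueError("need at least 10 samples with both expression and survival")
    features = features.loc[shared]
    surv = survival.data.loc[shared]

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(shared))
    n_train = max(int(round(train_fraction * len(shared))), 2)
    train_ids = list(shared[perm[:n_train]])
    test_ids = list(shared[perm[n_train:]])

    tr_surv = surv.loc[train_ids]
    if tr_surv["event"].sum() < 1:
        raise ValueError("no events in the training split")

    Xtr = features.loc[train_ids].to_numpy(dtype=float)
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xtr_s = (Xtr - mu) / sd_safe
    ytr = Surv.from_arrays(
        event=tr_surv["event"].to_numpy(bool), time=tr_surv["time"].to_numpy(float)
    )

    if lambda_grid is None:
        path = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, n_alphas=50, alpha_min_ratio=0.01, normalize=False
        )
        path.fit(Xtr_s, ytr)
        alphas = np.asarray(path.alphas_)
    else:
        alphas = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    time_tr = tr_surv["time"].to_numpy(float)
    event_tr = tr_surv["event"].to_numpy(float)
    fold_ll = []
    n_splits = min(k_folds, len(train_ids))
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed % (2**31))
    for tr_idx, te_idx in kf.split(Xtr_s):
        if event_tr[tr_idx].sum() < 1 or event_tr[te_idx].sum() < 1:
            logger.warning("CV fold without events skipped")
            continue
        model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, normalize=False)
        try:
            with warnings.catch_warnings():
                # an all-zero end of the path is expected, not a user error
                warnings.filterwarnings("ignore", message="all coefficients are zero")
                model.fit(Xtr_s[tr_idx], ytr[tr_idx])
        except Exception as exc:  # degenerate folds can break the path
            logger.warning("CV fold failed (%s); skipped", exc)
            continue
        fitted = np.asarray(model.alphas_)
        n_ev = event_tr[te_idx].sum()
        row = []
        for alpha in alphas:
            col = int(np.argmin(np.abs(fitted - alpha)))
            eta = Xtr_s[te_idx] @ model.coef_[:, col]
            # per-event held-out Breslow log-likelihood (comparable across folds)
            row.append(
                breslow_partial_loglik(eta, time_tr[te_idx], event_tr[te_idx]) / n_ev
            )
        fold_ll.append(row)
    if not fold_ll:
        raise ValueError("cross-validation failed in every fold")
    fold_ll = np.asarray(fold_ll)
    mean_ll = fold_ll.mean(axis=0)
    se_ll = (
        fold_ll.std(axis=0, ddof=1) / np.sqrt(len(fold_ll))
        if len(fold_ll) > 1 else np.zeros_like(mean_ll)
    )
    best_i = int(np.argmax(mean_ll))
    # one-standard-error rule: sparsest penalty within 1 SE of the best fit
    within = np.flatnonzero(mean_ll >= mean_ll[best_i] - se_ll[best_i])
    best = int(within[0])  # alphas are descending: first = largest penalty
    lam = float(alphas[best])

    final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, normalize=False)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="all coefficients are zero")
        final.fit(Xtr_s, ytr)
    fitted = np.asarray(final.alphas_)
    col = int(np.argmin(np.abs(fitted - lam)))
    beta_std = final.coef_[:, col].copy()
    if np.abs(beta_std).max() > _COEF_CAP:
        logger.warning("coefficient divergence; capping at +/-%g", _COEF_CAP)
        beta_std = np.clip(beta_std, -_COEF_CAP, _COEF_CAP)

    nz = np.flatnonzero(beta_std)
    names = list(features.columns)
    return RiskModel(
        features=[names[j] for j in nz],
        zeta={names[j]: float(beta_std[j] / sd_safe[j]) for j in nz},
        zeta_std={names[j]: float(beta_std[j]) for j in nz},
        lambda_=lam,
        train_fraction=train_fraction,
        seed=seed,
        train_samples=train_ids,
        test_samples=test_ids,
    )


def risk_score(model: RiskModel, expression: Mapping[str, float]) -> float:
    """Risk Score = sum_i zeta_i * Exp_i over the model's features."""
    total = 0.0
    for feat in model.features:
        if feat not in expression:
            raise KeyError(f"expression value missing for model feature {feat!r}")
        total += model.zeta[feat] * float(expression[feat])
    return total


def score_samples(model: RiskModel, features: pd.DataFrame) -> pd.Series:
    """Risk score for every row (sample) of a samples x features frame."""
    missing = [f for f in model.features if f not in features.columns]
    if missing:
        raise KeyError(f"expression value missing for model feature {missing[0]!r}")
    zeta = pd.Series(model.zeta)
    return features[model.features].mul(zeta, axis=1).sum(axis=1)


# ---------------------------------------------------------------------------
# stratification and survival comparison


def stratify_by_median(scores: pd.Series | Sequence[float]) -> pd.Series:
    """1:1 split at the median; exact-median ties (and the middle sample for
    odd n) go to the low group."""
    s = pd.Series(scores, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 scores")
    med = float(s.median())
    if s.nunique() == 1:
        logger.warning("all risk scores identical; every sample in the low group")
    return pd.Series(np.where(s <= med, "low", "high"), index=s.index)


def kaplan_meier(survival: SurvivalTable) -> SurvivalFit:
    """Product-limit estimator over the subset's event times."""
    kmf = KaplanMeierFitter()
    kmf.fit(survival.data["time"], survival.data["event"])
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = np.array([float(kmf.survival_function_.loc[t].iloc[0]) for t in times])
    return SurvivalFit(
        times=times,
        survival=surv,
        at_risk=ev["at_risk"].to_numpy(dtype=float),
        events=ev["observed"].to_numpy(dtype=float),
    )


def logrank(group_a: SurvivalTable, group_b: SurvivalTable) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p from chi2 with 1 df)."""
    if len(group_a.data) == 0 or len(group_b.data) == 0:
        raise ValueError("both groups must be non-empty")
    total_events = group_a.data["event"].sum() + group_b.data["event"].sum()
    if total_events == 0:
        logger.warning("no events in either group; log-rank undefined, p = 1")
        return 0.0, 1.0
    res = _ll_logrank(
        group_a.data["time"], group_b.data["time"],
        event_observed_A=group_a.data["event"], event_observed_B=group_b.data["event"],
    )
    return float(res.test_statistic), float(res.p_value)


def time_dependent_auc(
    scores: pd.Series,
    survival: SurvivalTable,
    eval_times: Sequence[float],
) -> dict[float, float]:
    """IPCW cumulative/dynamic AUC(t), censoring weights from the KM of the
    censoring distribution. Times without comparable pairs are dropped with
    a warning."""
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    shared = scores.index.intersection(survival.sample_ids)
    s = scores.loc[shared].to_numpy(dtype=float)
    surv = survival.data.loc[shared]
    y = Surv.from_arrays(
        event=surv["event"].to_numpy(bool), time=surv["time"].to_numpy(float)
    )
    times = np.asarray(sorted(eval_times), dtype=float)
    lo, hi = surv["time"].min(), surv["time"].max()
    usable = times[(times >= lo) & (times < hi)]
    if len(usable) < len(times):
        logger.warning("%d evaluation time(s) outside follow-up dropped",
                       len(times) - len(usable))
    if len(usable) == 0:
        return {}
    aucs, _ = cumulative_dynamic_auc(y, y, s, usable)
    out: dict[float, float] = {}
    for t, a in zip(usable, aucs):
        if np.isfinite(a):
            out[float(t)] = float(np.clip(a, 0.0, 1.0))
        else:
            logger.warning("AUC undefined at t=%g (no comparable pairs)", t)
    return out


# ---------------------------------------------------------------------------
# end-to-end evaluation convenience


def evaluate_risk_model(
    model: RiskModel,
    features: pd.DataFrame,
    survival: SurvivalTable,
    eval_times: Sequence[float] | None = None,
) -> dict:
    """Score, stratify and compare the validation split of a fitted model."""
    ids = [s for s in model.test_samples if s in features.index]
    if len(ids) < 4:
        ids = [s for s in features.index if s in survival.sample_ids]
    scores = score_samples(model, features.loc[ids])
    groups = stratify_by_median(scores)
    low_ids = groups.index[groups == "low"]
    high_ids = groups.index[groups == "high"]
    low = SurvivalTable(survival.data.loc[low_ids])
    high = SurvivalTable(survival.data.loc[high_ids]) if len(high_ids) else None
    out = {
        "scores": scores,
        "groups": groups,
        "km_low": kaplan_meier(low),
        "km_high": kaplan_meier(high) if high is not None else None,
    }
    if high is not None and len(high.data) > 0:
        out["logrank"] = logrank(low, high)
    if eval_times is not None:
        out["auc"] = time_dependent_auc(scores, survival, eval_times)
    return out
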