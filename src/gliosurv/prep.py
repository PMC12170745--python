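"""Feature normalization and the three-stage selection cascade.

The cascade runs on the training set only, in fixed order:

1. **variance filter** — remove features with variance < 0.01, applied to
   the *raw* (pre-z-score) values: after z-scoring every non-constant
   feature has variance exactly 1, which would make the threshold
   vacuous, so the filter is read as a near-constancy screen on raw
   features;
2. **Spearman redundancy prune** — for every pair with |rho| >= 0.95
   (visited in descending |rho| over a single static correlation matrix),
   drop the member with the higher mean |rho| against all other original
   features (ties: the lexicographically later name);
3. **LASSO-Cox** — L1-penalized Cox regression over a log-spaced penalty
   grid, the penalty chosen by k-fold cross-validated partial
   log-likelihood (Verweij-van Houwelingen score), nonzero coefficients
   selected.

Z-score normalization is computed within the given set (training
statistics for the training set, test statistics for the test set, each
on its own), switchable to train-statistics via ``stats_from``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv


@dataclass
class SelectionReport:
    removed_by_variance: list[str] = field(default_factory=list)
    removed_by_correlation: list[dict] = field(default_factory=list)
    lasso_selected: dict[str, float] = field(default_factory=dict)
    variance_threshold: float = 0.01
    rho_threshold: float = 0.95
    chosen_alpha: float | None = None
    empty_selection: bool = False

    @property
    def correlation_removed_names(self) -> list[str]:
        return [e["removed"] for e in self.removed_by_correlation]


def zscore_normalize(table: pd.DataFrame, stats_from: pd.DataFrame | None = None):
    """Per-column z-score; returns (normalized table, constant column list).

    Statistics come from ``stats_from`` when given (e.g. training-set
    statistics applied to the test set), otherwise from ``table`` itself.
    Constant columns are set to 0 and reported, never silently dropped.
    """
    if len(table) < 2:
        raise ValueError("zscore_normalize: need at least 2 rows")
    ref = table if stats_from is None else stats_from
    mu = ref.mean()
    sd = ref.std(ddof=1)
    # relative tolerance: a column constant up to float rounding is constant
    tol = 1e-12 * (mu.abs() + 1.0)
    constant = list(sd.index[(sd <= tol) | sd.isna()])
    safe_sd = sd.replace(0, 1.0).fillna(1.0)
    out = (table - mu) / safe_sd
    out[constant] = 0.0
    return out, constant


def variance_filter(raw: pd.DataFrame, threshold: float = 0.01):
    """Keep features with raw-value variance >= threshold (strict-< removal)."""
    var = raw.var(ddof=1)
    survivors = [c for c in raw.columns if var[c] >= threshold]
    removed = [c for c in raw.columns if var[c] < threshold]
    return survivors, removed


def spearman_prune(table: pd.DataFrame, rho_threshold: float = 0.95):
    """Single-pass redundancy prune on the static Spearman matrix.

    Returns (survivor names, removal records).  Each record carries the
    triggering pair, its |rho|, and both members' mean |rho| against all
    other original features.
    """
    cols = list(table.columns)
    if len(cols) < 3:
        return cols, []
    rho = stats.spearmanr(table.to_numpy()).statistic
    rho = np.atleast_2d(np.nan_to_num(rho))
    arho = np.abs(rho)
    np.fill_diagonal(arho, 0.0)
    mean_rho = arho.sum(axis=1) / (len(cols) - 1)

    pairs = [
        (i, j)
        for i in range(len(cols))
        for j in range(i + 1, len(cols))
        if arho[i, j] >= rho_threshold
    ]
    # descending |rho|; deterministic name-pair tie-break so column order
    # never changes the surviving set
    pairs.sort(key=lambda ij: (-arho[ij], tuple(sorted((cols[ij[0]], cols[ij[1]])))))

    removed_idx: set[int] = set()
    records = []
    for i, j in pairs:
        if i in removed_idx or j in removed_idx:
            continue
        # means equal up to float-summation noise count as tied -> name rule
        if abs(mean_rho[i] - mean_rho[j]) <= 1e-12:
            drop = i if cols[i] > cols[j] else j
        elif mean_rho[i] > mean_rho[j]:
            drop = i
        else:
            drop = j
        removed_idx.add(drop)
        records.append(
            {
                "removed": cols[drop],
                "pair": (cols[i], cols[j]),
                "abs_rho": float(arho[i, j]),
                "mean_abs_rho": {
                    cols[i]: float(mean_rho[i]),
                    cols[j]: float(mean_rho[j]),
                },
            }
        )
    survivors = [c for k, c in enumerate(cols) if k not in removed_idx]
    return survivors, records


def _breslow_pll(beta: np.ndarray, X: np.ndarray, time, event) -> float:
    """Breslow partial log-likelihood at fixed coefficients."""
    order = np.argsort(-time, kind="stable")  # descending time
    Xs, ts, es = X[order], time[order], event[order]
    eta = Xs @ beta
    log_cumsum = np.logaddexp.accumulate(eta)
    # risk set of t_i = all with t_j >= t_i; with descending sort, entries
    # 0..k where ts[k] is the last index with ts >= t_i
    pll = 0.0
    for i in np.flatnonzero(es == 1):
        k = np.searchsorted(-ts, -ts[i], side="right") - 1
        pll += eta[i] - log_cumsum[k]
    return float(pll)


def lasso_cox_select(
    table: pd.DataFrame,
    time,
    event,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    n_lambdas: int = 50,
    penalty_rule: str = "1se",
) -> SelectionReport:
    """LASSO-Cox feature selection with seeded, event-stratified CV.

    The penalty path is the coordinate-descent LASSO-Cox of scikit-survival;
    for each fold the held-out contribution to the partial log-likelihood
    is scored as pll(all) − pll(without fold) at the fold-training
    coefficients (Verweij-van Houwelingen).  ``penalty_rule="max"`` takes
    the score-maximizing penalty; the default ``"1se"`` takes the largest
    penalty within one standard error of the maximum (glmnet's
    ``lambda.1se``), which yields the parsimonious signatures appropriate
    for cohorts with few events.  The chosen penalty is refit on the full
    training set and its nonzero coefficients returned.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("lasso_cox_select: no events")
    X = table.to_numpy(dtype=float)
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    path = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, alpha_min_ratio=0.01, n_alphas=n_lambdas, fit_baseline_model=False
    )
    if lambda_grid is not None:
        path.set_params(alphas=list(lambda_grid))
    path.fit(X, y)
    alphas = np.asarray(path.alphas_)

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    fold_scores = np.zeros((cv_folds, alphas.size))
    complete = np.ones(alphas.size, dtype=bool)  # alphas every fold converged on
    for k, (train_idx, test_idx) in enumerate(skf.split(X, event)):
        if event[train_idx].sum() == 0:
            raise ValueError("lasso_cox_select: a CV training fold has no events")
        fold = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=list(alphas), fit_baseline_model=False
        )
        fold.fit(X[train_idx], y[train_idx])
        fold_alphas = np.asarray(fold.alphas_)  # may be truncated
        for a in range(alphas.size):
            match = np.flatnonzero(np.isclose(fold_alphas, alphas[a]))
            if match.size == 0:
                complete[a] = False
                continue
            beta = fold.coef_[:, match[0]]
            fold_scores[k, a] = _breslow_pll(beta, X, time, event) - _breslow_pll(
                beta, X[train_idx], time[train_idx], event[train_idx]
            )
    scores = fold_scores.sum(axis=0)
    scores[~complete] = -np.inf
    best = int(np.argmax(scores))
    if penalty_rule == "1se":
        se = fold_scores[:, best].std(ddof=1) * np.sqrt(cv_folds)
        ok = np.flatnonzero(complete & (scores >= scores[best] - se))
        # alphas_ descend: the smallest index within one SE is the largest penalty
        best = int(ok.min())
    elif penalty_rule != "max":
        raise ValueError("penalty_rule must be 'max' or '1se'")
    chosen = float(alphas[best])
    beta = path.coef_[:, best]
    selected = {
        c: float(b) for c, b in zip(table.columns, beta) if b != 0.0
    }
    return SelectionReport(
        lasso_selected=selected,
        chosen_alpha=chosen,
        empty_selection=len(selected) == 0,
    )


def select_features(
    raw_train: pd.DataFrame,
    norm_train: pd.DataFrame,
    time,
    event,
    variance_threshold: float = 0.01,
    rho_threshold: float = 0.95,
    cv_folds: int = 5,
    seed: int = 0,
    penalty_rule: str = "1se",
) -> SelectionReport:
    """Full cascade: variance (raw values) -> Spearman -> LASSO-Cox.

    ``raw_train`` supplies pre-normalization values for the variance
    screen; ``norm_train`` the z-scored values for stages 2-3.
    """
    stage1, removed_var = variance_filter(raw_train, variance_threshold)
    stage2, corr_records = spearman_prune(norm_train[stage1], rho_threshold)
    report = lasso_cox_select(
        norm_train[stage2], time, event, cv_folds=cv_folds, seed=seed,
        penalty_rule=penalty_rule,
    )
    report.removed_by_variance = removed_var
    report.removed_by_correlation = corr_records
    report.variance_threshold = variance_threshold
    report.rho_threshold = rho_threshold
    return report
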