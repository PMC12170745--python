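"""Cox proportional-hazards models, risk scores and exact linear SHAP.

The model specs mirror the study design: a preoperative clinical model
(preoperative tumor volume only), a full clinical model (tumor volume,
extent of resection, subtype), one radiomics model per tumor-related zone
(LASSO-Cox), combined models that refit clinical covariates jointly with
the LASSO-selected radiomics features, and a sensitivity variant of the
full clinical model with extent of resection replaced by postoperative
tumor volume.

Categorical coding: extent of resection enters as two indicators
(partial, complete) with biopsy as the reference level; subtype as a
single astrocytoma indicator (oligodendroglioma reference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceWarning


CLINICAL_PREOP = ["preop_volume_ml"]
CLINICAL_FULL = ["preop_volume_ml", "eor_partial", "eor_complete", "astrocytoma"]
CLINICAL_FULL_POSTOP = ["preop_volume_ml", "postop_volume_ml", "astrocytoma"]

MODEL_SPECS = {
    "preop_clinical": CLINICAL_PREOP,
    "full_clinical": CLINICAL_FULL,
    "full_clinical_postop": CLINICAL_FULL_POSTOP,
    # radiomics_<zone> and combined_* covariates are data-dependent
    # (LASSO-selected) and assembled by the pipeline.
}


@dataclass
class CoxModel:
    """Fitted Cox model: risk = beta . x (linear predictor).

    ``coefficients`` are log-hazard ratios per unit of each feature;
    ``feature_means`` are training-set means, retained as the default SHAP
    background.  ``converged`` is False when the partial likelihood is
    monotone (complete separation) and the optimizer stopped at its step
    cap rather than at a stationary point.
    """

    feature_names: list[str]
    coefficients: np.ndarray
    feature_means: np.ndarray
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)
    ties: str = "efron"

    def risk_score(self, X) -> np.ndarray:
        return risk_score(self, X)


def encode_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Expand categorical clinical covariates into model covariates."""
    out = pd.DataFrame(index=clinical.index)
    out["preop_volume_ml"] = clinical["preop_volume_ml"].astype(float)
    if "postop_volume_ml" in clinical:
        out["postop_volume_ml"] = clinical["postop_volume_ml"].astype(float)
    eor = clinical["extent_of_resection"]
    out["eor_partial"] = (eor == "partial").astype(float)
    out["eor_complete"] = (eor == "complete").astype(float)
    out["astrocytoma"] = (clinical["subtype"] == "astrocytoma").astype(float)
    return out


def fit_cox(
    X: pd.DataFrame,
    time,
    event,
    l1_penalty: float = 0.0,
) -> CoxModel:
    """Maximize the (optionally L1-penalized) Cox partial likelihood.

    Efron tie handling; Newton optimization with step-halving.  A monotone
    partial likelihood (e.g. a covariate that perfectly separates event
    order) is reported via ``converged=False`` instead of an exception.

    Raises
    ------
    ValueError
        If there are no events, missing covariate values, or a constant
        covariate (named in the message).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("fit_cox: no events in the outcome data")
    if len(X.columns) == 0:
        # null model: empty covariate set, risk identically zero
        return CoxModel([], np.zeros(0), np.zeros(0), True, {"null_model": True})
    if X.isna().any().any():
        raise ValueError("fit_cox: missing covariate values")
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"fit_cox: constant covariate(s): {const}")

    df = X.copy()
    df["_time"] = time
    df["_event"] = event
    fitter = CoxPHFitter(penalizer=l1_penalty, l1_ratio=1.0 if l1_penalty else 0.0)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        try:
            fitter.fit(df, duration_col="_time", event_col="_event")
        except Exception as exc:  # lifelines raises on hopeless separation
            raise ValueError(f"fit_cox: fit failed: {exc}") from exc
        messages = [str(w.message) for w in caught if issubclass(w.category, ConvergenceWarning)]
    if messages:
        converged = False
    coefs = fitter.params_.reindex(X.columns).to_numpy()
    return CoxModel(
        list(X.columns),
        coefs,
        X.mean().to_numpy(),
        converged,
        {
            "log_likelihood": float(fitter.log_likelihood_),
            "n_events": int(event.sum()),
            "warnings": messages,
        },
    )


def risk_score(model: CoxModel, X) -> np.ndarray:
    """Linear predictor beta . x for each row of X.

    No baseline hazard is needed: ranking, concordance and risk-group
    stratification depend on the linear predictor only.
    """
    if isinstance(X, pd.DataFrame):
        missing = [f for f in model.feature_names if f not in X.columns]
        if missing:
            raise ValueError(f"risk_score: missing feature(s) {missing}")
        mat = X[model.feature_names].to_numpy(dtype=float)
    else:
        mat = np.atleast_2d(np.asarray(X, dtype=float))
        if mat.shape[1] != len(model.feature_names):
            raise ValueError("risk_score: feature count mismatch")
    return mat @ model.coefficients if model.coefficients.size else np.zeros(len(mat))


def linear_shap(model: CoxModel, background: pd.DataFrame, X=None) -> pd.DataFrame:
    """Exact Shapley values for the linear risk score.

    Under the independent-feature value function the Shapley value of
    feature j for patient x is ``beta_j * (x_j - mean_background(x_j))``;
    contributions sum to ``risk(x) - mean(risk(background))`` exactly.
    """
    if len(background) == 0:
        raise ValueError("linear_shap: empty background")
    missing = [f for f in model.feature_names if f not in background.columns]
    if missing:
        raise ValueError(f"linear_shap: background missing feature(s) {missing}")
    if X is None:
        X = background
    missing = [f for f in model.feature_names if f not in X.columns]
    if missing:
        raise ValueError(f"linear_shap: missing feature(s) {missing}")
    mu = background[model.feature_names].mean().to_numpy()
    mat = X[model.feature_names].to_numpy(dtype=float)
    phi = (mat - mu) * model.coefficients
    return pd.DataFrame(phi, index=X.index, columns=model.feature_names)
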