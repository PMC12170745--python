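"""End-to-end study orchestration.

Runs the full design on a cohort: stratified 70:30 split, zone
extraction, radiomics feature table, per-zone selection cascade, the
eight survival models (preoperative clinical; full clinical; radiomics x
4 zones; combined preoperative and combined full) plus the
postoperative-volume sensitivity variant, IPCW concordance evaluation
with paired bootstrap and Wilcoxon comparisons, and log-rank optimal
risk-group stratification with Kaplan-Meier curves overall and per
subtype.  Every random stage is seeded from one master seed, so a run is
a pure function of (cohort, parameters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, models, prep, stratification, zones
from .features import DiscretizationSpec, extract_feature_table
from .synthetic import Cohort

PRIMARY_MODELS = (
    "preop_clinical",
    "full_clinical",
    "radiomics_tumor",
    "radiomics_band_pm5",
    "radiomics_ptz_0_10",
    "radiomics_ptz_10_20",
    "combined_preop",
    "combined_full",
)
SENSITIVITY_MODEL = "full_clinical_postop"


@dataclass
class StudyParams:
    train_frac: float = 0.7
    n_bootstrap: int = 1000
    tau_years: float = 5.0
    n_bins: int = 32
    cv_folds: int = 5
    test_zscore_stats: str = "self"  # "self" (per-set statistics) or "train"
    zone_subset: tuple = tuple(zones.ZONE_NAMES)
    master_seed: int = 0


def split_cohort(ids, event, subtype, train_frac: float = 0.7, seed: int = 0):
    """Stratified train/test split; training size is exactly
    floor(train_frac * n).

    Stratification is joint on (event indicator, subtype) with
    largest-remainder rounding of the per-stratum training quotas, so
    event and subtype proportions are preserved as closely as integer
    counts allow.  Empty strata are skipped.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    ids = np.asarray(ids)
    event = np.asarray(event, dtype=int)
    subtype = np.asarray(subtype)
    n = ids.size
    n_train = int(np.floor(train_frac * n))
    rng = np.random.default_rng(seed)

    strata = [
        np.flatnonzero((event == e) & (subtype == s))
        for e in np.unique(event)
        for s in np.unique(subtype)
    ]
    strata = [s for s in strata if s.size > 0]
    quotas = np.array([train_frac * s.size for s in strata])
    base = np.floor(quotas).astype(int)
    short = n_train - base.sum()
    # distribute the shortfall to the largest fractional remainders
    order = np.argsort(-(quotas - base), kind="stable")
    for k in order[:short]:
        base[k] += 1
    train_idx = []
    for s, q in zip(strata, base):
        perm = rng.permutation(s)
        train_idx.extend(perm[:q])
    train_mask = np.zeros(n, dtype=bool)
    train_mask[train_idx] = True
    return ids[train_mask].tolist(), ids[~train_mask].tolist()


def _prune_design(X_tr: pd.DataFrame) -> list[str]:
    """Drop covariates unidentifiable in a given training set: constants,
    and one resection indicator when no biopsy patient is present (the
    two indicators then sum to 1, a constant direction a no-intercept
    Cox model cannot identify; partial resection becomes the reference)."""
    cols = [c for c in X_tr.columns if X_tr[c].nunique() > 1]
    if {"eor_partial", "eor_complete"} <= set(cols):
        if (X_tr["eor_partial"] + X_tr["eor_complete"]).nunique() == 1:
            cols.remove("eor_partial")
    return cols


def _zone_columns(table: pd.DataFrame, zone: str) -> list[str]:
    return [c for c in table.columns if c.startswith(zone + "_")]


def _km_curve(time, event):
    t, s = evaluation.km_estimator(time, event)
    return {"time_years": [float(x) for x in t], "survival": [float(x) for x in s]}


def extract_cohort_features(cohort: Cohort, params: StudyParams) -> pd.DataFrame:
    """Zones + radiomics for every patient in the cohort."""
    spacing = cohort.config.voxel_spacing_mm
    specs = {z: zones.DEFAULT_ZONES[z] for z in params.zone_subset}
    zone_masks = {
        pid: zones.extract_all_zones(cohort.masks[pid], cohort.brain, spacing, specs)
        for pid in cohort.patient_ids
    }
    return extract_feature_table(
        cohort.images, zone_masks, spacing, DiscretizationSpec(params.n_bins)
    )


def run_study(cohort: Cohort, params: StudyParams = StudyParams()) -> dict:
    """Execute the whole study; returns a JSON-serializable results record.

    The record has one entry per primary model plus the sensitivity
    variant, each with the selected-feature count, test-set Uno's c
    median (IQR), Uno's c at tau median (IQR) and Harrell's c; pairwise
    Wilcoxon comparisons among the clinical, best-radiomics and combined
    models; and the risk-group stratification of the best combined model.
    """
    rng_root = np.random.SeedSequence(params.master_seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in rng_root.spawn(4)]
    outcomes = cohort.outcomes
    time = outcomes["time_years"].to_numpy()
    event = outcomes["event"].to_numpy()

    train_ids, test_ids = split_cohort(
        cohort.patient_ids,
        event,
        cohort.clinical["subtype"].to_numpy(),
        params.train_frac,
        seeds[0],
    )
    tr = outcomes.loc[train_ids]
    te = outcomes.loc[test_ids]

    features = extract_cohort_features(cohort, params)
    clin_enc = models.encode_clinical(cohort.clinical)
    results_n_features = int(features.shape[1])

    # ---- per-zone selection cascade + LASSO-Cox radiomics models -------
    results: dict = {"models": {}, "selection": {}}
    risk_test: dict[str, np.ndarray] = {}
    risk_all: dict[str, np.ndarray] = {}
    selected_norm_cols: dict[str, pd.DataFrame] = {}

    for zi, zone in enumerate(params.zone_subset):
        cols = [c for c in _zone_columns(features, zone) if features[c].notna().all()]
        raw_tr = features.loc[train_ids, cols]
        raw_te = features.loc[test_ids, cols]
        norm_tr, _ = prep.zscore_normalize(raw_tr)
        if params.test_zscore_stats == "self":
            norm_te, _ = prep.zscore_normalize(raw_te)
        else:
            norm_te, _ = prep.zscore_normalize(raw_te, stats_from=raw_tr)
        report = prep.select_features(
            raw_tr,
            norm_tr,
            tr["time_years"],
            tr["event"],
            cv_folds=params.cv_folds,
            seed=seeds[1] + zi,
        )
        name = f"radiomics_{zone}"
        sel = list(report.lasso_selected)
        beta = np.array([report.lasso_selected[c] for c in sel])
        model = models.CoxModel(
            sel, beta, norm_tr[sel].mean().to_numpy() if sel else np.zeros(0),
            True, {"lasso": True, "alpha": report.chosen_alpha},
        )
        risk_test[name] = (
            norm_te[sel].to_numpy() @ beta if sel else np.zeros(len(test_ids))
        )
        norm_all = pd.concat([norm_tr[sel], norm_te[sel]]).loc[cohort.patient_ids]
        risk_all[name] = (
            norm_all.to_numpy() @ beta if sel else np.zeros(len(cohort.patient_ids))
        )
        selected_norm_cols[zone] = pd.concat([norm_tr[sel], norm_te[sel]])
        results["selection"][zone] = {
            "n_input_features": len(cols),
            "n_after_variance": len(cols) - len(report.removed_by_variance),
            "n_after_correlation": len(cols)
            - len(report.removed_by_variance)
            - len(report.removed_by_correlation),
            "n_selected": len(sel),
            "selected": {c: float(report.lasso_selected[c]) for c in sel},
            "chosen_alpha": report.chosen_alpha,
            "empty_selection": report.empty_selection,
        }

    # ---- clinical models ----------------------------------------------
    def _fit_clinical(covs, name):
        usable = _prune_design(clin_enc.loc[train_ids, covs])
        m = models.fit_cox(
            clin_enc.loc[train_ids, usable], tr["time_years"], tr["event"]
        )
        risk_test[name] = models.risk_score(m, clin_enc.loc[test_ids, usable])
        risk_all[name] = models.risk_score(m, clin_enc.loc[cohort.patient_ids, usable])
        return m

    _fit_clinical(models.CLINICAL_PREOP, "preop_clinical")
    _fit_clinical(models.CLINICAL_FULL, "full_clinical")
    _fit_clinical(models.CLINICAL_FULL_POSTOP, SENSITIVITY_MODEL)

    # ---- combined models: clinical + best radiomics zone, refit jointly
    zone_point = {
        z: evaluation.uno_c(
            te["time_years"], te["event"], risk_test[f"radiomics_{z}"]
        ).estimate
        if np.unique(risk_test[f"radiomics_{z}"]).size > 1
        else 0.5
        for z in params.zone_subset
    }
    best_zone = max(zone_point, key=lambda z: (zone_point[z], z))
    results["best_radiomics_zone"] = best_zone
    rad_cols = selected_norm_cols[best_zone]

    def _fit_combined(covs, name):
        X = pd.concat([clin_enc[covs], rad_cols], axis=1).loc[cohort.patient_ids]
        usable = _prune_design(X.loc[train_ids])
        X = X[usable]
        m = models.fit_cox(X.loc[train_ids], tr["time_years"], tr["event"])
        risk_test[name] = models.risk_score(m, X.loc[test_ids])
        risk_all[name] = models.risk_score(m, X)
        return m

    _fit_combined(models.CLINICAL_PREOP, "combined_preop")
    combined_full_model = _fit_combined(models.CLINICAL_FULL, "combined_full")

    # ---- evaluation ----------------------------------------------------
    n_selected = {
        "preop_clinical": 1,
        "full_clinical": 3,
        SENSITIVITY_MODEL: 3,
        "combined_preop": 1 + results["selection"][best_zone]["n_selected"],
        "combined_full": 3 + results["selection"][best_zone]["n_selected"],
    }
    for z in params.zone_subset:
        n_selected[f"radiomics_{z}"] = results["selection"][z]["n_selected"]

    te_time = te["time_years"].to_numpy()
    te_event = te["event"].to_numpy()
    boot = evaluation.bootstrap_distribution(
        te_time, te_event, risk_test, B=params.n_bootstrap, seed=seeds[2]
    )
    boot5 = evaluation.bootstrap_distribution(
        te_time, te_event, risk_test, B=params.n_bootstrap, seed=seeds[2],
        tau=params.tau_years,
    )
    for name in list(PRIMARY_MODELS) + [SENSITIVITY_MODEL]:
        r = risk_test[name]
        degenerate = np.unique(r).size == 1
        entry = {
            "n_selected_features": n_selected[name],
            "uno_c": None if degenerate else evaluation.uno_c(te_time, te_event, r).estimate,
            "uno_c_median": boot[name].median,
            "uno_c_iqr": boot[name].iqr,
            "uno_c_tau_median": boot5[name].median,
            "uno_c_tau_iqr": boot5[name].iqr,
            "harrell_c": None
            if degenerate
            else evaluation.harrell_c(te_time, te_event, r).estimate,
        }
        try:
            entry["uno_c_tau"] = (
                None if degenerate
                else evaluation.uno_c(te_time, te_event, r, tau=params.tau_years).estimate
            )
        except ValueError:
            entry["uno_c_tau"] = None
        results["models"][name] = entry

    # ---- pairwise Wilcoxon comparisons ---------------------------------
    compare = [
        "preop_clinical",
        "full_clinical",
        f"radiomics_{best_zone}",
        "combined_preop",
        "combined_full",
    ]
    results["comparisons"] = {}
    for variant, dists in (("uno_c", boot), ("uno_c_tau", boot5)):
        out = {}
        for i, a in enumerate(compare):
            for b in compare[i + 1 :]:
                stat, p = evaluation.compare_distributions(dists[a], dists[b])
                out[f"{a}_vs_{b}"] = {"statistic": stat, "p_value": p}
        results["comparisons"][variant] = out

    # ---- risk groups from the best combined model ----------------------
    risks_cohort = risk_all["combined_full"]
    cut = stratification.find_cutpoint(risks_cohort, time, event)
    subtypes = cohort.clinical["subtype"].to_numpy()
    strat = {
        "threshold": cut.threshold,
        "chi_square": cut.chi_square,
        "p_value": cut.p_value,
        "n_high": int(cut.high_risk.sum()),
        "n_low": int((~cut.high_risk).sum()),
        "km": {
            "high": _km_curve(time[cut.high_risk], event[cut.high_risk]),
            "low": _km_curve(time[~cut.high_risk], event[~cut.high_risk]),
        },
        "by_subtype": {},
    }
    for st in np.unique(subtypes):
        sel = subtypes == st
        hi = cut.high_risk & sel
        lo = ~cut.high_risk & sel
        entry = {"n_high": int(hi.sum()), "n_low": int(lo.sum())}
        if hi.any() and lo.any():
            chi2, p = stratification.logrank_test(time[sel], event[sel], cut.high_risk[sel])
            entry.update(
                chi_square=chi2,
                p_value=p,
                km={
                    "high": _km_curve(time[hi], event[hi]),
                    "low": _km_curve(time[lo], event[lo]),
                },
            )
        strat["by_subtype"][str(st)] = entry
    results["risk_groups"] = strat

    results["n_features"] = results_n_features
    results["split"] = {
        "n_train": len(train_ids),
        "n_test": len(test_ids),
        "train_event_fraction": float(tr["event"].mean()),
        "test_event_fraction": float(te["event"].mean()),
    }
    results["params"] = {
        "train_frac": params.train_frac,
        "n_bootstrap": params.n_bootstrap,
        "tau_years": params.tau_years,
        "n_bins": params.n_bins,
        "cv_folds": params.cv_folds,
        "test_zscore_stats": params.test_zscore_stats,
        "master_seed": params.master_seed,
    }
    results["_risk_test"] = {m: [float(v) for v in r] for m, r in risk_test.items()}
    results["_combined_full_coefficients"] = {
        f: float(b)
        for f, b in zip(combined_full_model.feature_names, combined_full_model.coefficients)
    }
    return results


def write_results(results: dict, out_dir) -> Path:
    """Persist the results record (JSON, sorted keys) and metric table (CSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    rows = []
    for name, entry in results["models"].items():
        rows.append({"model": name, **{k: v for k, v in entry.items() if k != "km"}})
    pd.DataFrame(rows).to_csv(out / "model_metrics.csv", index=False)
    return out / "results.json"
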