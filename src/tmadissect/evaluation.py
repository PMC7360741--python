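"""Evaluation machinery: stratified train/test splits, ROC/AUC, the Youden
operating point, likelihood ratios, Kaplan-Meier risk stratification,
time-dependent AUC, and the six-model comparison harness.

Splits are stratified so that the proportion of patients recurring in each
year up to the horizon is preserved on both sides (risk-set-aware sampling);
binary 5-year outcome labels mask patients censored event-free before the
horizon, while KM curves and time-dependent AUC use the full censoring
information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import model as _model
from .tables import surv_to_sksurv

log = logging.getLogger(__name__)

MODEL_NAMES = ("clinical", "intensity", "null", "intensity+clinical", "spatial", "spatial+clinical")


# ---------------------------------------------------------------------------
# Splits and labels
# ---------------------------------------------------------------------------

def stratified_bootstrap_split(
    surv: pd.DataFrame, horizon_years: float = 5.0, seed: int = 0
) -> tuple[list, list]:
    """Disjoint ~50/50 train/test split preserving per-year recurrence counts.

    Strata are recurrence-in-year-1..H plus no-recurrence-by-horizon; within
    each stratum patients are split in half (odd remainders assigned to a
    side at random), so per-stratum train proportions stay within one
    patient of the global 50%.
    """
    rng = np.random.default_rng(seed)
    strata = _model.recurrence_strata(surv, horizon_years)
    ids = surv.index.to_numpy()
    train, test = [], []
    for members in strata.values():
        members = rng.permutation(members)
        n_train = len(members) // 2 + (int(rng.integers(2)) if len(members) % 2 else 0)
        train.extend(ids[members[:n_train]])
        test.extend(ids[members[n_train:]])
    return train, test


def binary_outcome_at_horizon(surv: pd.DataFrame, horizon_years: float = 5.0):
    """(labels, usable_mask): positive = event within the horizon; negative =
    event-free with follow-up past the horizon; censored early -> masked."""
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)
    positive = (event == 1) & (time <= horizon_years)
    negative = (time >= horizon_years) & ~positive
    labels = pd.Series(np.where(positive, 1, 0), index=surv.index)
    usable = pd.Series(positive | negative, index=surv.index)
    return labels, usable


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_positive: int
    n_negative: int
    operating_point: tuple | None = None  # (threshold, sens, spec)


def roc_curve(scores, labels) -> RocResult:
    """Empirical ROC; the AUC equals the Mann-Whitney concordance of scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return RocResult(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=float(_sk_auc(fpr, tpr)),
        n_positive=n_pos,
        n_negative=n_neg,
    )


def youden_operating_point(roc: RocResult) -> tuple[float, float, float]:
    """Threshold maximizing J = sens + spec - 1; ties favor specificity."""
    j = roc.sensitivity + roc.specificity - 1.0
    best = np.flatnonzero(j == j.max())
    idx = best[np.argmax(roc.specificity[best])]
    op = (float(roc.thresholds[idx]), float(roc.sensitivity[idx]), float(roc.specificity[idx]))
    roc.operating_point = op
    return op


def likelihood_ratios(sens: float, spec: float) -> tuple[float, float]:
    """LR+ = sens/(1-spec), LR- = (1-sens)/spec, with infinity sentinels."""
    lr_plus = float("inf") if spec >= 1.0 else sens / (1.0 - spec)
    lr_minus = float("inf") if spec <= 0.0 else (1.0 - sens) / spec
    return lr_plus, lr_minus


# ---------------------------------------------------------------------------
# Kaplan-Meier and time-dependent AUC
# ---------------------------------------------------------------------------

def km_curves(scores: pd.Series, surv: pd.DataFrame, threshold: float) -> dict[str, pd.DataFrame]:
    """Product-limit recurrence-free survival curves for the low/high-risk
    groups defined by thresholding the risk scores (high = score > threshold)."""
    from lifelines import KaplanMeierFitter

    scores = pd.Series(scores).loc[surv.index]
    groups = {"high": scores > threshold, "low": scores <= threshold}
    out = {}
    for name, mask in groups.items():
        if mask.sum() == 0:
            log.warning("risk group %r is empty", name)
            continue
        km = KaplanMeierFitter()
        sub = surv.loc[mask.to_numpy()]
        km.fit(sub["time"], sub["event"])
        curve = km.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        out[name] = curve
    return out


def time_dependent_auc(
    scores: pd.Series,
    surv: pd.DataFrame,
    times,
    train_surv: pd.DataFrame | None = None,
) -> pd.Series:
    """Cumulative-case / dynamic-control AUC(t) with IPCW from the KM censoring
    distribution (via scikit-survival).  Time points with no cases yet, no
    remaining controls, or beyond follow-up are masked (NaN)."""
    times = np.asarray(times, dtype=float)
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)
    y_test = surv_to_sksurv(surv)
    y_train = surv_to_sksurv(train_surv if train_surv is not None else surv)
    out = pd.Series(np.nan, index=times)
    scores = pd.Series(np.asarray(scores, dtype=float), index=surv.index)
    valid = np.array(
        [
            ((event == 1) & (time <= t)).any() and (time > t).any() and t < time.max()
            for t in times
        ]
    )
    if valid.any():
        from sksurv.metrics import cumulative_dynamic_auc

        try:
            aucs, _ = cumulative_dynamic_auc(
                y_train, y_test, np.asarray(scores, dtype=float), times[valid]
            )
            out.iloc[np.flatnonzero(valid)] = aucs
        except ValueError as exc:
            log.warning("time-dependent AUC failed: %s", exc)
    return out


def time_dependent_auc_ci(
    scores, surv: pd.DataFrame, times, n_boot: int = 100, seed: int = 0, level: float = 0.95
) -> pd.DataFrame:
    """Bootstrap percentile confidence band around AUC(t).

    Resamples patients with replacement; returns a frame with columns
    ``auc``, ``lo``, ``hi`` indexed by the time grid.
    """
    times = np.asarray(times, dtype=float)
    point = time_dependent_auc(scores, surv, times)
    rng = np.random.default_rng(seed)
    scores = pd.Series(np.asarray(scores, dtype=float), index=surv.index)
    draws = np.full((n_boot, len(times)), np.nan)
    for b in range(n_boot):
        idx = rng.integers(len(surv), size=len(surv))
        sb = surv.iloc[idx].reset_index(drop=True)
        draws[b] = time_dependent_auc(scores.iloc[idx].reset_index(drop=True), sb, times).to_numpy()
    alpha = (1.0 - level) / 2.0
    with np.errstate(all="ignore"):
        lo = np.nanquantile(draws, alpha, axis=0)
        hi = np.nanquantile(draws, 1.0 - alpha, axis=0)
    return pd.DataFrame({"auc": point.to_numpy(), "lo": lo, "hi": hi}, index=times)


# ---------------------------------------------------------------------------
# Model comparison harness
# ---------------------------------------------------------------------------

def _score_plus_clinical(base_lp, clin_lp, surv_train, test_index):
    """Combine a model score with the clinical score via an unpenalized Cox
    fit on the two training score columns; returns the test linear predictor."""
    from lifelines import CoxPHFitter

    df = pd.DataFrame(
        {
            "base": base_lp.loc[surv_train.index],
            "clinical": clin_lp.loc[surv_train.index],
            "time": surv_train["time"],
            "event": surv_train["event"],
        }
    )
    df = df.loc[:, (df.nunique() > 1) | df.columns.isin(["time", "event"])]
    cph = CoxPHFitter(penalizer=1e-4)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    test = pd.DataFrame({"base": base_lp.loc[test_index], "clinical": clin_lp.loc[test_index]})
    test = test[[c for c in cph.params_.index]]
    return pd.Series(test.to_numpy() @ cph.params_.to_numpy(), index=test_index)


def compare_models(
    domain_features: dict,
    spot_features: pd.DataFrame,
    intensity_features: pd.DataFrame,
    surv: pd.DataFrame,
    n_boot: int = 500,
    seed: int = 0,
    horizon_years: float = 5.0,
    stability_boots: int = 100,
    stability_threshold: float = 0.9,
    models=MODEL_NAMES,
) -> pd.DataFrame:
    """Out-of-bag AUC distributions for the recurrence-prediction models.

    For each stratified split every requested model is fit on the training
    half and scored on the held-out half; the 5-year binary AUC is recorded.
    Rows = splits, columns = models; failed fits leave NaN and are logged.

    Models: ``clinical`` (age/gender/stage Cox), ``intensity`` (undissected
    mean intensities only), ``null`` (full undissected feature vector),
    ``spatial`` (three-domain combined model), and the ``+clinical``
    concatenations of the score columns.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_boot):
        split_seed = int(rng.integers(2**31 - 1))
        train_ids, test_ids = stratified_bootstrap_split(surv, horizon_years, split_seed)
        surv_tr = surv.loc[train_ids]
        labels, usable = binary_outcome_at_horizon(surv.loc[test_ids], horizon_years)
        row = {}
        scores: dict[str, pd.Series] = {}
        clin_lp = None
        if any("clinical" in m for m in models):
            try:
                clin = _model.fit_clinical_model(surv_tr)
                clin_lp = clin.linear_predictor(surv)
                scores["clinical"] = clin_lp
            except Exception as exc:  # noqa: BLE001
                log.warning("split %d: clinical fit failed: %s", b, exc)
        fit_kw = dict(
            n_boot=stability_boots,
            threshold=stability_threshold,
            seed=split_seed,
            horizon_years=horizon_years,
        )
        if "intensity" in models or "intensity+clinical" in models:
            try:
                m = _model.fit_domain_model(
                    intensity_features.loc[train_ids], surv_tr, domain="intensity", **fit_kw
                )
                scores["intensity"] = m.linear_predictor(intensity_features)
            except Exception as exc:  # noqa: BLE001
                log.warning("split %d: intensity fit failed: %s", b, exc)
        if "null" in models:
            try:
                m = _model.fit_null_model(
                    spot_features.loc[train_ids], surv_tr, domain="null", **fit_kw
                )
                scores["null"] = m.linear_predictor(spot_features)
            except Exception as exc:  # noqa: BLE001
                log.warning("split %d: null fit failed: %s", b, exc)
        if "spatial" in models or "spatial+clinical" in models:
            try:
                sm = _model.fit_spatial_model(
                    {k: v.loc[train_ids] for k, v in domain_features.items()}, surv_tr, **fit_kw
                )
                scores["spatial"] = sm.log_risk(domain_features)
            except Exception as exc:  # noqa: BLE001
                log.warning("split %d: spatial fit failed: %s", b, exc)
        for combo, base in (("intensity+clinical", "intensity"), ("spatial+clinical", "spatial")):
            if combo in models and base in scores and clin_lp is not None:
                try:
                    scores[combo] = _score_plus_clinical(
                        scores[base], clin_lp, surv_tr, surv.index
                    )
                except Exception as exc:  # noqa: BLE001
                    log.warning("split %d: %s fit failed: %s", b, combo, exc)
        for name in models:
            row[name] = np.nan
            if name in scores:
                s = scores[name].loc[test_ids][usable]
                lab = labels[usable]
                if lab.nunique() == 2:
                    row[name] = roc_curve(s, lab).auc
        rows.append(row)
    return pd.DataFrame(rows, columns=list(models))
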