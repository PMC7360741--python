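"""Recurrence-guided penalized Cox modeling with bootstrap stability selection.

The per-domain pipeline is a two-step procedure on the domain's feature
matrix X (patients x features) and right-censored recurrence outcomes:

1. *Selection*: L1-penalized (LASSO) Cox regression, with the penalty weight
   chosen by 10-fold cross-validated partial-likelihood deviance.  Selection
   is repeated over stratified bootstrap resamples (default 500) and a
   feature is retained only if its coefficient is nonzero in at least 90% of
   them.
2. *Sign stability and refit*: the surviving features are refit per bootstrap
   under an L2 (ridge) penalty; a feature is kept only if its coefficient
   sign matches the full-data refit in at least 90% of bootstraps.  The final
   coefficients come from a ridge refit on the full data using only the final
   features, decoupling coefficient estimation from the initial 1540-feature
   search space.

The three domain models combine multiplicatively: the overall recurrence
risk score is ``exp(sum_s f_s' beta_s)`` over the epithelial, stromal, and
epithelial-stromal domains.  Ties in event times use the Breslow
approximation throughout, matching the plain partial likelihood

    L(beta) = prod_k exp(f_{i_k}' beta) / sum_{i in R_k} exp(f_i' beta).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis, CoxPHSurvivalAnalysis

from .tables import surv_to_sksurv

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Partial likelihood (also serves as the CV deviance and as a test oracle)
# ---------------------------------------------------------------------------

def cox_log_partial_likelihood(X, beta, surv) -> float:
    """Log Cox partial likelihood with Breslow handling of tied event times.

    ``X`` is (n, p) aligned row-wise with ``surv`` (columns ``time`` and
    ``event``); each event contributes its linear predictor minus the log of
    the summed hazards of its risk set (ties share a denominator).
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(surv["time"], dtype=float)
    event = np.asarray(surv["event"], dtype=int)
    if event.sum() == 0:
        raise ValueError("no events: partial likelihood undefined")
    eta = X @ np.asarray(beta, dtype=float)
    # stabilize exp
    eta = eta - eta.max()
    order = np.argsort(-time, kind="stable")  # decreasing time
    t_sorted, eta_sorted, ev_sorted = time[order], eta[order], event[order]
    cum = np.logaddexp.accumulate(eta_sorted)
    ll = 0.0
    i = 0
    n = len(t_sorted)
    while i < n:
        j = i
        while j + 1 < n and t_sorted[j + 1] == t_sorted[i]:
            j += 1
        log_risk = cum[j]  # all subjects with time >= t_i
        for k in range(i, j + 1):
            if ev_sorted[k]:
                ll += eta_sorted[k] - log_risk
        i = j + 1
    return float(ll)


# ---------------------------------------------------------------------------
# Penalized fits
# ---------------------------------------------------------------------------

@dataclass
class PenalizedCoxFit:
    alpha: int  # 1 = LASSO, 0 = ridge
    lambdas: np.ndarray
    chosen_lambda: float
    beta: pd.Series  # on the standardized scale
    deviance: np.ndarray | None
    converged: bool
    center: pd.Series
    scale: pd.Series

    @property
    def selected(self) -> list[str]:
        return list(self.beta.index[self.beta != 0.0])

    def linear_predictor(self, X: pd.DataFrame) -> pd.Series:
        Z = (X[self.beta.index] - self.center) / self.scale
        return pd.Series(Z.to_numpy() @ self.beta.to_numpy(), index=X.index)


def _standardize(X: pd.DataFrame):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1).replace(0.0, 1.0).fillna(1.0)
    return (X - mu) / sd, mu, sd


def _cv_folds(event, n_folds, seed):
    event = np.asarray(event, dtype=int)
    n_min = min(int(event.sum()), int(len(event) - event.sum()))
    if n_min >= 2:
        k = int(max(2, min(n_folds, n_min)))
        return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed).split(
            np.zeros(len(event)), event
        )
    from sklearn.model_selection import KFold

    k = int(max(2, min(n_folds, len(event) // 2)))
    return KFold(n_splits=k, shuffle=True, random_state=seed).split(np.zeros(len(event)))


def _held_out_deviance(X, surv, coefs, train, test):
    """-2 x held-out log partial likelihood for each column of ``coefs``;
    None when the held-out fold carries no events."""
    Xt = X[test]
    st = surv.iloc[test]
    if int(np.asarray(st["event"]).sum()) == 0:
        return None
    out = np.empty(coefs.shape[1])
    for a in range(coefs.shape[1]):
        out[a] = -2.0 * cox_log_partial_likelihood(Xt, coefs[:, a], st)
    return out


def fit_penalized_cox(
    X: pd.DataFrame,
    surv: pd.DataFrame,
    alpha: int,
    seed: int = 0,
    n_folds: int = 10,
    lambdas=None,
    strict: bool = False,
) -> PenalizedCoxFit:
    """Fit an L1 (``alpha=1``) or L2 (``alpha=0``) penalized Cox model.

    Features are standardized internally; coefficients are reported on the
    standardized scale with the transform stored on the fit.  The penalty
    weight is chosen by k-fold cross-validated partial-likelihood deviance
    (minimum along the path).
    """
    if alpha not in (0, 1):
        raise ValueError("alpha must be 0 (ridge) or 1 (LASSO)")
    if int(np.asarray(surv["event"]).sum()) == 0:
        raise ValueError("no events: cannot fit a Cox model")
    Z, mu, sd = _standardize(X)
    Zv = Z.to_numpy(dtype=float)
    y = surv_to_sksurv(surv)
    converged = True
    if alpha == 1:
        full = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=50, alpha_min_ratio=0.05)
        full.fit(Zv, y)
        lams = np.asarray(lambdas if lambdas is not None else full.alphas_, dtype=float)
        dev = np.zeros(len(lams))
        nfold = 0
        for train, test in _cv_folds(surv["event"], n_folds, seed):
            try:
                m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=lams, alpha_min_ratio=0.05)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m.fit(Zv[train], y[train])
                coefs = _coef_path(m, lams)
            except Exception as exc:  # noqa: BLE001 - a failed fold is skipped
                log.debug("CV fold failed: %s", exc)
                continue
            fold_dev = _held_out_deviance(Zv, surv, coefs, train, test)
            if fold_dev is None:
                continue
            dev += fold_dev
            nfold += 1
        if nfold == 0:
            if strict:
                raise RuntimeError("every CV fold failed")
            converged = False
            dev = None
            idx = len(lams) // 2
        else:
            dev = dev / nfold
            idx = int(np.argmin(dev))
        chosen = float(lams[idx])
        beta = pd.Series(_coef_path(full, lams)[:, idx], index=X.columns)
        return PenalizedCoxFit(1, lams, chosen, beta, dev, converged, mu, sd)
    # ridge
    lams = np.asarray(lambdas if lambdas is not None else np.logspace(-2, 3, 8), dtype=float)
    dev = np.zeros(len(lams))
    nfold = 0
    for train, test in _cv_folds(surv["event"], n_folds, seed):
        coefs = np.zeros((Zv.shape[1], len(lams)))
        ok = True
        for a, lam in enumerate(lams):
            b = _ridge_coefs(Zv[train], y[train], lam)
            if b is None:
                ok = False
                break
            coefs[:, a] = b
        if not ok:
            continue
        fold_dev = _held_out_deviance(Zv, surv, coefs, train, test)
        if fold_dev is None:
            continue
        dev += fold_dev
        nfold += 1
    if nfold == 0:
        if strict:
            raise RuntimeError("ridge CV failed on every fold")
        converged = False
        dev = None
        idx = len(lams) - 1
    else:
        dev = dev / nfold
        idx = int(np.argmin(dev))
    chosen = float(lams[idx])
    b = _ridge_coefs(Zv, y, chosen)
    if b is None:
        if strict:
            raise RuntimeError("ridge fit did not converge on the full data")
        converged = False
        b = np.zeros(Zv.shape[1])
    beta = pd.Series(b, index=X.columns)
    return PenalizedCoxFit(0, lams, chosen, beta, dev, converged, mu, sd)


def _coef_path(model: CoxnetSurvivalAnalysis, lams) -> np.ndarray:
    """Coefficients at each requested penalty weight, (p, len(lams))."""
    fitted = np.asarray(model.alphas_, dtype=float)
    out = np.zeros((model.coef_.shape[0], len(lams)))
    for a, lam in enumerate(lams):
        j = int(np.argmin(np.abs(fitted - lam)))
        out[:, a] = model.coef_[:, j]
    return out


def _ridge_coefs(Zv, y, lam):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = CoxPHSurvivalAnalysis(alpha=float(lam), ties="breslow", n_iter=200)
            m.fit(Zv, y)
        return m.coef_
    except Exception as exc:  # noqa: BLE001
        log.debug("ridge fit failed (lambda=%g): %s", lam, exc)
        return None


# ---------------------------------------------------------------------------
# Stability selection
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    frequency: pd.Series  # per-feature selection (or sign-consistency) frequency
    threshold: float
    n_bootstraps: int
    n_failed: int
    seed: int


def stratified_bootstrap_resample(surv: pd.DataFrame, horizon_years: float, rng) -> np.ndarray:
    """Positional indices of a with-replacement resample stratified by
    recurrence year (events within the horizon) vs no recurrence by horizon.

    Keeps the per-year recurrence counts of the original cohort in every
    resample, a form of risk-set sampling.
    """
    strata = recurrence_strata(surv, horizon_years)
    idx = []
    for _, members in strata.items():
        idx.append(rng.choice(members, size=len(members), replace=True))
    return np.concatenate(idx)


def recurrence_strata(surv: pd.DataFrame, horizon_years: float) -> dict:
    """Positional stratum membership: one stratum per recurrence year
    (merging degenerate single-patient years with the next year) plus a
    no-recurrence-by-horizon stratum."""
    time = np.asarray(surv["time"], dtype=float)
    event = np.asarray(surv["event"], dtype=int)
    H = int(np.ceil(horizon_years))
    year = np.minimum(np.ceil(time).astype(int), H)
    strata: dict = {}
    pending: list = []
    for k in range(1, H + 1):
        members = np.flatnonzero((event == 1) & (time <= horizon_years) & (year == k)).tolist()
        members = pending + members
        if 0 < len(members) < 2 and k < H:
            pending = members  # merge a degenerate year with the next
            continue
        pending = []
        if members:
            strata[f"year{k}"] = np.asarray(members)
    nonrec = np.flatnonzero(~((event == 1) & (time <= horizon_years)))
    if pending:  # degenerate final year folds into the non-recurrence pool? no: keep separate if possible
        if f"year{H}" in strata:
            strata[f"year{H}"] = np.concatenate([strata[f"year{H}"], np.asarray(pending)])
        else:
            strata[f"year{H}"] = np.asarray(pending)
    if len(nonrec):
        strata["nonrecurrent"] = nonrec
    return strata


def stability_select(
    X: pd.DataFrame,
    surv: pd.DataFrame,
    n_boot: int = 500,
    threshold: float = 0.9,
    seed: int = 0,
    horizon_years: float = 5.0,
    full_fit: PenalizedCoxFit | None = None,
) -> tuple[list[str], StabilityReport]:
    """Bootstrap stability screen: keep features selected by the LASSO in at
    least ``threshold`` of stratified bootstrap resamples.

    The penalty weight is fixed at the full-data cross-validated optimum;
    each bootstrap refits the LASSO path down to that weight.  Bootstraps
    whose fit fails are recorded and excluded from the frequency denominator.
    """
    if full_fit is None:
        full_fit = fit_penalized_cox(X, surv, alpha=1, seed=seed)
    lam = full_fit.chosen_lambda
    path = full_fit.lambdas[full_fit.lambdas >= lam]
    if path.size == 0 or path[-1] != lam:
        path = np.append(path, lam)
    rng = np.random.default_rng(seed)
    counts = np.zeros(X.shape[1])
    failed = 0
    surv_pos = surv.reset_index(drop=True)
    Xv = X.to_numpy(dtype=float)
    for _ in range(n_boot):
        idx = stratified_bootstrap_resample(surv_pos, horizon_years, rng)
        Xb = Xv[idx]
        sb = surv_pos.iloc[idx]
        mu = Xb.mean(axis=0)
        sd = Xb.std(axis=0, ddof=1)
        sd[~np.isfinite(sd) | (sd == 0)] = 1.0
        try:
            m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=path, alpha_min_ratio=0.05)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m.fit((Xb - mu) / sd, surv_to_sksurv(sb))
            coef = _coef_path(m, [lam])[:, 0]
        except Exception as exc:  # noqa: BLE001
            failed += 1
            log.debug("bootstrap fit failed: %s", exc)
            continue
        counts += coef != 0.0
    denom = max(n_boot - failed, 1)
    freq = pd.Series(counts / denom, index=X.columns)
    selected = list(freq.index[freq >= threshold])
    return selected, StabilityReport(freq, threshold, n_boot, failed, seed)


def sign_stability_check(
    X: pd.DataFrame,
    surv: pd.DataFrame,
    features: list[str],
    n_boot: int = 500,
    threshold: float = 0.9,
    seed: int = 0,
    horizon_years: float = 5.0,
) -> tuple[list[str], StabilityReport, PenalizedCoxFit]:
    """Second screen: keep stability-selected features whose ridge coefficient
    sign matches the full-data ridge refit in >= ``threshold`` of bootstraps.

    Returns the final feature list, the sign-consistency report, and the
    full-data ridge fit restricted to the input features.
    """
    if not features:
        raise ValueError("no features to check")
    Xs = X[features]
    ref = fit_penalized_cox(Xs, surv, alpha=0, seed=seed)
    ref_sign = np.sign(ref.beta.to_numpy())
    rng = np.random.default_rng(seed + 1)
    counts = np.zeros(len(features))
    failed = 0
    surv_pos = surv.reset_index(drop=True)
    Xv = Xs.to_numpy(dtype=float)
    y_lam = ref.chosen_lambda
    for _ in range(n_boot):
        idx = stratified_bootstrap_resample(surv_pos, horizon_years, rng)
        Xb = Xv[idx]
        sb = surv_pos.iloc[idx]
        mu = Xb.mean(axis=0)
        sd = Xb.std(axis=0, ddof=1)
        sd[~np.isfinite(sd) | (sd == 0)] = 1.0
        b = _ridge_coefs((Xb - mu) / sd, surv_to_sksurv(sb), y_lam)
        if b is None:
            failed += 1
            continue
        counts += (np.sign(b) == ref_sign) & (ref_sign != 0)
    denom = max(n_boot - failed, 1)
    freq = pd.Series(counts / denom, index=features)
    final = list(freq.index[freq >= threshold])
    return final, StabilityReport(freq, threshold, n_boot, failed, seed), ref


# ---------------------------------------------------------------------------
# Domain models and the combined spatial model
# ---------------------------------------------------------------------------

@dataclass
class DomainModel:
    """Final per-domain Cox model: features, ridge coefficients, transforms."""

    domain: str
    features: list[str]
    beta: pd.Series
    center: pd.Series
    scale: pd.Series
    selection_report: StabilityReport | None = None
    sign_report: StabilityReport | None = None
    degenerate: bool = False

    def linear_predictor(self, X: pd.DataFrame) -> pd.Series:
        if self.degenerate or not self.features:
            return pd.Series(0.0, index=X.index)
        Z = (X[self.features] - self.center) / self.scale
        return pd.Series(Z.to_numpy(dtype=float) @ self.beta.to_numpy(), index=X.index)

    def to_dict(self) -> dict:
        return {
            "domain": self.domain,
            "features": self.features,
            "beta": self.beta.to_dict(),
            "center": self.center.to_dict(),
            "scale": self.scale.to_dict(),
            "degenerate": self.degenerate,
        }


def _degenerate_model(domain: str) -> DomainModel:
    log.warning("domain %s: empty final feature set; risk score is constant 1", domain)
    empty = pd.Series(dtype=float)
    return DomainModel(domain, [], empty, empty, empty, degenerate=True)


def fit_domain_model(
    X: pd.DataFrame,
    surv: pd.DataFrame,
    domain: str = "domain",
    n_boot: int = 500,
    threshold: float = 0.9,
    seed: int = 0,
    horizon_years: float = 5.0,
) -> DomainModel:
    """Full two-step pipeline for one domain's feature table.

    stability_select -> sign_stability_check -> final L2 refit on the
    surviving features.  An empty final set yields a degenerate model whose
    risk score is identically 1.
    """
    X = X.loc[surv.index] if X.index.equals(surv.index) or set(surv.index) <= set(X.index) else X
    selected, sel_report = stability_select(
        X, surv, n_boot=n_boot, threshold=threshold, seed=seed, horizon_years=horizon_years
    )
    if not selected:
        m = _degenerate_model(domain)
        m.selection_report = sel_report
        return m
    final, sign_report, _ = sign_stability_check(
        X, surv, selected, n_boot=n_boot, threshold=threshold, seed=seed, horizon_years=horizon_years
    )
    if not final:
        m = _degenerate_model(domain)
        m.selection_report = sel_report
        m.sign_report = sign_report
        return m
    refit = fit_penalized_cox(X[final], surv, alpha=0, seed=seed)
    return DomainModel(
        domain=domain,
        features=final,
        beta=refit.beta,
        center=refit.center,
        scale=refit.scale,
        selection_report=sel_report,
        sign_report=sign_report,
    )


# the undissected-spot model runs the identical pipeline on whole-spot features
fit_null_model = fit_domain_model


@dataclass
class SpatialModel:
    """Per-domain models plus the multiplicative combination rule."""

    models: dict

    def log_risk(self, features_by_domain: dict) -> pd.Series:
        total = None
        for name, model in self.models.items():
            if name not in features_by_domain:
                log.warning("domain %s missing at scoring time; contributes 0", name)
                continue
            lp = model.linear_predictor(features_by_domain[name])
            total = lp if total is None else total.add(lp, fill_value=0.0)
        if total is None:
            raise ValueError("no domain features supplied")
        return total

    def combined_risk(self, features_by_domain: dict) -> pd.Series:
        """Hazard-ratio-scale score ``exp(sum_s f_s' beta_s)`` (> 0)."""
        return np.exp(self.log_risk(features_by_domain))

    def selected_biomarkers(self, domain: str) -> list[str]:
        """Biomarkers named by the domain's final features (for networks)."""
        markers: list[str] = []
        for f in self.models[domain].features:
            parts = f.split("__")[1:]
            for m in parts:
                if m not in markers:
                    markers.append(m)
        return markers


def fit_spatial_model(
    features_by_domain: dict,
    surv: pd.DataFrame,
    n_boot: int = 500,
    threshold: float = 0.9,
    seed: int = 0,
    horizon_years: float = 5.0,
) -> SpatialModel:
    models = {}
    for name, X in features_by_domain.items():
        models[name] = fit_domain_model(
            X, surv, domain=name, n_boot=n_boot, threshold=threshold, seed=seed,
            horizon_years=horizon_years,
        )
    return SpatialModel(models)


# ---------------------------------------------------------------------------
# Clinical model
# ---------------------------------------------------------------------------

@dataclass
class ClinicalModel:
    beta: pd.Series
    converged: bool

    def linear_predictor(self, covars: pd.DataFrame) -> pd.Series:
        Z = clinical_design(covars)
        return pd.Series(Z[self.beta.index].to_numpy() @ self.beta.to_numpy(), index=covars.index)


def clinical_design(surv: pd.DataFrame) -> pd.DataFrame:
    """Design matrix: age, male indicator, one-hot stage II/III (I reference)."""
    out = pd.DataFrame(index=surv.index)
    out["age"] = pd.to_numeric(surv["age"], errors="coerce")
    gender = surv["gender"].astype(str).str.lower()
    out["gender_male"] = (gender.isin(["m", "male", "1"])).astype(float)
    stage = surv["stage"].astype(str).str.upper()
    out["stage_II"] = (stage == "II").astype(float)
    out["stage_III"] = (stage == "III").astype(float)
    return out


def fit_clinical_model(surv: pd.DataFrame) -> ClinicalModel:
    """Unpenalized Cox fit on age, gender, and TNM stage (via lifelines)."""
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = clinical_design(surv)
    df["time"] = surv["time"].to_numpy(dtype=float)
    df["event"] = surv["event"].to_numpy(dtype=int)
    df = df.loc[:, df.nunique() > 1]  # drop constant covariates (e.g., single stage)
    cph = CoxPHFitter()
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        beta = cph.params_
    except ConvergenceError:
        log.warning("clinical Cox fit did not converge; retrying with a ridge penalty")
        converged = False
        cph = CoxPHFitter(penalizer=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        beta = cph.params_
    return ClinicalModel(beta=beta, converged=converged)


def schoenfeld_trend_check(X: pd.DataFrame, beta, surv: pd.DataFrame) -> pd.Series:
    """Diagnostic utility: Pearson correlation of Breslow-style Schoenfeld
    residuals with event time, per feature.  Large |r| hints at a violated
    proportional-hazards assumption.  Not used as a gate anywhere."""
    Xv = np.asarray(X, dtype=float)
    time = np.asarray(surv["time"], dtype=float)
    event = np.asarray(surv["event"], dtype=int)
    eta = Xv @ np.asarray(beta, dtype=float)
    w = np.exp(eta - eta.max())
    resids, times = [], []
    for i in np.flatnonzero(event == 1):
        at_risk = time >= time[i]
        xbar = (w[at_risk, None] * Xv[at_risk]).sum(axis=0) / w[at_risk].sum()
        resids.append(Xv[i] - xbar)
        times.append(time[i])
    R = np.asarray(resids)
    t = np.asarray(times)
    out = {}
    for j, name in enumerate(X.columns):
        r = R[:, j]
        out[name] = float(np.corrcoef(r, t)[0, 1]) if np.std(r) > 0 and len(t) > 2 else np.nan
    return pd.Series(out)
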