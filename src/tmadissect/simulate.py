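"""Synthetic hyperplexed TMA cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes so
every pipeline stage can be exercised without patient data:

* geometry — each patient contributes one circular 0.6 mm spot with an
  epithelial blob (E-cadherin positive cells) surrounded by stroma; the
  epithelial-stromal boundary is the +/-50 µm annulus around the blob edge;
* intensities — log2-scale values built from per-marker baselines, patient
  random intercepts, compartment-specific latent factors (which induce the
  background Kendall-correlation structure), planted patient-varying signals,
  slide offsets, and cell noise;
* outcomes — a proportional-hazards mechanism: each patient's true planted
  domain features are standardized across the cohort, dotted with the planted
  coefficients beta*, and an exponential event time with rate
  ``h0 * exp(eta)`` is drawn; censoring is uniform on (0, 1.5 x horizon).
  The baseline hazard h0 is calibrated by bisection so the expected fraction
  of observed recurrences within the horizon matches the target (default
  0.15, i.e. 65 of 432 patients).

``generate_feature_cohort`` skips the cell level entirely and emits a
feature matrix plus survival table directly, for model-level recovery
studies at full feature dimension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import features as _features
from .tables import CellTable, default_panel, validate_survival

log = logging.getLogger(__name__)

DAY = 1.0 / 365.25


@dataclass(frozen=True)
class PlantedFeature:
    """A ground-truth prognostic feature: which domain, which feature column
    (``mean__<marker>`` or ``tau__<m1>__<m2>``), and its log hazard ratio per
    standard deviation."""

    domain: str  # epithelial | stromal | epi_stromal | spot
    feature: str
    beta: float


@dataclass
class SyntheticCohortConfig:
    n_patients: int = 60
    panel_size: int = 55
    n_epithelial: int = 250
    n_stromal: int = 250
    spot_diameter_um: float = 600.0
    blob_radius_um: float = 180.0
    boundary_halfwidth_um: float = 50.0
    n_slides: int = 2
    slide_effect_sd: float = 0.3
    baseline_lo: float = 4.0
    baseline_hi: float = 9.0
    patient_sd: float = 0.4
    n_factors: int = 3
    factor_loading_sd: float = 0.25
    cell_noise_sd: float = 1.0
    planted: tuple = ()
    planted_mean_sd: float = 1.0
    planted_pair_loading: float = 1.5
    target_event_fraction: float = 0.15  # ~= 65 recurrences per 432 patients
    horizon_years: float = 5.0
    stage_iii_log_hr: float = 0.0
    qc_small_fraction: float = 0.03
    qc_lowq_fraction: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.target_event_fraction < 1:
            raise ValueError("target_event_fraction must be in (0, 1)")
        panel = default_panel(self.panel_size)
        valid = set(_features.feature_names(panel))
        for pf in self.planted:
            if pf.domain not in ("epithelial", "stromal", "epi_stromal", "spot"):
                raise ValueError(f"unknown planted domain {pf.domain!r}")
            if pf.feature not in valid:
                raise ValueError(f"planted feature {pf.feature!r} not in the panel's feature space")

    @property
    def panel(self) -> list[str]:
        return default_panel(self.panel_size)


# ---------------------------------------------------------------------------
# Cell-level generation
# ---------------------------------------------------------------------------

def _patient_state(config: SyntheticCohortConfig, rng) -> dict:
    state = {
        "intercepts": rng.normal(0.0, config.patient_sd, size=config.panel_size),
        "mean_shift": {},
        "pair_strength": {},
    }
    for pf in config.planted:
        if pf.feature.startswith("mean__"):
            state["mean_shift"][(pf.domain, pf.feature)] = rng.normal(0.0, 1.0)
        else:
            state["pair_strength"][(pf.domain, pf.feature)] = rng.uniform(0.0, 1.0)
    return state


def _domain_mask(xy: np.ndarray, is_epi: np.ndarray, config: SyntheticCohortConfig, domain: str):
    center = config.spot_diameter_um / 2.0
    r = np.hypot(xy[:, 0] - center, xy[:, 1] - center)
    if domain == "epithelial":
        return is_epi
    if domain == "stromal":
        return ~is_epi
    if domain == "epi_stromal":
        return np.abs(r - config.blob_radius_um) <= config.boundary_halfwidth_um
    return np.ones(len(xy), dtype=bool)  # spot


def generate_spot(
    config: SyntheticCohortConfig,
    patient_state: dict,
    rng,
    spot_id: str = "p000",
    baselines: np.ndarray | None = None,
    loadings: dict | None = None,
) -> tuple[CellTable, np.ndarray]:
    """One patient's spot.  Returns the cell table and the clean (pre-QC-noise,
    pre-slide-offset) intensity matrix used for ground-truth features."""
    P = config.panel_size
    if baselines is None:
        baselines = rng.uniform(config.baseline_lo, config.baseline_hi, size=P)
    if loadings is None:
        loadings = {
            "epithelial": rng.normal(0.0, config.factor_loading_sd, size=(P, config.n_factors)),
            "stromal": rng.normal(0.0, config.factor_loading_sd, size=(P, config.n_factors)),
        }
    spot_r = config.spot_diameter_um / 2.0
    center = spot_r
    n_e, n_s = config.n_epithelial, config.n_stromal
    # uniform positions: epithelial inside the blob, stromal in the annulus
    re = config.blob_radius_um * np.sqrt(rng.uniform(size=n_e))
    te = rng.uniform(0, 2 * np.pi, size=n_e)
    rs = np.sqrt(rng.uniform(config.blob_radius_um**2, spot_r**2, size=n_s))
    ts = rng.uniform(0, 2 * np.pi, size=n_s)
    x = np.concatenate([center + re * np.cos(te), center + rs * np.cos(ts)])
    y = np.concatenate([center + re * np.sin(te), center + rs * np.sin(ts)])
    is_epi = np.concatenate([np.ones(n_e, dtype=bool), np.zeros(n_s, dtype=bool)])
    n = n_e + n_s
    xy = np.column_stack([x, y])

    intensity = np.tile(baselines + patient_state["intercepts"], (n, 1))
    z = rng.normal(size=(n, config.n_factors))
    intensity[is_epi] += z[is_epi] @ loadings["epithelial"].T
    intensity[~is_epi] += z[~is_epi] @ loadings["stromal"].T
    panel = config.panel
    col = {m: k for k, m in enumerate(panel)}
    for (domain, feat), shift in patient_state["mean_shift"].items():
        mask = _domain_mask(xy, is_epi, config, domain)
        intensity[mask, col[feat.split("__")[1]]] += config.planted_mean_sd * shift
    for (domain, feat), strength in patient_state["pair_strength"].items():
        mask = _domain_mask(xy, is_epi, config, domain)
        _, m1, m2 = feat.split("__")
        zp = rng.normal(size=mask.sum())
        a = config.planted_pair_loading * strength
        intensity[mask, col[m1]] += a * zp
        intensity[mask, col[m2]] += a * zp
    intensity += rng.normal(0.0, config.cell_noise_sd, size=intensity.shape)
    clean = intensity.copy()

    size_px = rng.integers(15, 60, size=n).astype(float)
    small = rng.uniform(size=n) < config.qc_small_fraction
    size_px[small] = rng.integers(1, 11, size=int(small.sum()))
    quality = rng.uniform(0.93, 1.0, size=n)
    lowq = rng.uniform(size=n) < config.qc_lowq_fraction
    quality[lowq] = rng.uniform(0.5, 0.89, size=int(lowq.sum()))

    df = pd.DataFrame(
        {
            "cell_id": [f"{spot_id}_c{i:05d}" for i in range(n)],
            "spot_id": spot_id,
            "slide_id": "s0",
            "x": x,
            "y": y,
            "size_px": size_px,
            "quality_index": quality,
            "ecad_positive": is_epi,
        }
    )
    for k, m in enumerate(panel):
        df[m] = intensity[:, k]
    return CellTable(df=df, panel=panel, log2_applied=True), clean


def _true_planted_features(
    config: SyntheticCohortConfig, table: CellTable, clean: np.ndarray
) -> dict:
    """Ground-truth planted feature values from the clean intensities, using
    the same thresholding/correlation rules as the feature engine but the
    generator's geometric domain definitions."""
    df = table.df
    xy = df[["x", "y"]].to_numpy(dtype=float)
    is_epi = df["ecad_positive"].to_numpy(dtype=bool)
    panel = config.panel
    col = {m: k for k, m in enumerate(panel)}
    out = {}
    for pf in config.planted:
        mask = _domain_mask(xy, is_epi, config, pf.domain)
        parts = pf.feature.split("__")
        if parts[0] == "mean":
            v = clean[mask, col[parts[1]]]
            thr = _features.nearest_rank_threshold(clean[:, col[parts[1]]], 85.0)
            keep = v > thr
            out[(pf.domain, pf.feature)] = float(v[keep].mean()) if keep.any() else np.nan
        else:
            v1 = clean[:, col[parts[1]]]
            v2 = clean[:, col[parts[2]]]
            t1 = _features.nearest_rank_threshold(v1, 85.0)
            t2 = _features.nearest_rank_threshold(v2, 85.0)
            both = mask & (v1 > t1) & (v2 > t2)
            out[(pf.domain, pf.feature)] = _features.kendall_tau(v1[both], v2[both])
    return out


# ---------------------------------------------------------------------------
# Outcome mechanism
# ---------------------------------------------------------------------------

def _event_probability(h0: float, eta: np.ndarray, horizon: float, cens_upper: float) -> float:
    """Closed-form expected fraction of observed events within the horizon
    under exponential event times and uniform censoring on (0, cens_upper)."""
    lam = h0 * np.exp(eta)
    H, u = horizon, cens_upper
    surv_H = np.exp(-lam * H)
    p = (H - (1.0 - surv_H) / lam + (u - H) * (1.0 - surv_H)) / u
    return float(np.mean(p))


def calibrate_baseline_hazard(
    eta: np.ndarray, target: float, horizon: float, cens_upper: float
) -> float:
    """Bisection on h0 so the expected observed-event fraction hits target."""
    lo, hi = 1e-8, 1e4
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if _event_probability(mid, eta, horizon, cens_upper) < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def _draw_survival(
    eta: np.ndarray,
    rng,
    target: float,
    horizon: float,
    exact_events: int | None = None,
):
    n = len(eta)
    cens_upper = 1.5 * horizon
    E = rng.exponential(size=n)
    C = rng.uniform(0.0, cens_upper, size=n)
    if exact_events is None:
        h0 = calibrate_baseline_hazard(eta, target, horizon, cens_upper)
    else:
        # critical h0 at which each patient becomes an observed in-horizon
        # event; pick h0 between the K-th and (K+1)-th order statistic
        crit = np.sort(E / (np.exp(eta) * np.minimum(C, horizon)))
        if exact_events >= n:
            h0 = crit[-1] * 2.0
        else:
            h0 = float(np.sqrt(crit[exact_events - 1] * crit[exact_events])) if exact_events else crit[0] / 2.0
    for attempt in range(10):
        T = E / (h0 * np.exp(eta))
        event = (T <= C).astype(int)
        time = np.minimum(T, C)
        time = np.maximum(np.round(time / DAY), 1.0) * DAY  # quantize to days
        if event.sum() > 0:
            return time, event, h0
        log.warning("all-censored survival draw; doubling the baseline hazard")
        h0 *= 2.0
    raise RuntimeError("could not draw a cohort with at least one event")


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def generate_cohort(
    config: SyntheticCohortConfig, seed: int | None = None, exact_events: int | None = None
):
    """Full synthetic cohort: cell tables, survival table, and ground truth.

    Returns ``(cells, surv, truth)`` where ``cells`` is a single
    :class:`CellTable` holding every patient's spot (slides assigned
    round-robin, with per-slide additive offsets), ``surv`` is a validated
    survival table with stage/age/gender, and ``truth`` records beta*, the
    per-patient true linear predictor eta, and the calibrated h0.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    P = config.panel_size
    baselines = rng.uniform(config.baseline_lo, config.baseline_hi, size=P)
    loadings = {
        "epithelial": rng.normal(0.0, config.factor_loading_sd, size=(P, config.n_factors)),
        "stromal": rng.normal(0.0, config.factor_loading_sd, size=(P, config.n_factors)),
    }
    tables, cleans, states = [], [], []
    pids = [f"p{i:03d}" for i in range(config.n_patients)]
    for pid in pids:
        state = _patient_state(config, rng)
        tab, clean = generate_spot(config, state, rng, spot_id=pid, baselines=baselines, loadings=loadings)
        states.append(state)
        tables.append(tab)
        cleans.append(clean)

    # planted true features -> eta
    feats = {}
    for pid, tab, clean in zip(pids, tables, cleans):
        feats[pid] = _true_planted_features(config, tab, clean)
    eta = np.zeros(config.n_patients)
    beta_star = {}
    for pf in config.planted:
        key = (pf.domain, pf.feature)
        vals = np.array([feats[pid].get(key, np.nan) for pid in pids], dtype=float)
        vals = np.where(np.isnan(vals), np.nanmean(vals), vals)
        sd = vals.std(ddof=0)
        z = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
        eta += pf.beta * z
        beta_star[f"{pf.domain}:{pf.feature}"] = pf.beta

    stage = rng.choice(["I", "II", "III"], size=config.n_patients, p=[0.2, 0.45, 0.35])
    age = np.round(rng.normal(68.0, 10.0, size=config.n_patients), 1)
    gender = rng.choice(["female", "male"], size=config.n_patients)
    if config.stage_iii_log_hr:
        eta = eta + config.stage_iii_log_hr * (stage == "III")

    time, event, h0 = _draw_survival(
        eta, rng, config.target_event_fraction, config.horizon_years, exact_events
    )

    # assemble cells: slides round-robin plus per-slide marker offsets
    slide_ids = [f"s{i % config.n_slides}" for i in range(config.n_patients)]
    offsets = rng.normal(0.0, config.slide_effect_sd, size=(config.n_slides, P))
    panel = config.panel
    frames = []
    for i, (pid, tab) in enumerate(zip(pids, tables)):
        df = tab.df.copy()
        df["slide_id"] = slide_ids[i]
        df[panel] = df[panel].to_numpy() + offsets[i % config.n_slides]
        frames.append(df)
    cells = CellTable(df=pd.concat(frames, ignore_index=True), panel=panel, log2_applied=True)

    surv = validate_survival(
        pd.DataFrame(
            {
                "patient_id": pids,
                "time": time,
                "event": event,
                "stage": stage,
                "age": age,
                "gender": gender,
            }
        )
    )
    truth = {
        "beta_star": beta_star,
        "eta": pd.Series(eta, index=pids),
        "h0": h0,
        "planted": list(config.planted),
        "seed": config.seed if seed is None else seed,
        "true_features": feats,
    }
    return cells, surv, truth


def make_paper_scale_fixture(seed: int = 0):
    """Cohort preset mirroring the study scale: 432 patients, a 55-marker
    panel, and exactly 65 recurrences within the 5-year horizon."""
    config = SyntheticCohortConfig(
        n_patients=432,
        panel_size=55,
        n_epithelial=200,
        n_stromal=200,
        planted=(
            PlantedFeature("epithelial", "mean__m03", 0.7),
            PlantedFeature("stromal", "mean__m11", -0.7),
            PlantedFeature("epi_stromal", "tau__m05__m07", 0.7),
        ),
        seed=seed,
    )
    return generate_cohort(config, exact_events=65)


def generate_feature_cohort(
    n_patients: int = 400,
    n_features: int = 1540,
    n_planted: int = 10,
    hr_per_sd: float = 2.0,
    target_event_fraction: float = 0.15,
    horizon_years: float = 5.0,
    seed: int = 0,
):
    """Feature-level synthetic cohort for model recovery studies.

    Features are iid standard normal; the planted columns (evenly spread,
    alternating sign, |log HR| = log(hr_per_sd) per SD) drive an exponential
    proportional-hazards outcome with uniform censoring.  Returns
    ``(X, surv, truth)`` with truth holding the planted index -> beta map.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_patients, n_features))
    names = [f"f{i:04d}" for i in range(n_features)]
    planted_idx = np.linspace(0, n_features - 1, n_planted, dtype=int)
    beta = {}
    eta = np.zeros(n_patients)
    for k, idx in enumerate(planted_idx):
        b = np.log(hr_per_sd) * (1 if k % 2 == 0 else -1)
        beta[names[idx]] = b
        eta += b * X[:, idx]
    time, event, h0 = _draw_survival(eta, rng, target_event_fraction, horizon_years)
    pids = [f"p{i:03d}" for i in range(n_patients)]
    Xdf = pd.DataFrame(X, index=pids, columns=names)
    surv = validate_survival(
        pd.DataFrame(
            {
                "patient_id": pids,
                "time": time,
                "event": event,
                "stage": rng.choice(["I", "II", "III"], size=n_patients, p=[0.2, 0.45, 0.35]),
                "age": np.round(rng.normal(68, 10, size=n_patients), 1),
                "gender": rng.choice(["female", "male"], size=n_patients),
            }
        )
    )
    truth = {"beta_star": beta, "eta": pd.Series(eta, index=pids), "h0": h0}
    return Xdf, surv, truth
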