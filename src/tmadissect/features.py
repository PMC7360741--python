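"""Per-domain feature engineering: thresholded mean intensities and pairwise
Kendall rank correlations.

For a panel of P biomarkers each spatial domain yields a feature vector of
length ``P + P*(P-1)/2`` (1540 when P = 55): per-biomarker mean intensities
over expressing cells, followed by tie-corrected Kendall tau-b correlations
for every unordered biomarker pair, computed across the cells co-expressing
both markers.

"Expressing" is defined conservatively by a per-biomarker, per-spot
nearest-rank percentile threshold (default 85th): only intensities strictly
above the threshold count as expression.  The threshold distribution is
anchored to the whole spot and then applied inside each of the spot's
domains, so a domain's features are unaffected by cells below threshold.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .tables import CellTable

log = logging.getLogger(__name__)


def nearest_rank_threshold(values, percentile: float) -> float:
    """Nearest-rank percentile: the smallest value with >= p% of values <= it.

    For ``p = 0`` this is the minimum (so "strictly above threshold" keeps
    everything above the minimum).
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0 or np.isnan(v).any():
        raise ValueError("need at least one finite value")
    h = max(int(math.ceil(percentile / 100.0 * v.size)), 1)
    return float(v[h - 1])


def expression_threshold(values, percentile: float):
    """Threshold a per-spot intensity distribution.

    Returns ``(threshold, retained_values, retained_positions)`` where the
    retained values are strictly greater than the nearest-rank percentile of
    the input.  A constant input retains nothing; callers must mark dependent
    features missing.
    """
    v = np.asarray(values, dtype=float)
    thr = nearest_rank_threshold(v, percentile)
    keep = np.flatnonzero(v > thr)
    return thr, v[keep], keep


def spot_thresholds(spot: CellTable, percentile: float = 85.0) -> pd.Series:
    """Per-biomarker expression thresholds from one spot's full distribution."""
    return pd.Series(
        {m: nearest_rank_threshold(spot.df[m].to_numpy(dtype=float), percentile) for m in spot.panel},
        name="threshold",
    )


def kendall_tau(x, y) -> float:
    """Tie-corrected Kendall tau-b; NaN for n < 3 or a constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must be paired and equal length")
    if x.size < 3 or np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan")
    return float(stats.kendalltau(x, y).statistic)


def feature_names(panel) -> list[str]:
    """Fixed feature ordering: means in panel order, then pairs i<j."""
    names = [f"mean__{m}" for m in panel]
    names += [f"tau__{panel[i]}__{panel[j]}" for i in range(len(panel)) for j in range(i + 1, len(panel))]
    return names


def mean_intensity_features(
    domain: CellTable, percentile: float = 85.0, thresholds: pd.Series | None = None
) -> pd.Series:
    """Mean intensity of each biomarker over the domain's expressing cells.

    ``thresholds`` should come from :func:`spot_thresholds` on the whole spot;
    if omitted it is computed from the domain table itself.  Missing (NaN)
    where no cell is above threshold.
    """
    if thresholds is None:
        thresholds = spot_thresholds(domain, percentile) if domain.n_cells else None
    out = {}
    for m in domain.panel:
        if domain.n_cells == 0:
            out[f"mean__{m}"] = np.nan
            continue
        v = domain.df[m].to_numpy(dtype=float)
        keep = v > thresholds[m]
        out[f"mean__{m}"] = float(v[keep].mean()) if keep.any() else np.nan
    if domain.n_cells == 0:
        log.warning("empty domain: all mean-intensity features missing")
    return pd.Series(out)


def correlation_features(
    domain: CellTable,
    percentile: float = 85.0,
    thresholds: pd.Series | None = None,
    min_cells: int = 3,
) -> pd.Series:
    """Kendall tau-b for every unordered biomarker pair over co-expressing cells.

    For pair (i, j) the correlation uses the domain cells whose intensities
    exceed both markers' spot-level thresholds; NaN when fewer than
    ``min_cells`` cells co-express or either vector is constant.
    """
    panel = domain.panel
    if thresholds is None and domain.n_cells:
        thresholds = spot_thresholds(domain, percentile)
    vals = domain.df[panel].to_numpy(dtype=float) if domain.n_cells else np.empty((0, len(panel)))
    masks = [
        vals[:, k] > thresholds[m] if domain.n_cells else np.zeros(0, dtype=bool)
        for k, m in enumerate(panel)
    ]
    out = {}
    for i in range(len(panel)):
        for j in range(i + 1, len(panel)):
            name = f"tau__{panel[i]}__{panel[j]}"
            both = masks[i] & masks[j]
            if both.sum() < min_cells:
                out[name] = np.nan
            else:
                out[name] = kendall_tau(vals[both, i], vals[both, j])
    return pd.Series(out)


def assemble_feature_vector(
    domain: CellTable, percentile: float = 85.0, thresholds: pd.Series | None = None
) -> pd.Series:
    """Concatenated ``[means | taus]`` feature vector in fixed panel order."""
    if thresholds is None and domain.n_cells:
        thresholds = spot_thresholds(domain, percentile)
    means = mean_intensity_features(domain, percentile, thresholds)
    taus = correlation_features(domain, percentile, thresholds)
    vec = pd.concat([means, taus])
    expected = feature_names(domain.panel)
    assert list(vec.index) == expected, "feature ordering invariant violated"
    return vec


def cohort_feature_table(
    domain_tables: dict, thresholds_by_patient: dict, percentile: float = 85.0
) -> pd.DataFrame:
    """Rows = patients, columns = named features, for one spatial domain."""
    rows = {
        str(pid): assemble_feature_vector(tab, percentile, thresholds_by_patient.get(pid))
        for pid, tab in domain_tables.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def complete_features(
    table: pd.DataFrame, max_missing_fraction: float = 0.2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the missing-feature policy for modeling.

    Drop feature columns missing in more than ``max_missing_fraction`` of
    patients; median-impute the rest.  Returns the complete matrix and the
    original missing-mask (for logging/audit).
    """
    mask = table.isna()
    frac = mask.mean(axis=0)
    keep = frac[frac <= max_missing_fraction].index
    dropped = int((frac > max_missing_fraction).sum())
    if dropped:
        log.info("dropping %d features missing in >%.0f%% of patients", dropped, 100 * max_missing_fraction)
    out = table[keep].copy()
    out = out.fillna(out.median(axis=0))
    # columns that are entirely NaN even after the fraction screen
    out = out.dropna(axis=1, how="any")
    return out, mask
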