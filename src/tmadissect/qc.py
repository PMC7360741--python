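"""Cell-level quality filters and slide-level intensity normalization.

The protocol: keep cells strictly larger than 10 px (at x20) whose per-round
DAPI-overlap quality index is at least 0.9; log2-transform raw intensities;
then equalize per-biomarker slide medians to remove slide-to-slide
non-biological variability.  The median shift is additive on log2 scale and
therefore rank-preserving, so all downstream rank correlations are invariant
to it.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .tables import CellTable

log = logging.getLogger(__name__)


def collapse_quality_rounds(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-round quality columns to a single per-cell minimum.

    If columns named ``quality_index_<round>`` exist they are reduced to their
    row-wise minimum in ``quality_index``: a cell failing any imaging round is
    unreliable in every derived quantity.
    """
    rounds = [c for c in df.columns if c.startswith("quality_index_")]
    if not rounds:
        return df
    out = df.copy()
    cols = rounds + (["quality_index"] if "quality_index" in df.columns else [])
    out["quality_index"] = df[cols].min(axis=1)
    return out.drop(columns=rounds)


def filter_cells(
    table: CellTable, min_size_px: float = 10.0, min_quality: float = 0.9
) -> tuple[CellTable, dict]:
    """Apply the cell QC filters; returns the filtered table and removal counts.

    Size is a *strict* lower bound (``size_px > min_size_px``); quality is
    inclusive (``quality_index >= min_quality``).  An empty result is allowed
    (warned, not raised); downstream domain operations handle empty tables.
    """
    df = collapse_quality_rounds(table.df)
    size_ok = df["size_px"].to_numpy(dtype=float) > min_size_px
    quality_ok = df["quality_index"].to_numpy(dtype=float) >= min_quality
    keep = size_ok & quality_ok
    counts = {
        "removed_small": int((~size_ok).sum()),
        "removed_low_quality": int((~quality_ok).sum()),
        "removed_total": int((~keep).sum()),
        "retained": int(keep.sum()),
    }
    if counts["retained"] == 0:
        log.warning("QC removed every cell (of %d)", len(df))
    return table.with_df(df.loc[keep].reset_index(drop=True)), counts


def log2_transform(table: CellTable) -> CellTable:
    """``intensity -> log2(intensity + 1)`` with an at-most-once guard."""
    if table.log2_applied:
        raise ValueError("intensities are already log2 scale; refusing to transform twice")
    df = table.df.copy()
    vals = df[table.panel].to_numpy(dtype=float)
    if (vals < 0).any():
        r, _ = np.argwhere(vals < 0)[0]
        raise ValueError(f"negative raw intensity for cell {df['cell_id'].iloc[r]!r}")
    df[table.panel] = np.log2(vals + 1.0)
    out = table.with_df(df)
    out.log2_applied = True
    return out


def median_normalize(table: CellTable) -> CellTable:
    """Additively shift each slide's per-biomarker log2 intensities so every
    slide's median equals the pooled grand median.

    Post-condition: for every biomarker the per-slide medians agree across
    slides to machine precision.  The shift preserves within-slide ranks.
    """
    if not table.log2_applied:
        raise ValueError("median normalization expects log2-scale intensities")
    df = table.df.copy()
    slides = df["slide_id"]
    for marker in table.panel:
        grand = df[marker].median()
        shift = grand - df.groupby(slides, sort=False)[marker].transform("median")
        df[marker] = df[marker] + shift
    return table.with_df(df)
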