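"""Core tabular containers: per-cell tables, survival tables, biomarker panels.

A :class:`CellTable` wraps a :class:`pandas.DataFrame` with one row per
segmented cell (coordinates in µm, cell size in pixels, a per-round quality
index collapsed to its minimum, an epithelial/stromal compartment call or an
E-cadherin positivity flag, and one log2-scale intensity column per biomarker
in the panel).  The panel is an ordered list of biomarker names; its order
fixes feature indexing for the whole run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("cell_id", "spot_id", "slide_id", "x", "y", "size_px", "quality_index")

DOMAINS = ("epithelial", "stromal", "epi_stromal")


class SchemaError(ValueError):
    """A table violates the expected schema (missing column, bad invariant)."""


class ParseError(ValueError):
    """A cell in a delimited file could not be parsed as the expected type."""


class ReconciliationError(ValueError):
    """Cell and survival tables disagree on the patient/spot universe."""


def make_panel(names) -> list[str]:
    """Validate and return an ordered biomarker panel."""
    names = [str(n) for n in names]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise SchemaError(f"duplicate biomarker names in panel: {dupes}")
    return names


def default_panel(size: int) -> list[str]:
    """A generic numbered panel ``['m01', 'm02', ...]`` used by simulations."""
    return [f"m{i + 1:02d}" for i in range(size)]


@dataclass
class CellTable:
    """Per-cell records for one or more TMA spots plus the biomarker panel.

    Parameters
    ----------
    df :
        One row per cell.  Must contain :data:`REQUIRED_COLUMNS`, at least one
        of ``compartment`` / ``ecad_positive``, and one numeric column per
        panel biomarker.
    panel :
        Ordered biomarker names; defines the intensity columns.
    log2_applied :
        Whether intensities are already on log2 scale.  Guards against a
        double transform.
    """

    df: pd.DataFrame
    panel: list[str]
    log2_applied: bool = True

    def validate(self) -> "CellTable":
        df = self.df
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        if "compartment" not in df.columns and "ecad_positive" not in df.columns:
            raise SchemaError("need a 'compartment' or 'ecad_positive' column")
        for marker in self.panel:
            if marker not in df.columns:
                raise SchemaError(f"missing intensity column for panel biomarker {marker!r}")
            if not np.issubdtype(df[marker].dtype, np.number):
                raise ParseError(f"non-numeric intensity column {marker!r}")
        xy = df[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            bad = int(np.flatnonzero(~np.isfinite(xy).all(axis=1))[0])
            raise SchemaError(f"non-finite coordinates at row {bad}")
        if (df["size_px"].to_numpy(dtype=float) < 0).any():
            raise SchemaError("negative cell size")
        q = df["quality_index"].to_numpy(dtype=float)
        if ((q < 0) | (q > 1)).any():
            raise SchemaError("quality_index outside [0, 1]")
        dup = df.duplicated(subset=["spot_id", "cell_id"])
        if dup.any():
            pair = df.loc[dup, ["spot_id", "cell_id"]].iloc[0]
            raise SchemaError(
                f"duplicate cell_id {pair['cell_id']!r} within spot {pair['spot_id']!r}"
            )
        return self

    # -- convenience ----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.df)

    def copy(self) -> "CellTable":
        return replace(self, df=self.df.copy())

    def with_df(self, df: pd.DataFrame) -> "CellTable":
        return replace(self, df=df)

    def spots(self) -> list:
        return list(pd.unique(self.df["spot_id"]))

    def subset_spot(self, spot_id) -> "CellTable":
        return self.with_df(self.df[self.df["spot_id"] == spot_id])

    def intensities(self) -> pd.DataFrame:
        return self.df[self.panel]


SURVIVAL_COLUMNS = ("patient_id", "time", "event")


def validate_survival(df: pd.DataFrame) -> pd.DataFrame:
    """Check the per-patient survival table and return it indexed by patient.

    Columns: ``patient_id``, ``time`` (years of follow-up, > 0), ``event``
    (recurrence indicator in {0, 1}); optional ``stage`` (I/II/III), ``age``,
    ``gender``.
    """
    for col in SURVIVAL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required survival column {col!r}")
    if df["patient_id"].duplicated().any():
        raise SchemaError("duplicate patient_id in survival table")
    t = df["time"].to_numpy(dtype=float)
    if not np.all(t > 0):
        raise SchemaError("follow-up time must be > 0")
    ev = df["event"].to_numpy()
    if not np.isin(ev, [0, 1]).all():
        raise SchemaError("event indicator must be 0 or 1")
    out = df.copy()
    out["event"] = out["event"].astype(int)
    out["time"] = out["time"].astype(float)
    return out.set_index(out["patient_id"].astype(str), drop=False)


def surv_to_sksurv(surv: pd.DataFrame):
    """Convert a validated survival frame to a scikit-survival structured array."""
    from sksurv.util import Surv

    return Surv.from_arrays(
        event=surv["event"].to_numpy(dtype=bool), time=surv["time"].to_numpy(dtype=float)
    )
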