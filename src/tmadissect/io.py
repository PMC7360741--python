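"""Reading and writing cell tables, survival tables, and result sidecars.

Interchange format is delimited text (comma-separated by default; tabs are
sniffed from the header line).  Every writer can attach a JSON sidecar
recording the config hash and seed so outputs are traceable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .tables import (
    REQUIRED_COLUMNS,
    CellTable,
    ParseError,
    SchemaError,
    make_panel,
    validate_survival,
)

log = logging.getLogger(__name__)


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_cell_table(path, panel, assume_log2: bool = True) -> CellTable:
    """Read a per-cell table from CSV/TSV and validate it against ``panel``.

    Unknown columns are kept out of the table with a logged warning.  A
    missing required column raises :class:`SchemaError` naming the column; a
    non-numeric intensity raises :class:`ParseError` with the row index.
    """
    path = Path(path)
    panel = make_panel(panel)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    expected = set(REQUIRED_COLUMNS) | {"compartment", "ecad_positive", "epi_stromal"} | set(panel)
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        log.warning("ignoring unknown columns in %s: %s", path.name, unknown)
        df = df.drop(columns=unknown)
    for marker in panel:
        if marker not in df.columns:
            raise SchemaError(f"missing intensity column for panel biomarker {marker!r}")
        coerced = pd.to_numeric(df[marker], errors="coerce")
        bad = coerced.isna() & df[marker].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"non-numeric intensity in column {marker!r} at row {row}")
        df[marker] = coerced
    if "ecad_positive" in df.columns:
        df["ecad_positive"] = df["ecad_positive"].astype(bool)
    return CellTable(df=df, panel=panel, log2_applied=assume_log2).validate()


def write_cell_table(table: CellTable, path, config: RunConfig | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, index=False, sep="\t" if path.suffix == ".tsv" else ",")
    if config is not None:
        write_sidecar(path, config)


def read_survival_table(path) -> pd.DataFrame:
    path = Path(path)
    return validate_survival(pd.read_csv(path, sep=_sniff_sep(path)))


def write_survival_table(surv: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    surv.to_csv(path, index=False, sep="\t" if path.suffix == ".tsv" else ",")
    if config is not None:
        write_sidecar(path, config)


def write_sidecar(path, config: RunConfig, extra: dict | None = None) -> Path:
    """Write ``<path>.meta.json`` with the config hash and seed."""
    path = Path(path)
    meta = {"config_hash": config.hash(), "seed": config.seed}
    if extra:
        meta.update(extra)
    sidecar = path.with_name(path.name + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return sidecar


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")
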