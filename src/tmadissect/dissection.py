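"""Virtual dissection of a TMA spot into epithelial, stromal, and
epithelial-stromal spatial domains.

Compartments come straight from E-cadherin labeling: E-cad-positive cells are
epithelial, everything else is stromal.  The epithelial-stromal boundary
domain is built by a three-step circle tessellation: lay partially
overlapping circles (diameter 50 µm, centers on a square lattice) over the
spot, keep only circles containing both E-cad-positive and E-cad-negative
cells, and take the union of the retained discs.  For a dense straight
interface the union converges to a contiguous band two circle-diameters
(100 µm) wide as the lattice spacing shrinks.

The epithelial and stromal domains keep their band cells: the boundary
domain overlaps both compartments rather than carving cells out of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .tables import CellTable, SchemaError

log = logging.getLogger(__name__)


def assign_compartments(table: CellTable) -> CellTable:
    """Set ``compartment`` to epithelial/stromal from E-cadherin positivity.

    A precomputed ``compartment`` column is passed through unchanged.  The
    partition is exhaustive and exclusive by construction.
    """
    df = table.df
    if "compartment" in df.columns:
        bad = ~df["compartment"].isin(["epithelial", "stromal"])
        if bad.any():
            raise SchemaError(f"unknown compartment labels: {sorted(df.loc[bad, 'compartment'].unique())}")
        return table
    if "ecad_positive" not in df.columns:
        raise SchemaError("need 'ecad_positive' or 'compartment' to assign compartments")
    df = df.copy()
    df["compartment"] = np.where(df["ecad_positive"].astype(bool), "epithelial", "stromal")
    return table.with_df(df)


@dataclass
class DomainAssignment:
    """Per-cell boundary-domain membership plus the retained circle centers.

    ``epi_stromal`` is a boolean array aligned with the cell table; ``centers``
    records the retained circle centers per spot (for audit output).
    """

    epi_stromal: np.ndarray
    centers: pd.DataFrame
    circle_diameter_um: float
    center_spacing_um: float


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = max(int(np.floor((hi - lo) / step)) + 1, 1)
    return lo + step * np.arange(n)


def tessellate_boundary(
    table: CellTable,
    circle_diameter_um: float = 50.0,
    center_spacing_um: float | None = None,
) -> DomainAssignment:
    """Run the three-step boundary tessellation on every spot in the table.

    A circle is retained iff it contains at least one epithelial and one
    stromal cell (centroid within ``diameter/2``, inclusive); a cell joins the
    epithelial-stromal domain iff it lies inside the union of retained
    circles.  ``center_spacing_um`` defaults to ``diameter/10`` and must not
    exceed ``diameter/2`` so neighboring circles partially overlap.
    """
    spacing = center_spacing_um if center_spacing_um is not None else circle_diameter_um / 10.0
    if spacing > circle_diameter_um / 2.0:
        raise ValueError("center spacing must be <= circle_diameter/2 for partial overlap")
    r = circle_diameter_um / 2.0
    df = assign_compartments(table).df
    in_band = np.zeros(len(df), dtype=bool)
    all_centers = []
    for spot_id, sub in df.groupby("spot_id", sort=False):
        if len(sub) == 0:
            continue
        pts = sub[["x", "y"]].to_numpy(dtype=float)
        is_epi = (sub["compartment"] == "epithelial").to_numpy()
        if is_epi.all() or (~is_epi).all():
            log.warning("spot %s has a single compartment; boundary domain empty", spot_id)
            continue
        gx = _grid(pts[:, 0].min(), pts[:, 0].max(), spacing)
        gy = _grid(pts[:, 1].min(), pts[:, 1].max(), spacing)
        centers = np.column_stack([m.ravel() for m in np.meshgrid(gx, gy)])
        cell_tree = cKDTree(pts)
        hits = cell_tree.query_ball_point(centers, r)
        keep = np.fromiter(
            (len(h) > 0 and is_epi[h].any() and not is_epi[h].all() for h in hits),
            dtype=bool,
            count=len(centers),
        )
        retained = centers[keep]
        if len(retained):
            center_tree = cKDTree(retained)
            dist, _ = center_tree.query(pts, k=1)
            idx = sub.index[dist <= r]
            in_band[df.index.get_indexer(idx)] = True
            all_centers.append(
                pd.DataFrame({"spot_id": spot_id, "cx": retained[:, 0], "cy": retained[:, 1]})
            )
    centers_df = (
        pd.concat(all_centers, ignore_index=True)
        if all_centers
        else pd.DataFrame(columns=["spot_id", "cx", "cy"])
    )
    return DomainAssignment(
        epi_stromal=in_band,
        centers=centers_df,
        circle_diameter_um=circle_diameter_um,
        center_spacing_um=spacing,
    )


def boundary_band_extent(assignment: DomainAssignment, axis: str = "x") -> float:
    """Extent of the boundary band (the union of retained discs) along one
    axis: outermost retained center plus a radius on each side.  For a dense
    straight interface perpendicular to the axis this converges to twice the
    circle diameter as the lattice spacing shrinks."""
    if len(assignment.centers) == 0:
        return 0.0
    c = assignment.centers["c" + axis]
    r = assignment.circle_diameter_um / 2.0
    return float((c.max() + r) - (c.min() - r))


def split_domains(table: CellTable, assignment: DomainAssignment) -> dict[str, CellTable]:
    """Split a spot table into the three domain tables.

    Epithelial and stromal tables partition the cells; the epithelial-stromal
    table holds every cell flagged by the tessellation (both compartments).
    """
    df = assign_compartments(table).df.reset_index(drop=True)
    band = np.asarray(assignment.epi_stromal, dtype=bool)
    if len(band) != len(df):
        raise ValueError("assignment does not align with the cell table")
    is_epi = (df["compartment"] == "epithelial").to_numpy()
    out = {
        "epithelial": table.with_df(df.loc[is_epi].reset_index(drop=True)),
        "stromal": table.with_df(df.loc[~is_epi].reset_index(drop=True)),
        "epi_stromal": table.with_df(df.loc[band].reset_index(drop=True)),
    }
    for name, t in out.items():
        if t.n_cells == 0:
            log.warning("domain %s is empty", name)
    return out


def dissect_spot(
    table: CellTable,
    circle_diameter_um: float = 50.0,
    center_spacing_um: float | None = None,
) -> tuple[dict[str, CellTable], DomainAssignment]:
    """Convenience: compartments + tessellation + split for one table."""
    labeled = assign_compartments(table)
    assignment = tessellate_boundary(labeled, circle_diameter_um, center_spacing_um)
    return split_domains(labeled, assignment), assignment
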