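"""Recurrence-specific spatial-domain network inference.

Per patient and domain, a correlation matrix **C** over the N biomarkers
named by the domain's final selected features is assembled from the
already-computed Kendall rank correlations, nudged to positive definiteness
by the smallest ridge shrinkage ``C <- (1-d) C + d I`` on a 0.01 grid, and
inverted; partial correlations follow from the precision matrix **P** as
``rho_ij = -P_ij / sqrt(P_ii P_jj)``.

For every biomarker pair, the per-patient partial correlations are split by
outcome (recurrence vs no evidence of disease), histogrammed on [-1, 1], and
compared by the Jensen-Shannon divergence in bits (bounded by 1).  The
resulting symmetric information-distance matrix, thresholded at its 99th
percentile, is the domain's differential network; selected biomarkers that
lose all edges remain as isolated nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy.special import rel_entr

from .features import correlation_features, nearest_rank_threshold
from .tables import CellTable

log = logging.getLogger(__name__)

_LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# Correlation and partial-correlation matrices
# ---------------------------------------------------------------------------

def shrink_to_pd(C: np.ndarray, step: float = 0.01, floor: float = 1e-6):
    """Smallest grid shrinkage ``(1-d) C + d I`` with min eigenvalue >= floor."""
    C = np.asarray(C, dtype=float)
    for k in range(int(1.0 / step) + 1):
        d = k * step
        M = (1.0 - d) * C + d * np.eye(len(C))
        if np.linalg.eigvalsh(M).min() >= floor:
            return M, d
    raise np.linalg.LinAlgError("could not reach positive definiteness by shrinkage")


def build_correlation_matrix(
    domain: CellTable,
    markers: list[str],
    percentile: float = 85.0,
    thresholds: pd.Series | None = None,
    shrink_step: float = 0.01,
):
    """Kendall-tau correlation matrix over ``markers`` for one patient's
    domain table, shrunk to positive definiteness.

    Pairs whose tau is not computable (too few co-expressing cells) are set
    to 0 with a log message.  Returns ``(C as DataFrame, delta)``.
    """
    if len(markers) < 2:
        raise ValueError("need at least two biomarkers for a correlation matrix")
    sub = CellTable(df=domain.df, panel=list(markers), log2_applied=domain.log2_applied)
    taus = correlation_features(sub, percentile, thresholds)
    n_missing = int(taus.isna().sum())
    if n_missing:
        log.info("setting %d missing taus to 0 in correlation matrix", n_missing)
    C = np.eye(len(markers))
    for idx, (name, val) in enumerate(taus.items()):
        _, mi, mj = name.split("__")
        i, j = markers.index(mi), markers.index(mj)
        C[i, j] = C[j, i] = 0.0 if np.isnan(val) else val
    M, delta = shrink_to_pd(C, step=shrink_step)
    return pd.DataFrame(M, index=markers, columns=markers), delta


def partial_correlations(C) -> pd.DataFrame:
    """Partial correlations from a symmetric positive-definite correlation
    matrix: invert to the precision matrix P and normalize its off-diagonals.
    Diagonal is set to 1 by convention."""
    names = list(C.index) if isinstance(C, pd.DataFrame) else list(range(len(C)))
    M = np.asarray(C, dtype=float)
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if np.linalg.eigvalsh(M).min() <= 0:
        raise ValueError("correlation matrix must be positive definite (apply shrinkage first)")
    P = np.linalg.inv(M)
    d = np.sqrt(np.diag(P))
    rho = -P / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=names, columns=names)


# ---------------------------------------------------------------------------
# Group distributions and information distances
# ---------------------------------------------------------------------------

def group_distributions(
    values, groups, n_bins: int = 40, pseudocount: float = 1e-12
):
    """Histogram the per-patient partial correlations of one biomarker pair on
    [-1, 1] for each outcome group.

    Returns ``(P_recurrent, P_nonrecurrent, bin_edges)``; both histograms are
    normalized to sum to one after adding a pseudocount per bin.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=int)
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    out = []
    for g, name in ((1, "recurrent"), (0, "non-recurrent")):
        v = values[groups == g]
        if v.size == 0:
            raise ValueError(f"empty outcome group: {name}")
        h, _ = np.histogram(np.clip(v, -1.0, 1.0), bins=edges)
        h = h.astype(float) + pseudocount
        out.append(h / h.sum())
    return out[0], out[1], edges


def jsd(p, q) -> float:
    """Jensen-Shannon divergence in bits (base 2); symmetric, in [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must share a support")
    for name, v in (("P", p), ("Q", q)):
        if abs(v.sum() - 1.0) > 1e-8:
            raise ValueError(f"{name} is not normalized (sum={v.sum()!r})")
        if (v < 0).any():
            raise ValueError(f"{name} has negative mass")
    m = 0.5 * (p + q)
    div = 0.5 * (rel_entr(p, m).sum() + rel_entr(q, m).sum()) / _LN2
    return float(div)


def distance_matrix(
    partials: dict, outcomes: pd.Series, n_bins: int = 40
) -> pd.DataFrame:
    """Pairwise Jensen-Shannon information distances between the two outcome
    groups' partial-correlation distributions.

    ``partials`` maps patient id -> N x N partial-correlation DataFrame (all
    sharing marker names); ``outcomes`` maps patient id -> {0, 1}.
    """
    pids = list(partials)
    markers = list(partials[pids[0]].index)
    groups = np.asarray([int(outcomes[p]) for p in pids])
    if (groups == 1).sum() < 2 or (groups == 0).sum() < 2:
        raise ValueError("need at least two patients per outcome group")
    stack = np.stack([np.asarray(partials[p], dtype=float) for p in pids])
    D = np.zeros((len(markers), len(markers)))
    for i in range(len(markers)):
        for j in range(i + 1, len(markers)):
            p1, p0, _ = group_distributions(stack[:, i, j], groups, n_bins)
            D[i, j] = D[j, i] = jsd(p1, p0)
    return pd.DataFrame(D, index=markers, columns=markers)


# ---------------------------------------------------------------------------
# Thresholded networks
# ---------------------------------------------------------------------------

@dataclass
class DomainNetwork:
    graph: nx.Graph
    percentile: float
    threshold: float

    @property
    def nodes(self):
        return list(self.graph.nodes)

    @property
    def edges(self):
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]


def threshold_network(D: pd.DataFrame, percentile: float = 99.0) -> DomainNetwork:
    """Keep edges whose information distance is strictly above the
    nearest-rank percentile of the off-diagonal distances; all biomarkers
    stay as nodes (isolated nodes are meaningful)."""
    markers = list(D.index)
    M = np.asarray(D, dtype=float)
    iu = np.triu_indices(len(markers), k=1)
    weights = M[iu]
    if weights.size == 0:
        raise ValueError("need at least one biomarker pair")
    thr = nearest_rank_threshold(weights, percentile)
    g = nx.Graph()
    g.add_nodes_from(markers)
    for i, j, w in zip(iu[0], iu[1], weights):
        if w > thr:
            g.add_edge(markers[i], markers[j], weight=float(w))
    return DomainNetwork(graph=g, percentile=percentile, threshold=float(thr))


def export_network(net: DomainNetwork, basename) -> dict:
    """Write GraphML plus a TSV edge list (node_i, node_j, weight) and a node
    list (for external enrichment tools).  Returns the written paths."""
    from pathlib import Path

    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    graphml = base.with_suffix(".graphml")
    nx.write_graphml(net.graph, graphml)
    edges = base.with_suffix(".edges.tsv")
    with open(edges, "w") as fh:
        fh.write("node_i\tnode_j\tweight\n")
        for u, v, w in sorted(net.edges):
            fh.write(f"{u}\t{v}\t{w!r}\n")
    nodes = base.with_suffix(".nodes.txt")
    nodes.write_text("".join(f"{n}\n" for n in net.nodes))
    return {"graphml": graphml, "edges": edges, "nodes": nodes}


def read_network(graphml_path) -> DomainNetwork:
    g = nx.read_graphml(graphml_path)
    return DomainNetwork(graph=g, percentile=float("nan"), threshold=float("nan"))
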