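"""Genus co-occurrence networks from pairwise Pearson correlations.

Workflow: filter rare genera, compute all-pairs Pearson r on
replicate-averaged relative abundances with two-sided p-values from
t = r sqrt((n-2)/(1-r^2)), optionally Benjamini-Hochberg adjust across
pairs, then keep edges with |r| > 0.80 (strict) and p < 0.05. Node
degree and degree-ranked key genera summarize the graph; exports are
Cytoscape-readable (edge/node TSV and GraphML).
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from decaywood.diff_abundance import benjamini_hochberg
from decaywood.tables_io import CountMatrix

logger = logging.getLogger(__name__)


def filter_genera(cm: CountMatrix, min_representatives: int = 5,
                  mode: str = "reads") -> CountMatrix:
    """Drop genera with too few representatives.

    ``mode="reads"`` (default) keeps genera whose total read count
    across samples is >= ``min_representatives``; ``mode="samples"`` is
    the prevalence alternative (present in that many samples).
    """
    if mode == "reads":
        keep = cm.data.columns[cm.data.sum(axis=0) >= min_representatives]
    elif mode == "samples":
        keep = cm.data.columns[(cm.data > 0).sum(axis=0)
                               >= min_representatives]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(keep) == 0:
        raise ValueError(
            f"no genus has >= {min_representatives} {mode}; "
            "reduce the threshold")
    return CountMatrix(cm.data[list(keep)].copy())


def correlation_matrix(abund: pd.DataFrame):
    """All-pairs Pearson r and two-sided p over genera (columns).

    ``abund`` holds one row per (parent) sample. Genera with zero
    variance are excluded with a warning. Needs >= 4 samples for the
    t-based p-value (n - 2 df) to be meaningful.
    """
    n = abund.shape[0]
    if n < 4:
        raise ValueError(f"need >= 4 samples for correlation p-values, "
                         f"got {n}")
    var = abund.var(axis=0, ddof=0)
    constant = list(abund.columns[var == 0])
    if constant:
        logger.warning("excluding %d constant genera from correlations",
                       len(constant))
        abund = abund.drop(columns=constant)
    if abund.shape[1] < 2:
        raise ValueError("need at least 2 varying genera")
    x = abund.to_numpy()
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    np.fill_diagonal(p, 0.0)
    genera = list(abund.columns)
    return (pd.DataFrame(r, index=genera, columns=genera),
            pd.DataFrame(p, index=genera, columns=genera))


def build_network(r: pd.DataFrame, p: pd.DataFrame,
                  abs_r: float = 0.80, p_max: float = 0.05,
                  use_fdr: bool = False, q_max: float = 0.05,
                  kingdoms: dict[str, str] | None = None) -> nx.Graph:
    """Threshold the correlation matrices into a co-occurrence graph.

    An unordered genus pair becomes an edge iff |r| > ``abs_r``
    (strictly) and p < ``p_max`` (and q < ``q_max`` when ``use_fdr``).
    Only genera incident to at least one edge become nodes. Edge
    attributes: r, p, q (NaN without FDR), sign; node attributes:
    kingdom (from ``kingdoms``, default "unknown") and degree.
    """
    if list(r.index) != list(p.index) or list(r.columns) != list(p.columns):
        raise ValueError("r and p matrices must be aligned")
    genera = list(r.index)
    iu = np.triu_indices(len(genera), k=1)
    pair_r = r.to_numpy()[iu]
    pair_p = p.to_numpy()[iu]
    pair_q = benjamini_hochberg(pair_p) if len(pair_p) else np.array([])
    keep = (np.abs(pair_r) > abs_r) & (pair_p < p_max)
    if use_fdr:
        keep &= pair_q < q_max

    g = nx.Graph()
    g.graph["thresholds"] = {"abs_r": abs_r, "p_max": p_max,
                             "use_fdr": use_fdr,
                             "q_max": q_max if use_fdr else None}
    for k in np.flatnonzero(keep):
        a, b = genera[iu[0][k]], genera[iu[1][k]]
        g.add_edge(a, b, r=float(pair_r[k]), p=float(pair_p[k]),
                   q=float(pair_q[k]),
                   sign="positive" if pair_r[k] > 0 else "negative")
    kingdoms = kingdoms or {}
    for node in g.nodes:
        g.nodes[node]["kingdom"] = kingdoms.get(node, "unknown")
        g.nodes[node]["degree"] = int(g.degree[node])
    return g


def network_stats(net: nx.Graph) -> dict:
    """Node/edge counts, average degree 2E/N, per-node degree, key nodes."""
    n, e = net.number_of_nodes(), net.number_of_edges()
    degree = {node: int(d) for node, d in net.degree()}
    key_nodes = sorted(degree, key=lambda g: (-degree[g], g))
    return {
        "n_nodes": n,
        "n_edges": e,
        "average_degree": (2.0 * e / n) if n else 0.0,
        "degree": degree,
        "key_nodes": key_nodes,
    }


def export_network(net: nx.Graph, edge_path=None, node_path=None,
                   graphml_path=None) -> None:
    """Write Cytoscape-readable edge list TSV, node table TSV, GraphML."""
    if edge_path is not None:
        rows = [{"source": a, "target": b, **d}
                for a, b, d in sorted(net.edges(data=True))]
        cols = ["source", "target", "r", "p", "q", "sign"]
        pd.DataFrame(rows, columns=cols).to_csv(edge_path, sep="\t",
                                                index=False)
    if node_path is not None:
        rows = [{"genus": g, "kingdom": d.get("kingdom", "unknown"),
                 "degree": d.get("degree", 0)}
                for g, d in sorted(net.nodes(data=True))]
        pd.DataFrame(rows, columns=["genus", "kingdom", "degree"]) \
            .to_csv(node_path, sep="\t", index=False)
    if graphml_path is not None:
        g = net.copy()
        g.graph.pop("thresholds", None)  # GraphML rejects dict attributes
        nx.write_graphml(g, graphml_path)
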