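"""Integrated co-expression network assembly and topological diagnostics.

The integrated network is the union, over the exon, position and allele
levels, of all gene pairs with a non-zero significance-weighted CCA weight.
Edges carry their per-level weights plus a combined weight (the maximum
across levels, i.e. the strongest single-level evidence); nodes are exactly
the genes incident to at least one retained edge.

Degree assortativity is the Pearson correlation between the degrees at the
two ends of each edge, computed over the double-counted (directed) edge
list; negative values mean hubs preferentially attach to low-degree nodes
(disassortative), the signature reported for biological networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .cca import CCAEdgeScore

__all__ = [
    "build_network",
    "assortativity_coefficient",
    "compare_assortativity",
    "UndefinedAssortativityError",
    "write_edge_list",
    "read_edge_list",
]

LEVEL_ATTRS = {"exon": "w_exon", "position": "w_position", "allele": "w_allele"}


class UndefinedAssortativityError(ValueError):
    """Degree assortativity is undefined (constant endpoint degrees)."""


def build_network(scores: list[CCAEdgeScore]) -> nx.Graph:
    """Assemble the integrated gene network from per-level edge scores.

    An edge is kept iff any level weight is > 0; the node set is the genes
    incident to at least one edge.  Self-pairs are rejected and a duplicate
    (pair, level) entry is a pipeline bug, reported as an error.
    Idempotent and independent of the score-list order.
    """
    g = nx.Graph()
    seen: set[tuple[str, str, str]] = set()
    for s in scores:
        if s.gene_a == s.gene_b:
            raise ValueError(f"self-pair score for {s.gene_a}")
        a, b = sorted((s.gene_a, s.gene_b))
        key = (a, b, s.level)
        if key in seen:
            raise ValueError(f"duplicate score for pair {a}-{b} at level {s.level}")
        seen.add(key)
        if s.weight <= 0:
            continue
        if not g.has_edge(a, b):
            g.add_edge(a, b, levels=set())
        attr = g[a][b]
        attr[LEVEL_ATTRS[s.level]] = s.weight
        attr["levels"].add(s.level)
    for _, _, attr in g.edges(data=True):
        attr["w_combined"] = max(
            attr.get(col, 0.0) for col in LEVEL_ATTRS.values()
        )
        attr["levels"] = frozenset(attr["levels"])
    return g


def _endpoint_degrees(net: nx.Graph) -> tuple[np.ndarray, np.ndarray]:
    deg = dict(net.degree())
    x, y = [], []
    for u, v in net.edges():
        x.extend((deg[u], deg[v]))
        y.extend((deg[v], deg[u]))
    return np.asarray(x, float), np.asarray(y, float)


def assortativity_coefficient(net: nx.Graph) -> float:
    """Newman degree assortativity: Pearson correlation of the endpoint
    degrees over the double-counted edge list.

    Raises :class:`UndefinedAssortativityError` when every endpoint has the
    same degree (e.g. a cycle or a perfect clique), where the correlation
    is 0/0 — an explicitly undefined outcome, never reported as 0.
    """
    if net.number_of_edges() < 2:
        raise UndefinedAssortativityError("need at least 2 edges")
    x, y = _endpoint_degrees(net)
    if np.ptp(x) == 0:
        raise UndefinedAssortativityError("constant endpoint degrees")
    return float(np.corrcoef(x, y)[0, 1])


def compare_assortativity(
    net: nx.Graph, references: dict[str, nx.Graph] | None = None
) -> pd.DataFrame:
    """Tabulate assortativity for the integrated network and any
    user-supplied reference graphs.

    Columns: network, n_nodes, n_edges, assortativity (NaN when
    undefined), classification (assortative / disassortative / neutral /
    undefined).  Empty references are skipped with a warning row.
    """
    import warnings

    rows = []
    graphs = {"integrated": net, **(references or {})}
    for name, g in graphs.items():
        if g.number_of_edges() == 0:
            warnings.warn(f"reference network {name!r} is empty; skipped")
            continue
        try:
            coeff = assortativity_coefficient(g)
            label = (
                "assortative" if coeff > 0
                else "disassortative" if coeff < 0
                else "neutral"
            )
        except UndefinedAssortativityError:
            coeff, label = float("nan"), "undefined"
        rows.append(
            {
                "network": name,
                "n_nodes": g.number_of_nodes(),
                "n_edges": g.number_of_edges(),
                "assortativity": coeff,
                "classification": label,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# edge-list I/O
# ---------------------------------------------------------------------------

_COLS = ["gene_a", "gene_b", "w_exon", "w_position", "w_allele", "w_combined"]


def write_edge_list(net: nx.Graph, path) -> None:
    """Write the network as a TSV with per-level and combined weights
    (absent level = empty field)."""
    rows = []
    for u, v in sorted(net.edges()):
        attr = net[u][v]
        rows.append(
            [u, v]
            + [attr.get(c, np.nan) for c in ("w_exon", "w_position", "w_allele")]
            + [attr.get("w_combined", np.nan)]
        )
    pd.DataFrame(rows, columns=_COLS).to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> nx.Graph:
    """Read a TSV written by :func:`write_edge_list` (or any edge list with
    at least gene_a/gene_b columns)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_a", "gene_b"}.issubset(df.columns):
        raise ValueError("edge list needs gene_a and gene_b columns")
    g = nx.Graph()
    for _, row in df.iterrows():
        attrs = {}
        levels = set()
        for level, col in LEVEL_ATTRS.items():
            if col in df.columns and pd.notna(row[col]):
                attrs[col] = float(row[col])
                levels.add(level)
        if "w_combined" in df.columns and pd.notna(row.get("w_combined")):
            attrs["w_combined"] = float(row["w_combined"])
        g.add_edge(str(row["gene_a"]), str(row["gene_b"]), levels=frozenset(levels), **attrs)
    return g


def write_graphml(net: nx.Graph, path) -> None:
    """GraphML export for external viewers (levels flattened to a string)."""
    g = net.copy()
    for _, _, attr in g.edges(data=True):
        attr["levels"] = ",".join(sorted(attr.get("levels", ())))
    nx.write_graphml(g, path)
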