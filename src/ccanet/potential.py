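"""PPI-guided candidate-gene calling from disease-related modules.

For each disease-related co-expression module: induce its protein-protein
interaction (PPI) subnetwork from a STRING-style edge table, detect dense
PPI sub-modules with MCODE, test each sub-module for annotation enrichment
with a one-sided hypergeometric test against a user gene-set (GMT) file,
and flag sub-modules whose significantly enriched terms match configured
disease-process keywords.  Candidate genes are the members of flagged
sub-modules plus the *mediators* — genes of the module's PPI subnetwork
outside the sub-module but connected to a member within a configurable
number of hops.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy import stats

from .mcode import MCODEParams, Module, find_modules

__all__ = [
    "load_ppi",
    "read_gmt",
    "module_ppi_subnetwork",
    "hypergeometric_enrichment",
    "call_potential_genes",
    "EnrichmentResult",
    "PotentialGeneCall",
    "DEFAULT_KEYWORDS",
]

#: disease-process keywords (translation / energy / homeostasis themes)
DEFAULT_KEYWORDS = (
    "translation",
    "ribosome",
    "energy",
    "electron transport",
    "oxidative phosphorylation",
    "homeostasis",
)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    name: str
    k_overlap: int
    term_size: int
    query_size: int
    universe_size: int
    p_value: float
    selected: bool
    flagged_disease_related: bool


@dataclass(frozen=True)
class PotentialGeneCall:
    gene: str
    role: str  # "submodule_member" | "mediator"
    source_submodule: str
    supporting_edges: tuple[tuple[str, str], ...] = ()


# ---------------------------------------------------------------------------
# input readers
# ---------------------------------------------------------------------------

def load_ppi(
    path,
    score_cutoff: int = 400,
    id_map: dict[str, str] | None = None,
) -> nx.Graph:
    """Load a STRING-style PPI table (protein_a, protein_b, combined_score).

    Whitespace- or tab-separated with a header.  Edges below
    ``score_cutoff`` are dropped (inclusive >= keeps), self-interactions
    are removed, and duplicate pairs keep the maximum score.  ``id_map``
    optionally translates protein ids to gene symbols; unmapped ids are
    retained verbatim with a warning.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas reports the line
        raise ValueError(f"malformed PPI file {path}: {exc}") from exc
    needed = {"protein_a", "protein_b", "combined_score"}
    if not needed.issubset(df.columns):
        raise ValueError(f"PPI file missing columns {needed - set(df.columns)}")
    if df[["protein_a", "protein_b"]].isna().any().any():
        bad = int(df[["protein_a", "protein_b"]].isna().any(axis=1).idxmax()) + 2
        raise ValueError(f"malformed PPI line {bad}: missing protein id")
    scores = pd.to_numeric(df["combined_score"], errors="coerce")
    if scores.isna().any():
        bad = int(scores.isna().idxmax()) + 2  # +2: header + 1-based
        raise ValueError(f"malformed PPI line {bad}: non-numeric combined_score")

    g = nx.Graph()
    n_self = 0
    unmapped: set[str] = set()

    def _map(pid: str) -> str:
        pid = str(pid)
        if id_map is None:
            return pid
        if pid not in id_map:
            unmapped.add(pid)
            return pid
        return id_map[pid]

    for a, b, s in zip(df["protein_a"], df["protein_b"], scores):
        s = int(s)
        if s < score_cutoff:
            continue
        a, b = _map(a), _map(b)
        if a == b:
            n_self += 1
            continue
        if g.has_edge(a, b):
            g[a][b]["combined_score"] = max(g[a][b]["combined_score"], s)
        else:
            g.add_edge(a, b, combined_score=s)
    if unmapped:
        warnings.warn(f"{len(unmapped)} PPI ids had no mapping; kept verbatim")
    g.graph["n_self_loops_dropped"] = n_self
    g.graph["score_cutoff"] = score_cutoff
    return g


def read_gmt(path) -> dict[str, tuple[str, frozenset[str]]]:
    """Parse a GMT file: term <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {lineno}: need term, description, genes")
            term, desc, genes = parts[0], parts[1], parts[2:]
            sets[term] = (desc, frozenset(g for g in genes if g))
    return sets


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------

def module_ppi_subnetwork(
    module: Module | list[str], ppi: nx.Graph
) -> tuple[nx.Graph, float]:
    """PPI subgraph induced on a module's gene set, plus the fraction of
    module genes present in the PPI network (coverage)."""
    genes = sorted(module.members) if isinstance(module, Module) else sorted(module)
    present = [g for g in genes if g in ppi]
    coverage = len(present) / len(genes) if genes else 0.0
    sub = ppi.subgraph(present).copy()
    if sub.number_of_edges() == 0:
        warnings.warn("module PPI subnetwork has no edges; sub-module detection will be skipped")
    return sub, coverage


def hypergeometric_enrichment(
    query: set[str] | list[str],
    gene_sets: dict[str, tuple[str, frozenset[str]]],
    universe: set[str] | list[str],
    alpha: float = 0.05,
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation test per term.

    With universe size N, term size K (restricted to the universe), query
    size n and overlap k, ``p = P[X >= k]`` for
    ``X ~ Hypergeom(N, K, n)``.  Terms with ``p < alpha`` are selected;
    selected terms whose name matches a keyword (case-insensitive
    substring) are flagged disease-related.
    """
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        raise ValueError("query genes must be contained in the universe")
    if not query:
        return []
    results = []
    n = len(query)
    N = len(universe)
    kws = tuple(k.lower() for k in keywords)
    for term, (desc, genes) in gene_sets.items():
        term_genes = genes & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(query & term_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(p, 1.0)
        selected = p < alpha
        label = f"{term} {desc}".lower()
        results.append(
            EnrichmentResult(
                term=term,
                name=desc,
                k_overlap=k,
                term_size=K,
                query_size=n,
                universe_size=N,
                p_value=p,
                selected=selected,
                flagged_disease_related=selected and any(kw in label for kw in kws),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def call_potential_genes(
    flagged_submodules: list[Module],
    module_ppi: nx.Graph,
    mediator_depth: int = 1,
) -> list[PotentialGeneCall]:
    """Candidate genes: members of flagged PPI sub-modules plus mediators.

    A mediator is a gene of the module's PPI graph outside the flagged
    sub-module, connected to at least one member within ``mediator_depth``
    hops; its call records the certifying path edges.  The call set is the
    union over flagged sub-modules, deduplicated with the member role
    taking precedence, and grows monotonically with ``mediator_depth``.
    """
    if mediator_depth < 1:
        raise ValueError("mediator_depth must be >= 1")
    calls: dict[str, PotentialGeneCall] = {}
    for sub in flagged_submodules:
        for g in sorted(sub.members):
            if g not in calls or calls[g].role == "mediator":
                calls[g] = PotentialGeneCall(
                    gene=g, role="submodule_member", source_submodule=sub.id
                )
        # breadth-first out to mediator_depth hops from the member set
        dist = {g: 0 for g in sub.members if g in module_ppi}
        parent: dict[str, str] = {}
        frontier = sorted(dist)
        for depth in range(1, mediator_depth + 1):
            nxt = []
            for u in frontier:
                for w in sorted(module_ppi.neighbors(u)):
                    if w in dist:
                        continue
                    dist[w] = depth
                    parent[w] = u
                    nxt.append(w)
            frontier = nxt
        for g, d in sorted(dist.items()):
            if d == 0 or g in sub.members:
                continue
            if g in calls:  # member call (from any sub-module) wins
                continue
            path_edges = []
            node = g
            while node in parent:
                path_edges.append((parent[node], node))
                node = parent[node]
            calls[g] = PotentialGeneCall(
                gene=g,
                role="mediator",
                source_submodule=sub.id,
                supporting_edges=tuple(reversed(path_edges)),
            )
    return sorted(calls.values(), key=lambda c: c.gene)


def analyze_disease_module(
    module_genes: list[str],
    ppi: nx.Graph,
    gene_sets: dict[str, tuple[str, frozenset[str]]],
    universe: set[str],
    mcode_params: MCODEParams = MCODEParams(),
    alpha: float = 0.05,
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS,
    mediator_depth: int = 1,
    module_id: str = "module",
) -> dict:
    """Full per-module pass: PPI subnetwork -> sub-modules -> enrichment ->
    candidate-gene calls.  Returns a JSON-serialisable report dict."""
    sub_ppi, coverage = module_ppi_subnetwork(module_genes, ppi)
    submodules = find_modules(sub_ppi, mcode_params, source_graph=f"{module_id}-ppi")
    submodules = [
        Module(
            id=f"{module_id}.{m.id}", members=m.members, seed=m.seed,
            score=m.score, source_graph=m.source_graph,
        )
        for m in submodules
    ]
    enrichment: dict[str, list[EnrichmentResult]] = {}
    flagged = []
    for m in submodules:
        res = hypergeometric_enrichment(
            set(m.members) & universe, gene_sets, universe, alpha, keywords
        )
        enrichment[m.id] = res
        if any(r.flagged_disease_related for r in res):
            flagged.append(m)
    calls = call_potential_genes(flagged, sub_ppi, mediator_depth)
    return {
        "module_id": module_id,
        "ppi_coverage": coverage,
        "submodules": submodules,
        "enrichment": enrichment,
        "flagged_submodules": flagged,
        "calls": calls,
    }


def write_calls(report: dict | list, path_json, path_tsv) -> None:
    """Write the per-module report JSON and a flat TSV of called genes."""
    reports = report if isinstance(report, list) else [report]
    payload = []
    rows = []
    for rep in reports:
        payload.append(
            {
                "module_id": rep["module_id"],
                "ppi_coverage": rep["ppi_coverage"],
                "submodules": [
                    {"id": m.id, "seed": m.seed, "score": m.score,
                     "members": sorted(m.members)}
                    for m in rep["submodules"]
                ],
                "flagged_submodules": [m.id for m in rep["flagged_submodules"]],
                "enrichment": {
                    mid: [
                        {
                            "term": r.term, "name": r.name, "k": r.k_overlap,
                            "K": r.term_size, "n": r.query_size,
                            "N": r.universe_size, "p_value": r.p_value,
                            "selected": r.selected,
                            "disease_related": r.flagged_disease_related,
                        }
                        for r in res
                    ]
                    for mid, res in rep["enrichment"].items()
                },
                "calls": [
                    {
                        "gene": c.gene, "role": c.role,
                        "source_submodule": c.source_submodule,
                        "supporting_edges": [list(e) for e in c.supporting_edges],
                    }
                    for c in rep["calls"]
                ],
            }
        )
        rows += [
            {"gene": c.gene, "role": c.role, "source_submodule": c.source_submodule}
            for c in rep["calls"]
        ]
    with open(path_json, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    pd.DataFrame(rows, columns=["gene", "role", "source_submodule"]).to_csv(
        path_tsv, sep="\t", index=False
    )
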