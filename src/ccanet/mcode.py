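"""MCODE-style dense-module detection.

Re-implements the three-stage molecular-complex-detection scheme on any
simple undirected graph:

1. *Vertex weighting* — each vertex is weighted by ``k * density`` of the
   highest-k-core of its closed neighbourhood (the vertex plus its
   neighbours); vertices below the degree cutoff get weight 0.
2. *Complex prediction* — starting from the highest-weight unvisited seed,
   the module grows outward over neighbours whose weight is at least
   ``(1 - node_score_cutoff) * seed_weight``; every included vertex is
   marked visited, so a vertex belongs to at most one module.
3. *Post-processing* — candidate modules lacking a ``k_core`` are
   discarded; *haircut* trims tree-like appendages by keeping the 2-core;
   *fluff* (off by default) adds boundary neighbours whose closed
   neighbourhood density exceeds the fluff cutoff.

Detection is purely topological (unweighted edges); co-expression weights
are carried through for reporting only.  All tie-breaks are lexicographic
on vertex id, so results are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = ["MCODEParams", "Module", "vertex_weights", "find_modules",
           "write_modules_json", "write_modules_tsv"]


@dataclass(frozen=True)
class MCODEParams:
    """Published MCODE defaults; every knob is configuration, not constant."""

    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2  # VWP: vertex weight percentage
    k_core: int = 2
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.5
    max_depth: int = 100

    def validate(self) -> None:
        if self.degree_cutoff < 1:
            raise ValueError("degree_cutoff must be >= 1")
        if not (0.0 <= self.node_score_cutoff < 1.0):
            raise ValueError("node_score_cutoff must be in [0, 1)")
        if self.k_core < 1:
            raise ValueError("k_core must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass(frozen=True)
class Module:
    """A detected dense module; ``score`` is density x size of its induced
    subgraph."""

    id: str
    members: frozenset[str]
    seed: str
    score: float
    source_graph: str = ""

    @property
    def size(self) -> int:
        return len(self.members)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _highest_k_core(g: nx.Graph) -> tuple[int, nx.Graph]:
    """Highest-k core of ``g``: the maximum k with a non-empty k-core, and
    that core's induced subgraph."""
    if g.number_of_nodes() == 0:
        return 0, g
    core = nx.core_number(g)
    k = max(core.values())
    nodes = [v for v, c in core.items() if c >= k]
    return k, g.subgraph(nodes)


def vertex_weights(graph: nx.Graph, degree_cutoff: int = 2) -> dict[str, float]:
    """Stage-1 MCODE weights: ``k * density`` of the highest-k-core of each
    vertex's closed neighbourhood; 0 below the degree cutoff."""
    weights: dict[str, float] = {}
    for v in graph.nodes():
        if graph.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = graph.subgraph([v, *graph.neighbors(v)])
        k, core = _highest_k_core(nbhd)
        weights[v] = k * _density(core)
    return weights


def _expand(
    graph: nx.Graph,
    seed,
    weights: dict,
    visited: set,
    threshold: float,
    max_depth: int,
) -> set:
    """Seeded outward expansion including unvisited vertices meeting the
    weight threshold, breadth-first up to ``max_depth`` hops."""
    members = {seed}
    visited.add(seed)
    frontier = [seed]
    depth = 0
    while frontier and depth < max_depth:
        nxt = []
        for u in frontier:
            for w in sorted(graph.neighbors(u), key=str):
                if w in visited:
                    continue
                if weights[w] >= threshold:
                    visited.add(w)
                    members.add(w)
                    nxt.append(w)
        frontier = nxt
        depth += 1
    return members


def _fluff(graph: nx.Graph, members: set, cutoff: float) -> set:
    """Add boundary neighbours whose closed-neighbourhood density exceeds
    ``cutoff`` (fluffed vertices may overlap other modules)."""
    extra = set()
    for u in sorted(members, key=str):
        for w in graph.neighbors(u):
            if w in members or w in extra:
                continue
            nbhd = graph.subgraph([w, *graph.neighbors(w)])
            if _density(nbhd) > cutoff:
                extra.add(w)
    return members | extra


def find_modules(
    graph: nx.Graph,
    params: MCODEParams = MCODEParams(),
    source_graph: str = "",
) -> list[Module]:
    """Detect dense modules, sorted by score descending (ties by smallest
    member id).  Every reported module induces a connected subgraph."""
    params.validate()
    if graph.number_of_nodes() == 0:
        return []
    if any(graph.has_edge(v, v) for v in graph.nodes()):
        raise ValueError("graph must be simple (no self-loops)")

    weights = vertex_weights(graph, params.degree_cutoff)
    order = sorted(graph.nodes(), key=lambda v: (-weights[v], str(v)))
    visited: set = set()
    raw: list[tuple[set, str]] = []
    for seed in order:
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = (1.0 - params.node_score_cutoff) * weights[seed]
        members = _expand(graph, seed, weights, visited, threshold, params.max_depth)
        raw.append((members, seed))

    modules: list[Module] = []
    for members, seed in raw:
        sub = graph.subgraph(members)
        if sub.number_of_nodes() < 2:
            continue
        # discard candidates without a k_core
        core = nx.core_number(sub)
        if max(core.values()) < params.k_core:
            continue
        if params.fluff:
            members = _fluff(graph, set(members), params.fluff_density_cutoff)
            sub = graph.subgraph(members)
        if params.haircut:
            sub = nx.k_core(sub, 2)
            if sub.number_of_nodes() == 0:
                continue
        # keep the component containing the seed (or the largest one if the
        # seed itself was trimmed; ties by smallest member id)
        comps = sorted(
            nx.connected_components(sub), key=lambda c: (-len(c), min(map(str, c)))
        )
        final = next((c for c in comps if seed in c), comps[0])
        sub = graph.subgraph(final)
        score = _density(sub) * sub.number_of_nodes()
        if score <= 0:
            continue
        modules.append(
            Module(
                id="",
                members=frozenset(final),
                seed=seed,
                score=score,
                source_graph=source_graph,
            )
        )
    modules.sort(key=lambda m: (-m.score, min(map(str, m.members))))
    return [
        Module(
            id=f"M{i+1}", members=m.members, seed=m.seed, score=m.score,
            source_graph=m.source_graph,
        )
        for i, m in enumerate(modules)
    ]


def write_modules_json(modules: list[Module], path) -> None:
    payload = [
        {
            "id": m.id,
            "seed": m.seed,
            "score": m.score,
            "size": m.size,
            "members": sorted(m.members, key=str),
            "source_graph": m.source_graph,
        }
        for m in modules
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def write_modules_tsv(modules: list[Module], path) -> None:
    rows = [
        {"module_id": m.id, "gene": g} for m in modules for g in sorted(m.members, key=str)
    ]
    pd.DataFrame(rows, columns=["module_id", "gene"]).to_csv(
        path, sep="\t", index=False
    )
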