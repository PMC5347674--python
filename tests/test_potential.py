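"""PPI loading, hypergeometric enrichment, and candidate-gene calling."""

import math

import networkx as nx
import numpy as np
import pytest

import ccanet as cn
from ccanet.mcode import Module
from ccanet.potential import analyze_disease_module, call_potential_genes


def _write_ppi(path, rows):
    path.write_text(
        "protein_a\tprotein_b\tcombined_score\n"
        + "\n".join("\t".join(map(str, r)) for r in rows)
        + "\n"
    )


# ---------------------------------------------------------------------------
# load_ppi
# ---------------------------------------------------------------------------

def test_score_cutoff_is_inclusive(tmp_path):
    p = tmp_path / "ppi.tsv"
    _write_ppi(p, [("a", "b", 900), ("b", "c", 350), ("c", "d", 400)])
    g = cn.load_ppi(p, score_cutoff=400)
    assert set(map(frozenset, g.edges())) == {frozenset("ab"), frozenset("cd")}


def test_duplicate_pair_keeps_max_score(tmp_path):
    p = tmp_path / "ppi.tsv"
    _write_ppi(p, [("a", "b", 500), ("b", "a", 700)])
    g = cn.load_ppi(p)
    assert g["a"]["b"]["combined_score"] == 700


def test_self_interactions_dropped_and_counted(tmp_path):
    p = tmp_path / "ppi.tsv"
    _write_ppi(p, [("a", "a", 900), ("a", "b", 800)])
    g = cn.load_ppi(p)
    assert not g.has_edge("a", "a")
    assert g.graph["n_self_loops_dropped"] == 1


def test_malformed_score_reports_line_number(tmp_path):
    p = tmp_path / "ppi.tsv"
    _write_ppi(p, [("a", "b", 500), ("b", "c", "high")])
    with pytest.raises(ValueError, match="line 3"):
        cn.load_ppi(p)


def test_id_mapping_with_unmapped_warning(tmp_path):
    p = tmp_path / "ppi.tsv"
    _write_ppi(p, [("9606.P1", "9606.P2", 800), ("9606.P1", "9606.P3", 700)])
    with pytest.warns(UserWarning, match="no mapping"):
        g = cn.load_ppi(p, id_map={"9606.P1": "TP53", "9606.P2": "MDM2"})
    assert g.has_edge("TP53", "MDM2")
    assert g.has_edge("TP53", "9606.P3")


# ---------------------------------------------------------------------------
# module_ppi_subnetwork
# ---------------------------------------------------------------------------

def test_induced_subnetwork_and_coverage(tmp_path):
    p = tmp_path / "ppi.tsv"
    _write_ppi(p, [("a", "b", 800), ("b", "c", 800), ("c", "d", 800)])
    ppi = cn.load_ppi(p)
    mod = Module(id="M1", members=frozenset(["a", "b", "x"]), seed="a", score=1.0)
    sub, coverage = cn.module_ppi_subnetwork(mod, ppi)
    assert set(sub.nodes()) == {"a", "b"}
    assert sub.has_edge("a", "b") and not sub.has_edge("b", "c")
    assert coverage == pytest.approx(2 / 3)


def test_empty_induced_subnetwork_warns(tmp_path):
    p = tmp_path / "ppi.tsv"
    _write_ppi(p, [("a", "b", 800)])
    ppi = cn.load_ppi(p)
    with pytest.warns(UserWarning, match="no edges"):
        sub, coverage = cn.module_ppi_subnetwork(["x", "y"], ppi)
    assert coverage == 0.0


# ---------------------------------------------------------------------------
# hypergeometric enrichment
# ---------------------------------------------------------------------------

def _brute_force_tail(N, K, n, k):
    """Exact one-sided tail by summing hypergeometric point masses."""
    total = 0.0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
    return total


def _sets(**kw):
    return {t: (d, frozenset(genes)) for t, (d, genes) in kw.items()}


def test_fully_contained_query_worked_example():
    universe = [f"u{i}" for i in range(100)]
    term = universe[:10]
    query = universe[:5]
    res = cn.hypergeometric_enrichment(
        query, _sets(T1=("some term", term)), universe
    )[0]
    expected = math.comb(10, 5) / math.comb(100, 5)
    assert res.p_value == pytest.approx(expected, abs=1e-12)
    assert res.p_value == pytest.approx(3.35e-6, rel=5e-3)
    assert res.selected


def test_matches_brute_force_tail_sums(rng):
    universe = [f"u{i}" for i in range(60)]
    for _ in range(25):
        term = list(rng.choice(universe, size=rng.integers(3, 30), replace=False))
        query = list(rng.choice(universe, size=rng.integers(1, 20), replace=False))
        res = cn.hypergeometric_enrichment(
            query, _sets(T=("t", term)), universe, alpha=0.05
        )[0]
        brute = _brute_force_tail(60, len(term), len(query), res.k_overlap)
        assert res.p_value == pytest.approx(brute, abs=1e-10)


def test_disjoint_query_gets_p_one():
    universe = [f"u{i}" for i in range(50)]
    res = cn.hypergeometric_enrichment(
        universe[:5], _sets(T=("t", universe[40:])), universe
    )[0]
    assert res.k_overlap == 0
    assert res.p_value == pytest.approx(1.0)
    assert not res.selected


def test_keyword_flagging():
    universe = [f"u{i}" for i in range(100)]
    sets = _sets(
        T1=("translation elongation", universe[:10]),
        T2=("lipid storage", universe[:10]),
    )
    res = {r.name: r for r in cn.hypergeometric_enrichment(universe[:5], sets, universe)}
    assert res["translation elongation"].selected
    assert res["translation elongation"].flagged_disease_related
    assert res["lipid storage"].selected
    assert not res["lipid storage"].flagged_disease_related


def test_query_outside_universe_rejected():
    with pytest.raises(ValueError):
        cn.hypergeometric_enrichment(["x"], _sets(T=("t", ["a"])), ["a", "b"])
    assert cn.hypergeometric_enrichment([], _sets(T=("t", ["a"])), ["a"]) == []


def test_gmt_round_trip(tmp_path):
    p = tmp_path / "x.gmt"
    p.write_text("T1\ttranslation\tg1\tg2\tg3\nT2\tenergy pathway\tg4\n")
    sets = cn.read_gmt(p)
    assert sets["T1"] == ("translation", frozenset({"g1", "g2", "g3"}))
    assert sets["T2"][1] == frozenset({"g4"})
    (tmp_path / "bad.gmt").write_text("T1\tonly-description\n")
    with pytest.raises(ValueError, match="line 1"):
        cn.read_gmt(tmp_path / "bad.gmt")


# ---------------------------------------------------------------------------
# call_potential_genes
# ---------------------------------------------------------------------------

def _sub(genes, mid="S1"):
    return Module(id=mid, members=frozenset(genes), seed=sorted(genes)[0], score=1.0)


def test_members_and_adjacent_mediator_called():
    g = nx.Graph([("A", "B"), ("B", "C"), ("A", "C"), ("B", "D"), ("D", "E")])
    calls = {c.gene: c for c in call_potential_genes([_sub("ABC")], g)}
    assert set(calls) == {"A", "B", "C", "D"}
    assert calls["A"].role == "submodule_member"
    assert calls["D"].role == "mediator"
    assert calls["D"].supporting_edges == (("B", "D"),)


def test_mediator_depth_two_reaches_chain_end():
    g = nx.Graph([("A", "B"), ("B", "X"), ("X", "Y")])
    depth1 = {c.gene for c in call_potential_genes([_sub("AB")], g, mediator_depth=1)}
    depth2 = {c.gene: c for c in call_potential_genes([_sub("AB")], g, mediator_depth=2)}
    assert "Y" not in depth1
    assert "Y" in depth2
    path = depth2["Y"].supporting_edges
    assert len(path) == 2
    assert all(g.has_edge(*e) for e in path)


def test_call_set_monotone_in_mediator_depth(rng):
    g = nx.gnp_random_graph(40, 0.08, seed=3)
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
    sub = _sub(sorted(g.nodes())[:5])
    prev: set = set()
    for depth in (1, 2, 3):
        cur = {c.gene for c in call_potential_genes([sub], g, mediator_depth=depth)}
        assert prev <= cur
        prev = cur


def test_member_role_takes_precedence_over_mediator():
    g = nx.Graph([("A", "B"), ("B", "C"), ("C", "D")])
    calls = {c.gene: c for c in call_potential_genes([_sub("AB", "S1"), _sub("CD", "S2")], g)}
    assert calls["C"].role == "submodule_member"  # member of S2, mediator of S1
    assert calls["B"].role == "submodule_member"


def test_no_flagged_submodules_is_valid_empty_outcome():
    assert call_potential_genes([], nx.Graph([("A", "B")])) == []


def test_analyze_disease_module_end_to_end(tmp_path):
    # module of 6 genes; PPI has a 4-clique core + appendages
    core = ["m1", "m2", "m3", "m4"]
    rows = [(a, b, 900) for i, a in enumerate(core) for b in core[i + 1:]]
    rows += [("m4", "m5", 800), ("m5", "m6", 800), ("m1", "out", 900)]
    p = tmp_path / "ppi.tsv"
    _write_ppi(p, rows)
    ppi = cn.load_ppi(p)
    universe = {f"m{i}" for i in range(1, 7)} | {"out"} | {f"bg{i}" for i in range(40)}
    gene_sets = _sets(
        GOOD=("translation elongation", core),
        BAD=("unrelated decoy", [f"bg{i}" for i in range(10)]),
    )
    rep = analyze_disease_module(
        [f"m{i}" for i in range(1, 7)], ppi, gene_sets, universe, module_id="A"
    )
    assert rep["submodules"], "the PPI core should be detected"
    assert rep["flagged_submodules"]
    called = {c.gene for c in rep["calls"]}
    assert set(core) <= called
    assert "out" not in called  # outside the module's PPI subnetwork
    mediators = {c.gene for c in rep["calls"] if c.role == "mediator"}
    assert mediators <= {"m5", "m6"}
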