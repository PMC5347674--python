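"""From a disease-related module to candidate genes: PPI subnetwork,
dense sub-modules, annotation enrichment, members + mediators."""

import ccanet as cn
from ccanet.potential import analyze_disease_module

module_genes = [f"m{i}" for i in range(1, 8)]

# STRING-style PPI: a high-confidence core m1-m4 plus weaker periphery
ppi_rows = [
    ("m1", "m2", 950), ("m1", "m3", 920), ("m1", "m4", 910),
    ("m2", "m3", 900), ("m2", "m4", 880), ("m3", "m4", 930),
    ("m4", "m5", 650), ("m5", "m6", 620), ("m6", "m7", 300),  # below cutoff
]
import tempfile, pathlib
tmp = pathlib.Path(tempfile.mkdtemp())
(tmp / "ppi.tsv").write_text(
    "protein_a\tprotein_b\tcombined_score\n"
    + "\n".join("\t".join(map(str, r)) for r in ppi_rows) + "\n"
)
ppi = cn.load_ppi(tmp / "ppi.tsv", score_cutoff=400)

universe = set(module_genes) | {f"bg{i}" for i in range(60)}
gene_sets = {
    "GO:0006414": ("translation elongation", frozenset(["m1", "m2", "m3", "m4"])),
    "GO:0007010": ("cytoskeleton organization", frozenset(f"bg{i}" for i in range(12))),
}

report = analyze_disease_module(
    module_genes, ppi, gene_sets, universe, mediator_depth=1, module_id="A",
)
print(f"PPI coverage of the module: {report['ppi_coverage']:.2f}")
for m in report["submodules"]:
    flag = "FLAGGED" if m in report["flagged_submodules"] else "not flagged"
    top = report["enrichment"][m.id][0]
    print(f"sub-module {m.id} {sorted(m.members)}: top term "
          f"'{top.name}' p={top.p_value:.2e} -> {flag}")
for c in report["calls"]:
    print(f"candidate {c.gene}: {c.role} (via {c.source_submodule})")
# Members of the enriched sub-module are called directly; m5 is called as a
# mediator because it interacts with a sub-module member (edge m4-m5).
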