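# ccanet

Multi-level RNA-Seq co-expression network inference by canonical
correlation analysis (CCA), with dense-module detection, permutation
screening of case/control correlation shifts, and PPI-guided candidate-gene
calling.

`ccanet` is for researchers who want to move from multi-level RNA-Seq read
counts of a case/control study — exon counts, genomic-position counts and
allele-specific expression (ASE) of heterozygous SNPs — to a ranked set of
disease candidate genes, using co-expression structure rather than
differential expression.

## The method

**Edge scoring.** A gene is not one number per sample: gene *g₁* has *p*
exon (or position) count vectors X⁽¹⁾ = [X₁⁽¹⁾, …, X_p⁽¹⁾]ᵀ and gene *g₂*
has *q* of them. CCA finds the linear combinations U = aᵀX⁽¹⁾,
V = bᵀX⁽²⁾ with maximal correlation, giving canonical correlations
λ₁ ≥ λ₂ ≥ … with per-dimension significance Pᵢ. The pair's co-expression
weight is the −log-P-weighted mean over significant dimensions:

    w = Σᵢ λᵢ·I(log Pᵢ) / Σᵢ I(log Pᵢ),   I(log Pᵢ) = −log Pᵢ if Pᵢ ≤ 0.05, else 0

and w = 0 when no dimension is significant. ASE data are scored the same
way after stacking each gene's two allele blocks (Y = [Y⁽¹⁾, Y⁽²⁾]ᵀ), so
the canonical coefficients weight both alleles jointly. Leading-dimension
significance is decided by a sample-permutation test of a
ridge-regularized λ₁, which stays calibrated when feature counts approach
the sample count (see `docs/methods.md`); higher dimensions use the
Bartlett–Lawley sequential chi-square.

**Network & modules.** The integrated network is the union of all gene
pairs with w > 0 at any level. Degree assortativity (Pearson correlation
of endpoint degrees) characterises its topology. Dense modules are
detected with a faithful re-implementation of the MCODE
vertex-weighting / seeded-expansion / haircut scheme.

**Disease screening.** Each module's shift statistic
D = mean over gene pairs of |r_case − r_control| (gene-level Pearson
correlations of per-sample exon-count sums) is compared with 1000 random
same-size gene sets; modules with permutation p < 0.05 are
disease-related.

**Candidate genes.** Each disease-related module's STRING-style PPI
subnetwork is decomposed into MCODE sub-modules; sub-modules enriched
(one-sided hypergeometric, p < 0.05 against a user GMT) in
disease-process terms (keyword-matched: translation, ribosome, energy,
electron transport, oxidative phosphorylation, homeostasis) are flagged,
and candidates are their members plus *mediators* — genes interacting
with a flagged sub-module within a configurable number of hops.

A seeded synthetic-data generator (`ccanet.simulate`) produces
two-condition multi-level counts with planted co-expression and
differential-correlation modules, so every stage has a ground-truth test
surface.

## Worked example

```python
import ccanet as cn

ds = cn.simulate_dataset(cn.SimulationConfig(
    n_genes=40, module_spec=(cn.ModuleSpec(8, 0.95, 0.0),), seed=7))
ppi, gmt = cn.simulate.synthesize_reference_inputs(ds, seed=7)
# ... write inputs, then:
report = cn.run_pipeline(cn.PipelineConfig(
    ppi_path="ppi.tsv", gmt_path="anno.gmt",
    output_dir="out", n_perm=500, seed=7), dataset=ds)
```

Running `python examples/07_full_pipeline.py` (this exact study) prints:

```
{
  "genes": 40,
  "samples": 30,
  "pairs_scored": 2155,
  "network_nodes": 40,
  "network_edges": 107,
  "modules_found": 1,
  "modules_screened": 1,
  "disease_modules": 1,
  "genes_called": 8
}
planted disease-module genes recovered in calls: 8/8
```

Reading the funnel: 2155 pair-level CCA fits (exon + position + allele)
over 40 genes and the 15 case samples produced 107 edges; MCODE found one
dense module; the permutation screen called it disease-related; and the
PPI stage called 8 candidate genes — exactly the 8 genes of the planted
module whose co-expression (latent r = 0.95 in cases) disappears in
controls. The `examples/` directory holds one short script per capability;
each prints what it computes and what the numbers mean.

The same pipeline is available from the shell:

```bash
ccanet simulate --n-genes 40 --module 8,0.95,0.0 --seed 7
ccanet run --config config.yaml
```

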