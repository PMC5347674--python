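# Methods

This note documents the statistical model behind `ccanet`, the choices made
where the design was genuinely open, and what the synthetic benchmarks do
and do not demonstrate.

## The inference problem

A case/control RNA-Seq study yields, per gene, read counts at three
granularities: per exon, per genomic position, and per allele of
heterozygous SNPs (allele-specific expression, ASE). Co-expression between
two genes is then a relationship between two *sets* of count vectors, not
two scalars, which is exactly the setting of canonical correlation
analysis. The pipeline scores all gene pairs at all three levels on the
disease cohort, assembles the union of significant pairs into an
integrated network, finds dense modules, screens them for case/control
correlation shifts, and maps disease-related modules onto a
protein–protein interaction (PPI) network to call candidate genes.

## Canonical correlation scoring

### Solver

For feature matrices A (p×n) and B (q×n), rows are centred and
standardised (CCA is invariant to per-feature affine scaling), the
covariance blocks are whitened by eigendecomposition, and the canonical
correlations are the singular values of the whitened cross-covariance,
clipped to [0, 1]. The number of dimensions is capped at min(p, q, n−1).
Eigenvalues of a covariance block below 1e−8 of its mean diagonal are
floored at that value: rank-deficient directions (common at n = 15 when a
gene has ≥ 14 features) stay numerically defined while well-conditioned
problems are untouched. The solver agrees with a dense
generalized-eigenvalue solution of the CCA normal equations to better than
1e−6 (measured ~1e−15; see `scripts/acceptance.py`).

For ASE the two allele blocks of each gene are stacked into a single
matrix of 2s rows, so the canonical coefficient vector c = [c⁽¹⁾, c⁽²⁾]
weights both alleles jointly; scoring is otherwise identical to the
exon/position case.

### Dimension significance

The classical Bartlett–Lawley statistic for dimensions i…r,
−(n − 1 − (p+q+1)/2)·ln Π_{k=i}^r (1 − λ_k²) on (p−i+1)(q−i+1) degrees of
freedom, relies on a large-sample chi-square approximation. At this
pipeline's operating point — n = 15 samples with up to 10 features per
gene — that approximation collapses: simulated independent genes exceed
the nominal 5% level at ~34% overall and ~70% when p = q = 10 (the
feature count approaches the sample count and the leading sample canonical
correlation saturates near 1 regardless of signal). Rao's F approximation
is closer but loses essentially all power at the same dimensions because
Wilks' Λ dilutes the leading correlation across junk dimensions.

`ccanet` therefore tests the *leading* dimension by a permutation test:
the statistic is the first canonical correlation of a ridge-regularized
problem (ridge 0.1 added to the unit-diagonal correlation blocks before
whitening), and the null is built by permuting the sample columns of one
gene (199 permutations by default), which preserves each gene's internal
covariance exactly. The regularization shrinks the overfit null sharply
while leaving genuine shared signal detectable; the permutation makes the
test exactly calibrated for any statistic. Measured on simulated
independent pairs at the study size: 4.9–5.7% rejections at nominal 5%,
with 94–99% power for pairs sharing a latent factor at r = 0.95. The
regularized statistic is used only inside this test; reported λ values are
the standard CCA estimates.

Dimensions beyond the first keep the Bartlett–Lawley chi-square, applied
as the textbook sequential *stopping* procedure: dimension i counts as
significant only if dimensions 1…i all test at or below α = 0.05
(inclusive, as the weight definition requires). Edge existence
(weight > 0) therefore depends only on the exactly calibrated
leading-dimension test; the higher dimensions only refine the weight's
value. `dim_test="bartlett"` switches to the pure chi-square ladder for
comparison.

### The weight

w = Σ λᵢ·(−log Pᵢ) / Σ(−log Pᵢ) over the significant run, zero when the
run is empty. The weight is a convex combination of the significant λᵢ
(so 0 ≤ w ≤ λ₁) and is invariant to the logarithm base — the base change
rescales numerator and denominator identically; the implementation uses
the natural log, and underflowed P = 0 is replaced by 1e−300 to keep
−log P finite. Zero-variance feature rows are dropped before CCA; a gene
left with no rows makes the pair degenerate (weight 0, flagged).

Per-pair permutation seeds are derived from (global seed, sorted gene
ids, level) via CRC32, so scoring is deterministic, symmetric in argument
order, and independent of scheduling.

## Network construction and topology

An edge exists iff any level's weight is non-zero; node set = genes with
at least one edge. Each edge stores its per-level weights and a combined
weight defined as the **maximum** across levels: the union rule defines
membership only, and no cross-level combination is prescribed by the
method itself, so the combined weight is reporting-only "strongest
evidence" (module detection is unweighted). Scoring uses the disease
cohort only; the control cohort is reserved for the screening stage.

Degree assortativity is the Pearson correlation of endpoint degrees over
the double-counted edge list. On graphs where every endpoint degree is
equal (cycles, cliques) the coefficient is 0/0; this is surfaced as an
explicit *undefined* outcome, never as 0, to avoid fake neutrality.
Reference graphs for comparison are supplied by the user as edge lists.

## MCODE module detection

Re-implemented from the published three-stage scheme with the published
defaults (degree cutoff 2, node score cutoff 0.2, k-core 2, haircut on,
fluff off, max depth 100), all exposed as configuration since the
upstream tool is typically run with defaults but nothing guarantees it:

1. weight(v) = k × density of the highest-k-core of v's closed
   neighbourhood; vertices under the degree cutoff weigh 0;
2. from the highest-weight unvisited seed, expand over neighbours with
   weight ≥ (1 − cutoff)·seed weight, each vertex joining at most one
   module;
3. drop candidates lacking a 2-core; haircut keeps the 2-core (trimming
   tree-like appendages); fluff optionally adds boundary vertices whose
   closed neighbourhood is dense.

Module score = density × size. All tie-breaks are lexicographic on vertex
id, making detection deterministic. A planted 5- or 6-clique in an
ER(100, 0.05) background is recovered with exact member-set equality in
≥ 95% of trials (measured 100%).

## Permutation screening

Gene-level expression is the per-sample sum of exon counts (position
counts as fallback) — the standard gene-count definition; the method
itself does not prescribe the collapsing rule, so it is configuration by
convention, not an assertion about any particular upstream pipeline. The
shift statistic D averages |r_case − r_control| over module gene pairs;
the absolute difference captures both gained and lost co-expression
(a directional variant would halve the alternative space; the absolute
form is an interpretation, flagged as such). Pairs with a constant vector
in either cohort are skipped and counted.

The null resamples random gene *sets* of the module's size from the
network's gene universe (1000 by default), with the add-one empirical
p-value (1 + #{D_null ≥ D_obs})/(n_perm + 1), so p ∈ [1/(n_perm+1), 1] and
is never zero; verdicts use p < 0.05 with no multiple-testing correction
across modules (a deliberate mirror of the screening convention; a
Benjamini–Hochberg flag would be a straightforward extension). Measured
calibration at the study conditions: 6% type-I error at nominal 5% (the
add-one correction and D-statistic ties make the test very slightly
liberal at n_perm = 200), and 100% power against a 10-gene module with
latent r = 0.9 in cases and 0 in controls at 15 + 15 samples.

## Candidate genes

PPI edges come from a STRING-style table with combined scores 0–1000,
kept at score ≥ 400 (the conventional medium-confidence cutoff; the
method states none); self-loops dropped, duplicate pairs keep the
maximum. Sub-modules of each disease-related module's induced PPI
subgraph are found with the same MCODE machinery. Enrichment is a local
one-sided hypergeometric test against a user GMT (p < 0.05, uncorrected),
replacing any web-service dependency; "disease-associated process" is
operationalized as a configurable keyword list over term names
(translation, ribosome, energy, electron transport, oxidative
phosphorylation, homeostasis) because the biological judgement it stands
for cannot be computed. Candidates are members of flagged sub-modules
plus mediators within `mediator_depth` hops (default 1 = direct
interactors; depth 2 exists because a relevant mediator can plausibly sit
two steps out, and the call set grows monotonically with depth). Every
mediator call carries its certifying path edges.

## Synthetic data generator

Emulates the study conditions: two cohorts of 15 samples; per gene 1–10
exons, 1–10 positions, 0–5 biallelic SNPs (uniform); negative-binomial
counts around a log-normal per-sample gene mean (Poisson-lognormal-style
overdispersion, the stylised standard for bulk RNA-Seq). Parameters, with
defaults chosen once as biologically plausible desk-scale values:

| parameter | default | meaning |
|---|---|---|
| `baseline_mean` | 100 | expected count of a unit-offset feature |
| `dispersion` | 10 | NB size; smaller = more overdispersed |
| `latent_sd` | 0.5 | log-scale SD of the per-sample gene signal (≈ CV 0.5) |
| feature offsets | U(0.5, 1.5) | per-feature expression multiplier |
| allelic ratio | Beta(5, 5) per SNP | fixed per gene; splits SNP signal into two correlated-but-distinct allele rows |

Modules are planted through per-condition latent factors: member genes'
latents are √ρ·f + √(1−ρ)·ε, so any two members correlate ρ in
expectation, with ρ_case ≠ ρ_control planting the differential signal the
screen must find. Observed count-scale correlations sit below ρ because
count noise attenuates the latent correlation; tests therefore compare
against a Monte-Carlo estimate of the generator's own expectation rather
than ρ itself. Background genes are independent. Generation is
bit-deterministic given the seed.

What the generator does **not** model: library-size differences and
normalization, gene length effects, correlated feature offsets (isoform
structure), mapping biases in ASE, batch effects, or read-level noise.
Passing benchmarks therefore demonstrate that the statistical machinery
is calibrated and powerful under the assumed factor-plus-NB model — not
that real studies are free of the confounders above, which enter upstream
of this pipeline.

## Numerical and procedural details

- λ clipped to 1 − 1e−12 before ln(1 − λ²); P = 0 replaced by 1e−300.
- Permutation p-values count ties with a 1e−12 tolerance (a permuted
  index order perturbs means by ~1 ulp).
- Counts are analysed as given (the method prescribes no transform); a
  `log1p` flag enables a variance-stabilising transform as a documented
  deviation.
- Degenerate pairs, empty PPI subnetworks, unscreenable modules and
  undefined assortativity are explicit signalled outcomes, not silent
  zeros.
- All-pairs scoring is O(G²) CCA fits; `max_genes` and `min_features`
  guard desk-scale runs. Benchmarks in `scripts/acceptance.py` use
  40-gene studies (1000 pairs for null calibration, 500 datasets for
  screen calibration), sizes at which every stage's behaviour is already
  resolved to within a few percent.
- The pipeline manifest records versions, seed, parameters and per-stage
  counts; identical configs reproduce byte-identical artifacts.

## Known limitations

- With p or q near n, even the calibrated leading-dimension test has
  modest power for weak signals; the method is designed for strong
  co-expression (the regime where w > 0 edges are meaningful).
- The exon-sum definition of gene-level expression under-uses the
  multi-level information available to the screen (the edges use it; D
  does not).
- Keyword-based disease flagging is a proxy for curation and inherits its
  term-naming conventions.
- MCODE's visited-vertex rule makes module membership order-dependent in
  principle; determinism is recovered by the lexicographic tie-breaks,
  but a different id ordering can assign boundary vertices differently.
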