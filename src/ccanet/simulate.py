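"""Two-condition multi-level RNA-Seq count simulator with planted co-expression.

Counts are generated at three levels per gene — exon, position and
SNP-allele (allele-specific expression, ASE) — for a case and a control
cohort.  Co-expression structure is planted through a per-condition latent
factor model: genes in the same module share a latent factor with a chosen
correlation, which may differ between conditions (the differential
co-expression signal the downstream screen must detect).  Counts follow a
Poisson-lognormal-style negative-binomial law, i.e. overdispersed around a
log-normal per-sample gene mean, which is the standard stylised model for
bulk RNA-Seq read counts.

The dataset carries its own ground truth (module membership and the planted
per-condition latent correlations) so tests never have to re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "ModuleSpec",
    "MultiLevelDataset",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
]

CASE = "case"
CONTROL = "control"
LEVELS = ("exon", "position", "allele")


@dataclass(frozen=True)
class ModuleSpec:
    """A planted module: ``n_genes`` sharing a latent factor with correlation
    ``rho_case`` among case samples and ``rho_control`` among controls."""

    n_genes: int
    rho_case: float
    rho_control: float

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ValueError("a module needs at least 2 genes")
        for rho in (self.rho_case, self.rho_control):
            if not (0.0 <= rho <= 0.99):
                raise ValueError(f"latent correlation {rho} outside [0, 0.99]")


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings.

    ``exons_per_gene`` / ``positions_per_gene`` / ``snps_per_gene`` are
    inclusive integer ranges sampled uniformly per gene.  ``baseline_mean``
    is the expected read count of a unit-offset feature; ``dispersion`` is
    the negative-binomial size parameter (smaller = more overdispersed);
    ``latent_sd`` is the log-scale standard deviation of the per-sample
    latent gene signal (≈ biological coefficient of variation).
    """

    n_genes: int = 60
    n_samples_case: int = 15
    n_samples_control: int = 15
    exons_per_gene: tuple[int, int] = (1, 10)
    positions_per_gene: tuple[int, int] = (1, 10)
    snps_per_gene: tuple[int, int] = (0, 5)
    module_spec: tuple[ModuleSpec, ...] = ()
    baseline_mean: float = 100.0
    dispersion: float = 10.0
    latent_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_samples_case < 3 or self.n_samples_control < 3:
            raise ValueError(
                "need >= 3 samples per condition (CCA and Pearson r are "
                "degenerate below that)"
            )
        for name, (lo, hi) in (
            ("exons_per_gene", self.exons_per_gene),
            ("positions_per_gene", self.positions_per_gene),
        ):
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} range {lo}..{hi} invalid (min 1)")
        lo, hi = self.snps_per_gene
        if lo < 0 or hi < lo:
            raise ValueError(f"snps_per_gene range {lo}..{hi} invalid (min 0)")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.latent_sd <= 0:
            raise ValueError("latent_sd must be positive")
        for m in self.module_spec:
            m.validate()
        if sum(m.n_genes for m in self.module_spec) > self.n_genes:
            raise ValueError("planted modules require more genes than n_genes")


@dataclass
class MultiLevelDataset:
    """Per-gene count matrices at the exon, position and ASE levels.

    Matrices are features x samples with an identical sample ordering across
    all genes and levels.  ASE matrices have an even row count ``2s``: rows
    0..s-1 are allele 1 of SNPs 1..s, rows s..2s-1 are allele 2 of the same
    SNPs (two aligned allele blocks).
    """

    genes: list[str]
    samples: list[tuple[str, str]]  # (sample_id, condition)
    exon: dict[str, np.ndarray]
    position: dict[str, np.ndarray]
    ase: dict[str, np.ndarray]
    truth: dict | None = None

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.samples]

    def condition_mask(self, condition: str) -> np.ndarray:
        return np.array([c == condition for _, c in self.samples])

    def level_matrix(self, gene: str, level: str) -> np.ndarray:
        if level not in LEVELS:
            raise KeyError(f"unknown level {level!r}")
        return {"exon": self.exon, "position": self.position, "allele": self.ase}[
            level
        ][gene]

    def validate(self) -> None:
        n = self.n_samples
        for g in self.genes:
            for level in LEVELS:
                m = self.level_matrix(g, level)
                if m.shape[1] != n:
                    raise ValueError(f"{g}/{level}: sample count mismatch")
                if m.size and (np.any(m < 0) or np.any(m != np.round(m))):
                    raise ValueError(f"{g}/{level}: counts must be non-negative integers")
            if self.ase[g].shape[0] % 2:
                raise ValueError(f"{g}: ASE matrix must have an even row count")


def _latent(rng: np.random.Generator, rho: float, factor: np.ndarray) -> np.ndarray:
    """Standard-normal latent correlated ``rho`` with the module factor."""
    eps = rng.standard_normal(factor.shape)
    return np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * eps


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, size: float
) -> np.ndarray:
    """Negative-binomial draws with the given mean matrix and size parameter."""
    mean = np.maximum(mean, 1e-12)
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(np.int64)


def simulate_dataset(config: SimulationConfig) -> MultiLevelDataset:
    """Generate a :class:`MultiLevelDataset` from ``config``.

    Deterministic given ``config.seed``: identical configs yield
    bit-identical datasets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sd = config.latent_sd

    n_case, n_ctrl = config.n_samples_case, config.n_samples_control
    samples = [(f"case_{i+1}", CASE) for i in range(n_case)] + [
        (f"control_{i+1}", CONTROL) for i in range(n_ctrl)
    ]
    genes = [f"g{i+1:04d}" for i in range(config.n_genes)]

    # module assignment: consecutive blocks from the front, rest background
    membership: dict[str, int] = {}
    cursor = 0
    for mi, mod in enumerate(config.module_spec):
        for g in genes[cursor : cursor + mod.n_genes]:
            membership[g] = mi
        cursor += mod.n_genes

    factors_case = rng.standard_normal((len(config.module_spec), n_case))
    factors_ctrl = rng.standard_normal((len(config.module_spec), n_ctrl))

    exon: dict[str, np.ndarray] = {}
    position: dict[str, np.ndarray] = {}
    ase: dict[str, np.ndarray] = {}
    latents: dict[str, np.ndarray] = {}

    for g in genes:
        if g in membership:
            mi = membership[g]
            mod = config.module_spec[mi]
            z_case = _latent(rng, mod.rho_case, factors_case[mi])
            z_ctrl = _latent(rng, mod.rho_control, factors_ctrl[mi])
        else:
            z_case = rng.standard_normal(n_case)
            z_ctrl = rng.standard_normal(n_ctrl)
        z = np.concatenate([z_case, z_ctrl])
        latents[g] = z
        # log-normal per-sample gene mean, mean-one on the count scale
        gene_scale = np.exp(sd * z - sd * sd / 2.0)

        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        n_pos = int(
            rng.integers(config.positions_per_gene[0], config.positions_per_gene[1] + 1)
        )
        n_snp = int(rng.integers(config.snps_per_gene[0], config.snps_per_gene[1] + 1))

        off_ex = rng.uniform(0.5, 1.5, size=n_ex)
        exon[g] = _nb_counts(
            rng, config.baseline_mean * off_ex[:, None] * gene_scale[None, :],
            config.dispersion,
        )
        off_pos = rng.uniform(0.5, 1.5, size=n_pos)
        position[g] = _nb_counts(
            rng, config.baseline_mean * off_pos[:, None] * gene_scale[None, :],
            config.dispersion,
        )
        if n_snp:
            off_snp = rng.uniform(0.5, 1.5, size=n_snp)
            theta = rng.beta(5.0, 5.0, size=n_snp)  # allelic ratio, fixed per SNP
            mu_snp = config.baseline_mean * off_snp[:, None] * gene_scale[None, :]
            a1 = _nb_counts(rng, theta[:, None] * mu_snp, config.dispersion)
            a2 = _nb_counts(rng, (1.0 - theta[:, None]) * mu_snp, config.dispersion)
            ase[g] = np.vstack([a1, a2])
        else:
            ase[g] = np.zeros((0, n_case + n_ctrl), dtype=np.int64)

    truth = {
        "modules": [
            {
                "genes": [g for g in genes if membership.get(g) == mi],
                "rho_case": mod.rho_case,
                "rho_control": mod.rho_control,
            }
            for mi, mod in enumerate(config.module_spec)
        ],
        "latent_sd": sd,
        "latents": latents,
    }
    ds = MultiLevelDataset(
        genes=genes, samples=samples, exon=exon, position=position, ase=ase,
        truth=truth,
    )
    ds.validate()
    return ds


def expected_gene_correlation(
    rho: float,
    config: SimulationConfig,
    n_mc: int = 10_000,
    seed: int = 12345,
    n_features: int | None = None,
) -> float:
    """Monte-Carlo estimate of the expected Pearson correlation between the
    exon-sum expression of two module genes with latent correlation ``rho``.

    This is the generator's own expectation, estimated by re-simulating the
    latent/count model at large sample size — used as an independent oracle
    for planted-signal recovery.  ``n_features`` fixes the exon count of
    both genes (default: midpoint of the configured range).
    """
    rng = np.random.default_rng(seed)
    sd = config.latent_sd
    if n_features is None:
        n_features = (config.exons_per_gene[0] + config.exons_per_gene[1]) // 2
        n_features = max(n_features, 1)
    f = rng.standard_normal(n_mc)
    sums = []
    for _ in range(2):
        z = np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.standard_normal(n_mc)
        scale = np.exp(sd * z - sd * sd / 2)
        off = rng.uniform(0.5, 1.5, size=n_features)
        counts = _nb_counts(
            rng, config.baseline_mean * off[:, None] * scale[None, :],
            config.dispersion,
        )
        sums.append(counts.sum(axis=0).astype(float))
    return float(np.corrcoef(sums[0], sums[1])[0, 1])


def synthesize_reference_inputs(
    ds: MultiLevelDataset,
    seed: int = 0,
    within_module_edge_prob: float = 0.9,
    background_edge_prob: float = 0.03,
) -> tuple[str, str]:
    """Synthetic STRING-style PPI text and GMT text matched to a simulated
    dataset's planted modules (synthetic stand-ins for real interaction and
    annotation databases, for end-to-end test surfaces and examples).

    Each planted module gets a dense high-confidence PPI core and an
    annotation term named after a disease-associated process
    ("translation ..."), so the candidate-gene stage has a recoverable
    ground truth; background gene pairs get sparse medium-confidence edges
    and decoy terms.
    """
    import itertools

    if ds.truth is None:
        raise ValueError("dataset carries no planted-module truth")
    rng = np.random.default_rng(seed)
    module_genes = [m["genes"] for m in ds.truth["modules"]]
    in_module = {g for genes in module_genes for g in genes}
    background = [g for g in ds.genes if g not in in_module]

    lines = ["protein_a\tprotein_b\tcombined_score"]
    for genes in module_genes:
        for a, b in itertools.combinations(genes, 2):
            if rng.random() < within_module_edge_prob:
                lines.append(f"{a}\t{b}\t{rng.integers(700, 1000)}")
    for a, b in itertools.combinations(ds.genes, 2):
        if a in in_module and b in in_module:
            continue
        if rng.random() < background_edge_prob:
            lines.append(f"{a}\t{b}\t{rng.integers(400, 700)}")
    ppi_text = "\n".join(lines) + "\n"

    gmt_lines = []
    for i, genes in enumerate(module_genes):
        extra = list(background[: min(2, len(background))])
        gmt_lines.append(
            f"MOD{i+1}\ttranslation elongation (planted module {i+1})\t"
            + "\t".join(list(genes) + extra)
        )
    n_decoy = max(1, len(background) // 10)
    decoys = rng.permutation(background) if background else []
    for j in range(n_decoy):
        members = decoys[j::n_decoy]
        if len(members):
            gmt_lines.append(
                f"DECOY{j+1}\tcytoskeleton organization (decoy {j+1})\t"
                + "\t".join(members)
            )
    gmt_text = "\n".join(gmt_lines) + "\n"
    return ppi_text, gmt_text


# ---------------------------------------------------------------------------
# long-format TSV I/O
# ---------------------------------------------------------------------------

def write_dataset(ds: MultiLevelDataset, counts_path, samples_path) -> None:
    """Write the long-format counts TSV and the samples TSV.

    Counts columns: gene_id, level, feature_id, allele_index (1|2 or NA),
    then one column per sample.  Samples columns: sample_id, condition.
    """
    rows = []
    for g in ds.genes:
        for level in LEVELS:
            m = ds.level_matrix(g, level)
            if level == "allele":
                s = m.shape[0] // 2
                for i in range(m.shape[0]):
                    snp = i % s if s else 0
                    allele = 1 if i < s else 2
                    rows.append(
                        [g, level, f"snp{snp+1}", str(allele), *m[i].tolist()]
                    )
            else:
                for i in range(m.shape[0]):
                    rows.append([g, level, f"{level}{i+1}", "NA", *m[i].tolist()])
    cols = ["gene_id", "level", "feature_id", "allele_index", *ds.sample_ids]
    pd.DataFrame(rows, columns=cols).to_csv(counts_path, sep="\t", index=False)
    pd.DataFrame(ds.samples, columns=["sample_id", "condition"]).to_csv(
        samples_path, sep="\t", index=False
    )


def read_dataset(counts_path, samples_path) -> MultiLevelDataset:
    """Parse the long-format TSV dialect written by :func:`write_dataset`."""
    counts = pd.read_csv(counts_path, sep="\t", dtype={"allele_index": str})
    sam = pd.read_csv(samples_path, sep="\t")
    required = {"gene_id", "level", "feature_id", "allele_index"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts TSV missing columns {required - set(counts.columns)}")
    if not {"sample_id", "condition"}.issubset(sam.columns):
        raise ValueError("samples TSV needs sample_id and condition columns")
    bad = set(sam["condition"]) - {CASE, CONTROL}
    if bad:
        raise ValueError(f"unknown conditions {bad}; expected case/control")
    samples = list(sam.itertuples(index=False, name=None))
    sample_ids = [s for s, _ in samples]
    missing = set(sample_ids) - set(counts.columns)
    if missing:
        raise ValueError(f"counts TSV lacks sample columns {sorted(missing)}")

    genes = list(dict.fromkeys(counts["gene_id"]))
    exon: dict[str, np.ndarray] = {}
    position: dict[str, np.ndarray] = {}
    ase: dict[str, np.ndarray] = {}
    for g, sub in counts.groupby("gene_id", sort=False):
        for level, store in (("exon", exon), ("position", position)):
            block = sub[sub["level"] == level]
            store[g] = block[sample_ids].to_numpy(dtype=np.int64)
        block = sub[sub["level"] == "allele"]
        if len(block):
            a1 = block[block["allele_index"] == "1"]
            a2 = block[block["allele_index"] == "2"]
            if len(a1) != len(a2):
                raise ValueError(f"{g}: unpaired allele rows")
            # align allele-2 rows to allele-1 SNP order
            a2 = a2.set_index("feature_id").loc[a1["feature_id"]].reset_index()
            ase[g] = np.vstack(
                [a1[sample_ids].to_numpy(np.int64), a2[sample_ids].to_numpy(np.int64)]
            )
        else:
            ase[g] = np.zeros((0, len(sample_ids)), dtype=np.int64)
    for g in genes:
        exon.setdefault(g, np.zeros((0, len(sample_ids)), dtype=np.int64))
        position.setdefault(g, np.zeros((0, len(sample_ids)), dtype=np.int64))
    ds = MultiLevelDataset(
        genes=genes, samples=samples, exon=exon, position=position, ase=ase
    )
    ds.validate()
    return ds
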