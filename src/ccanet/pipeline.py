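"""End-to-end orchestration: counts -> CCA edges -> network -> modules ->
permutation screen -> PPI sub-modules -> candidate-gene calls.

Every stage is a pure function of (inputs, config, seed); reruns with an
identical config produce byte-identical artifacts.  The manifest records
package versions, the seed, all parameters and per-stage counts.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cca import CCAEdgeScore, FeatureMatrix, score_pair_bivariate_ase, score_pair_univariate
from .mcode import MCODEParams, find_modules, write_modules_json, write_modules_tsv
from .network import build_network, compare_assortativity, read_edge_list, write_edge_list
from .potential import (
    DEFAULT_KEYWORDS,
    analyze_disease_module,
    load_ppi,
    read_gmt,
    write_calls,
)
from .screening import permutation_screen, write_screen_report
from .simulate import MultiLevelDataset, read_dataset

logger = logging.getLogger("ccanet")

__all__ = ["PipelineConfig", "PipelineStageError", "score_all_pairs", "run_pipeline"]

STAGES = (
    "load", "score", "network", "topology", "modules", "screen", "potential",
)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    counts_path: str | None = None
    samples_path: str | None = None
    ppi_path: str | None = None
    gmt_path: str | None = None
    output_dir: str = "ccanet_out"
    reference_networks: dict[str, str] = field(default_factory=dict)
    alpha: float = 0.05
    n_perm: int = 1000          # permutation-screen null size
    cca_n_perm: int = 199       # permutations for the CCA dimension-1 test
    cca_dim_test: str = "permutation"
    mcode: MCODEParams = MCODEParams()
    string_cutoff: int = 400
    mediator_depth: int = 1
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS
    log1p: bool = False         # optional variance-stabilising transform
    min_features: int = 1
    max_genes: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.cca_n_perm < 19:
            raise ValueError("cca_n_perm too small to resolve alpha")
        if self.mediator_depth < 1:
            raise ValueError("mediator_depth must be >= 1")
        if self.string_cutoff < 0 or self.string_cutoff > 1000:
            raise ValueError("string_cutoff must be within 0..1000")
        if self.min_features < 1:
            raise ValueError("min_features must be >= 1")
        self.mcode.validate()

    # -- config file round-trip -------------------------------------------
    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["mcode"] = asdict(self.mcode)
        data["keywords"] = list(self.keywords)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "mcode" in data and isinstance(data["mcode"], dict):
            data["mcode"] = MCODEParams(**data["mcode"])
        if "keywords" in data:
            data["keywords"] = tuple(data["keywords"])
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _feature_matrix(
    ds: MultiLevelDataset, gene: str, level: str, log1p: bool,
    mask: np.ndarray | None = None,
) -> FeatureMatrix:
    values = ds.level_matrix(gene, level).astype(float)
    if mask is not None:
        values = values[:, mask]
    if log1p:
        values = np.log1p(values)
    return FeatureMatrix(gene_id=gene, level=level, values=values)


def score_all_pairs(
    dataset: MultiLevelDataset,
    alpha: float = 0.05,
    dim_test: str = "permutation",
    n_perm: int = 199,
    seed: int = 0,
    log1p: bool = False,
    min_features: int = 1,
    max_genes: int | None = None,
    condition: str | None = "case",
) -> list[CCAEdgeScore]:
    """Score every gene pair at every level with at least ``min_features``
    features in both genes (for the allele level: at least one SNP each).

    Scoring uses the ``condition`` samples only (default the disease
    cohort: the co-expression network describes the disease state, and the
    control cohort is reserved for the later correlation-shift screen);
    pass ``condition=None`` to use all samples.  ``max_genes`` caps the
    gene set (first genes kept) for desk-scale runs; all-pairs scoring is
    O(G^2) CCA fits.
    """
    genes = dataset.genes[:max_genes] if max_genes else dataset.genes
    mask = dataset.condition_mask(condition) if condition else None
    scores: list[CCAEdgeScore] = []
    for level, scorer in (
        ("exon", score_pair_univariate),
        ("position", score_pair_univariate),
        ("allele", score_pair_bivariate_ase),
    ):
        eligible = [
            g
            for g in genes
            if dataset.level_matrix(g, level).shape[0]
            >= (max(min_features, 2) if level == "allele" else min_features)
        ]
        for ga, gb in itertools.combinations(eligible, 2):
            scores.append(
                scorer(
                    _feature_matrix(dataset, ga, level, log1p, mask),
                    _feature_matrix(dataset, gb, level, log1p, mask),
                    alpha=alpha,
                    dim_test=dim_test,
                    n_perm=n_perm,
                    seed=seed,
                )
            )
    return scores


def run_pipeline(
    config: PipelineConfig, dataset: MultiLevelDataset | None = None
) -> dict:
    """Run every stage, writing all intermediate artifacts plus a manifest
    to ``config.output_dir``.  Returns the report dict.

    Any stage failure raises :class:`PipelineStageError` naming the stage;
    artifacts written before the failure are retained.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    report: dict = {"config": config, "counts": counts}

    def _stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except PipelineStageError:
                raise
            except BaseException as exc:
                raise PipelineStageError(name, exc) from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result
        return deco

    @_stage("load")
    def dataset_():
        if dataset is not None:
            return dataset
        if not (config.counts_path and config.samples_path):
            raise ValueError("counts_path and samples_path required")
        return read_dataset(config.counts_path, config.samples_path)

    counts["genes"] = len(dataset_.genes)
    counts["samples"] = dataset_.n_samples

    @_stage("score")
    def scores():
        return score_all_pairs(
            dataset_,
            alpha=config.alpha,
            dim_test=config.cca_dim_test,
            n_perm=config.cca_n_perm,
            seed=config.seed,
            log1p=config.log1p,
            min_features=config.min_features,
            max_genes=config.max_genes,
        )

    counts["pairs_scored"] = len(scores)

    @_stage("network")
    def net():
        g = build_network(scores)
        write_edge_list(g, out / "edges.tsv")
        return g

    counts["network_nodes"] = net.number_of_nodes()
    counts["network_edges"] = net.number_of_edges()
    report["network"] = net

    @_stage("topology")
    def topology():
        refs = {
            name: read_edge_list(path)
            for name, path in config.reference_networks.items()
        }
        table = compare_assortativity(net, refs)
        table.to_csv(out / "assortativity.tsv", sep="\t", index=False)
        return table

    report["assortativity"] = topology

    @_stage("modules")
    def modules():
        mods = find_modules(net, config.mcode, source_graph="integrated")
        write_modules_json(mods, out / "modules.json")
        write_modules_tsv(mods, out / "modules.tsv")
        return mods

    counts["modules_found"] = len(modules)
    report["modules"] = modules

    @_stage("screen")
    def screen():
        results = permutation_screen(
            modules,
            dataset_,
            universe=sorted(net.nodes()),
            n_perm=config.n_perm,
            seed=config.seed,
            alpha=config.alpha,
        )
        write_screen_report(results, out / "screen.tsv")
        return results

    disease = [
        m for m, r in zip(modules, screen) if r.disease_related
    ]
    counts["modules_screened"] = len(screen)
    counts["disease_modules"] = len(disease)
    report["screen"] = screen
    report["disease_modules"] = disease

    @_stage("potential")
    def potential():
        if not disease:
            write_calls([], out / "potential_genes.json", out / "potential_genes.tsv")
            return []
        if not (config.ppi_path and config.gmt_path):
            logger.warning("no PPI/GMT supplied; candidate-gene stage skipped")
            write_calls([], out / "potential_genes.json", out / "potential_genes.tsv")
            return []
        ppi = load_ppi(config.ppi_path, config.string_cutoff)
        gene_sets = read_gmt(config.gmt_path)
        universe = set(dataset_.genes)
        reports = [
            analyze_disease_module(
                sorted(m.members),
                ppi,
                gene_sets,
                universe,
                mcode_params=config.mcode,
                alpha=config.alpha,
                keywords=config.keywords,
                mediator_depth=config.mediator_depth,
                module_id=m.id,
            )
            for m in disease
        ]
        write_calls(reports, out / "potential_genes.json", out / "potential_genes.tsv")
        return reports

    calls = sorted({c.gene for rep in potential for c in rep["calls"]})
    counts["genes_called"] = len(calls)
    report["potential"] = potential
    report["called_genes"] = calls

    manifest = {
        "ccanet_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "networkx": nx.__version__,
        },
        "seed": config.seed,
        "parameters": {
            **{
                k: v
                for k, v in asdict(config).items()
                if k not in ("mcode", "keywords")
            },
            "mcode": asdict(config.mcode),
            "keywords": list(config.keywords),
        },
        "stage_counts": counts,
        "called_genes": calls,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    report["manifest"] = manifest
    return report
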