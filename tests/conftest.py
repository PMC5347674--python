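import numpy as np
import pytest

import ccanet as cn


@pytest.fixture(scope="session")
def planted_dataset() -> cn.MultiLevelDataset:
    """30 genes, one 8-gene module strongly co-expressed in cases only."""
    cfg = cn.SimulationConfig(
        n_genes=30,
        module_spec=(cn.ModuleSpec(8, 0.95, 0.0),),
        seed=11,
    )
    return cn.simulate_dataset(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def brute_force_canonical_correlations(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Independent oracle: canonical correlations from the generalized
    eigenvalue form of the normal equations,
    Sxx^-1 Sxy Syy^-1 Syx a = lambda^2 a, solved densely."""
    n = A.shape[1]
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    Sxx = Ac @ Ac.T / (n - 1)
    Syy = Bc @ Bc.T / (n - 1)
    Sxy = Ac @ Bc.T / (n - 1)
    M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
    evals = np.linalg.eigvals(M)
    evals = np.clip(np.real(evals), 0.0, 1.0)
    return np.sort(np.sqrt(evals))[::-1]


@pytest.fixture(scope="session")
def reference_inputs(planted_dataset, tmp_path_factory):
    """Synthetic PPI + GMT files matched to the planted module."""
    d = tmp_path_factory.mktemp("refs")
    ppi_text, gmt_text = cn.simulate.synthesize_reference_inputs(
        planted_dataset, seed=11
    )
    (d / "ppi.tsv").write_text(ppi_text)
    (d / "anno.gmt").write_text(gmt_text)
    return d / "ppi.tsv", d / "anno.gmt"
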