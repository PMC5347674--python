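"""Canonical-correlation scoring of gene pairs.

A gene pair is scored at one expression level by canonical correlation
analysis (CCA) between the two genes' feature-by-sample count matrices:
exon or position counts (univariate case) or the stacked two-allele ASE
matrices (bivariate case).  The ordered canonical correlations
``lambda_1 >= lambda_2 >= ...`` are collapsed into a single edge weight

    w = sum_i lambda_i * I(log P_i) / sum_i I(log P_i),

where ``I(log P_i) = -log P_i`` when dimension ``i`` is significant
(``P_i <= alpha``, inclusive) and 0 otherwise; ``w = 0`` when no dimension
is significant.  The weight is therefore a -log-P-weighted convex
combination of the significant canonical correlations, invariant to the
logarithm base.

Dimension significance is sequential (a stopping rule): dimension ``i``
counts as significant only when dimensions ``1..i`` all test at or below
``alpha``.  The leading dimension is tested by a sample-permutation null of
a ridge-regularized first canonical correlation, which stays calibrated
when the feature counts approach the sample count (n = 15 with up to ten
exons per gene); higher dimensions use the Bartlett–Lawley sequential
chi-square statistic

    -(n - 1 - (p + q + 1)/2) * ln prod_{k=i}^{r} (1 - lambda_k^2)

on ``(p - i + 1)(q - i + 1)`` degrees of freedom.  ``dim_test="bartlett"``
applies the chi-square to every dimension instead.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "FeatureMatrix",
    "CCAEdgeScore",
    "DegeneratePairError",
    "canonical_correlations",
    "bartlett_lawley_pvalues",
    "significance_weighted_score",
    "significant_dimensions",
    "score_pair_univariate",
    "score_pair_bivariate_ase",
]

#: smallest substitute for an underflowed P-value so -log P stays finite
MIN_PVALUE = 1e-300

#: ridge (correlation scale) used only inside the permutation test statistic
PERM_RIDGE = 0.1


class DegeneratePairError(ValueError):
    """Raised when a gene pair cannot be scored (no non-constant features)."""


@dataclass(frozen=True)
class FeatureMatrix:
    """One gene's feature-by-sample matrix at one level.

    ``values`` has one row per feature (exon, position, or allele row) and
    one column per sample; sample ordering must match across the pair.
    """

    gene_id: str
    level: str
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("FeatureMatrix values must be 2-D (features x samples)")
        if np.isnan(v).any():
            raise ValueError("FeatureMatrix values contain missing entries")
        object.__setattr__(self, "values", v)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def nonconstant(self) -> np.ndarray:
        """Rows with non-zero sample variance (constant rows carry no
        correlation information and are dropped before CCA)."""
        return self.values[self.values.std(axis=1) > 0]


@dataclass(frozen=True)
class CCAEdgeScore:
    """CCA result for one gene pair at one level."""

    gene_a: str
    gene_b: str
    level: str
    lambdas: tuple[float, ...]
    pvalues: tuple[float, ...]
    weight: float
    n_significant: int
    degenerate: bool = False
    note: str = ""

    def __post_init__(self):
        if len(self.lambdas) != len(self.pvalues):
            raise ValueError("lambdas and pvalues must align")
        if any(l2 > l1 + 1e-12 for l1, l2 in zip(self.lambdas, self.lambdas[1:])):
            raise ValueError("lambdas must be sorted non-increasing")
        if (self.weight == 0) != (self.n_significant == 0):
            raise ValueError("weight must be 0 exactly when no dimension is significant")


# ---------------------------------------------------------------------------
# core computation
# ---------------------------------------------------------------------------

def _center_whiten(X: np.ndarray, ridge_rel: float) -> np.ndarray:
    """Center rows and whiten by the covariance: rows become an orthonormal
    basis under the empirical inner product.

    Near-singular covariance directions are stabilised by flooring the
    eigenvalues at ``ridge_rel`` times the mean diagonal, which keeps the
    estimator defined under rank deficiency without perturbing
    well-conditioned problems at all.
    """
    n = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    # row standardisation: CCA is invariant to per-feature scale, and it
    # makes the eigenvalue floor act on the correlation (unit-diagonal) scale
    sd = Xc.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    Xc = Xc / sd[:, None]
    S = Xc @ Xc.T / (n - 1)
    evals, evecs = np.linalg.eigh(S)
    evals = np.maximum(evals, max(ridge_rel, 1e-300))
    inv_sqrt = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T
    return inv_sqrt @ Xc


def _lambdas(A: np.ndarray, B: np.ndarray, ridge_rel: float = 1e-8) -> np.ndarray:
    """Canonical correlations of two feature-by-sample matrices by the
    whitening-plus-SVD scheme, clipped to [0, 1], sorted non-increasing."""
    n = A.shape[1]
    At = _center_whiten(A, ridge_rel)
    Bt = _center_whiten(B, ridge_rel)
    s = np.linalg.svd(At @ Bt.T / (n - 1), compute_uv=False)
    return np.clip(s, 0.0, 1.0)


def _standardize(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = Xc.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    return Xc / sd[:, None]


def _regularized_whiten(X: np.ndarray, ridge: float) -> np.ndarray:
    """Whitening on the correlation scale with an absolute ridge — the
    shrunken statistic used by the permutation test."""
    n = X.shape[1]
    Xs = _standardize(X)
    S = Xs @ Xs.T / (n - 1) + ridge * np.eye(X.shape[0])
    evals, evecs = np.linalg.eigh(S)
    inv_sqrt = evecs @ np.diag(1.0 / np.sqrt(np.maximum(evals, 1e-300))) @ evecs.T
    return inv_sqrt @ Xs


def _perm_pvalue_first_dim(
    A: np.ndarray, B: np.ndarray, n_perm: int, rng: np.random.Generator,
    ridge: float = PERM_RIDGE,
) -> float:
    """Permutation P-value for the existence of any canonical association.

    The statistic is the first canonical correlation of the ridge-
    regularized problem; the null resamples by permuting the sample columns
    of one gene, which preserves each gene's internal covariance exactly.
    """
    n = A.shape[1]
    At = _regularized_whiten(A, ridge)
    Bt = _regularized_whiten(B, ridge)
    obs = np.linalg.svd(At @ Bt.T / (n - 1), compute_uv=False)[0]
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    Bp = np.transpose(Bt[:, perms], (1, 2, 0))  # n_perm x n x q
    cross = np.einsum("pn,mnq->mpq", At, Bp) / (n - 1)
    null = np.linalg.svd(cross, compute_uv=False)[:, 0]
    return float((1 + np.sum(null >= obs - 1e-12)) / (n_perm + 1))


def bartlett_lawley_pvalues(
    lambdas: np.ndarray, n: int, p: int, q: int
) -> np.ndarray:
    """Sequential chi-square P-values for the canonical dimensions.

    For dimension ``i`` (1-based) the statistic is
    ``-(n - 1 - (p + q + 1)/2) * ln prod_{k=i}^{r} (1 - lambda_k^2)`` with
    ``(p - i + 1)(q - i + 1)`` degrees of freedom.
    """
    lam = np.clip(np.asarray(lambdas, dtype=float), 0.0, 1.0 - 1e-12)
    r = len(lam)
    mult = n - 1 - (p + q + 1) / 2.0
    out = np.empty(r)
    for i in range(r):
        stat = -mult * float(np.sum(np.log1p(-lam[i:] ** 2)))
        df = (p - i) * (q - i)
        out[i] = stats.chi2.sf(max(stat, 0.0), df) if df > 0 else 1.0
    return out


def canonical_correlations(
    A: np.ndarray | FeatureMatrix,
    B: np.ndarray | FeatureMatrix,
    *,
    ridge_rel: float = 1e-8,
    dim_test: str = "permutation",
    n_perm: int = 199,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Canonical correlations of two genes' matrices with per-dimension
    P-values.

    Constant (zero-variance) feature rows are dropped first; a gene left
    with no rows makes the pair degenerate (:class:`DegeneratePairError`).
    Returns ``min(p, q, n - 1)`` correlations sorted non-increasing.
    """
    Am = A.values if isinstance(A, FeatureMatrix) else np.asarray(A, float)
    Bm = B.values if isinstance(B, FeatureMatrix) else np.asarray(B, float)
    if Am.ndim != 2 or Bm.ndim != 2:
        raise ValueError("feature matrices must be 2-D")
    if Am.shape[1] != Bm.shape[1]:
        raise ValueError(
            f"sample count mismatch: {Am.shape[1]} vs {Bm.shape[1]}"
        )
    n = Am.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    Am = Am[Am.std(axis=1) > 0]
    Bm = Bm[Bm.std(axis=1) > 0]
    if Am.shape[0] == 0 or Bm.shape[0] == 0:
        raise DegeneratePairError("all feature rows constant in one gene")
    p, q = sorted((Am.shape[0], Bm.shape[0]))
    r = min(p, q, n - 1)
    lam = _lambdas(Am, Bm, ridge_rel)[:r]

    pvals = bartlett_lawley_pvalues(lam, n, p, q)
    if dim_test == "permutation":
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        pvals = pvals.copy()
        pvals[0] = _perm_pvalue_first_dim(Am, Bm, n_perm, rng)
    elif dim_test != "bartlett":
        raise ValueError(f"unknown dim_test {dim_test!r}")
    return lam, pvals


# ---------------------------------------------------------------------------
# significance weighting
# ---------------------------------------------------------------------------

def significant_dimensions(
    pvalues: np.ndarray, alpha: float = 0.05, sequential: bool = True
) -> np.ndarray:
    """Boolean mask of significant canonical dimensions.

    Sequential (default): the leading run of dimensions with
    ``P_i <= alpha``; testing stops at the first non-significant dimension.
    """
    pv = np.asarray(pvalues, dtype=float)
    mask = pv <= alpha
    if sequential and not mask.all():
        first_fail = int(np.argmin(mask))
        mask[first_fail:] = False
    return mask


def significance_weighted_score(
    lambdas, pvalues, alpha: float = 0.05, sequential: bool = True
) -> float:
    """Collapse canonical correlations into the -log-P-weighted edge weight.

    ``w = sum lambda_i * (-ln P_i) / sum (-ln P_i)`` over significant
    dimensions; 0 when none are significant.  Invariant to the log base.
    Underflowed ``P = 0`` is replaced by ``1e-300``.
    """
    lam = np.asarray(lambdas, dtype=float)
    pv = np.asarray(pvalues, dtype=float)
    if lam.shape != pv.shape:
        raise ValueError("lambdas and pvalues must align")
    if lam.size == 0:
        return 0.0
    mask = significant_dimensions(pv, alpha, sequential)
    if not mask.any():
        return 0.0
    logs = -np.log(np.maximum(pv[mask], MIN_PVALUE))
    w = float(np.sum(lam[mask] * logs) / np.sum(logs))
    # guard float round-off: w is a convex combination of the selected lambdas
    return float(np.clip(w, lam[mask].min(), lam[mask].max()))


# ---------------------------------------------------------------------------
# pair scoring
# ---------------------------------------------------------------------------

def _pair_rng(seed: int, gene_a: str, gene_b: str, level: str) -> np.random.Generator:
    """Deterministic per-pair RNG, symmetric in the gene order."""
    key = "|".join(sorted((gene_a, gene_b))) + "|" + level
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(key.encode())])


def _degenerate(a: FeatureMatrix, b: FeatureMatrix, note: str) -> CCAEdgeScore:
    return CCAEdgeScore(
        gene_a=a.gene_id, gene_b=b.gene_id, level=a.level,
        lambdas=(), pvalues=(), weight=0.0, n_significant=0,
        degenerate=True, note=note,
    )


def _score(
    a: FeatureMatrix, b: FeatureMatrix, alpha: float, dim_test: str,
    n_perm: int, seed: int,
) -> CCAEdgeScore:
    # place the gene with fewer features first so p <= q (canonical order;
    # ties broken by id so score(a, b) == score(b, a) exactly)
    if (a.n_features, a.gene_id) > (b.n_features, b.gene_id):
        a, b = b, a
    rng = _pair_rng(seed, a.gene_id, b.gene_id, a.level)
    try:
        lam, pv = canonical_correlations(
            a.values, b.values, dim_test=dim_test, n_perm=n_perm, seed=rng
        )
    except DegeneratePairError as exc:
        return _degenerate(a, b, str(exc))
    mask = significant_dimensions(pv, alpha)
    w = significance_weighted_score(lam, pv, alpha)
    return CCAEdgeScore(
        gene_a=a.gene_id, gene_b=b.gene_id, level=a.level,
        lambdas=tuple(float(x) for x in lam),
        pvalues=tuple(float(x) for x in pv),
        weight=w, n_significant=int(mask.sum()),
    )


def score_pair_univariate(
    a: FeatureMatrix,
    b: FeatureMatrix,
    alpha: float = 0.05,
    dim_test: str = "permutation",
    n_perm: int = 199,
    seed: int = 0,
) -> CCAEdgeScore:
    """Score one gene pair at the exon or position level."""
    if a.level != b.level:
        raise ValueError(f"level mismatch: {a.level} vs {b.level}")
    if a.level not in ("exon", "position"):
        raise ValueError("univariate scoring applies to exon or position matrices")
    if a.gene_id == b.gene_id:
        raise ValueError("cannot score a gene against itself")
    return _score(a, b, alpha, dim_test, n_perm, seed)


def score_pair_bivariate_ase(
    a: FeatureMatrix,
    b: FeatureMatrix,
    alpha: float = 0.05,
    dim_test: str = "permutation",
    n_perm: int = 199,
    seed: int = 0,
) -> CCAEdgeScore:
    """Score one gene pair on the stacked two-allele ASE matrices.

    Each matrix holds both allele blocks (2s rows for s SNPs); the CCA runs
    on the stacked matrices so the canonical coefficient vectors combine
    both alleles, and the correlations are aggregated with the same
    significance weighting as the univariate case.
    """
    if a.level != b.level or a.level != "allele":
        raise ValueError("bivariate ASE scoring requires allele-level matrices")
    if a.gene_id == b.gene_id:
        raise ValueError("cannot score a gene against itself")
    for m in (a, b):
        if m.n_features == 0 or m.n_features % 2:
            raise ValueError(
                f"{m.gene_id}: ASE matrix must have a positive even row count"
            )
    return _score(a, b, alpha, dim_test, n_perm, seed)
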