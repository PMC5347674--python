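"""CCA scoring: solver correctness, the significance-weighted edge weight,
and its invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import ccanet as cn
from ccanet.cca import (
    MIN_PVALUE,
    DegeneratePairError,
    bartlett_lawley_pvalues,
    significant_dimensions,
)
from conftest import brute_force_canonical_correlations


def _fm(gene, level, values):
    return cn.FeatureMatrix(gene_id=gene, level=level, values=np.asarray(values, float))


# ---------------------------------------------------------------------------
# canonical_correlations
# ---------------------------------------------------------------------------

def test_scalar_pair_equals_absolute_pearson(rng):
    for _ in range(20):
        x = rng.normal(size=(1, 25))
        y = rng.normal(size=(1, 25))
        lam, _ = cn.canonical_correlations(x, y, dim_test="bartlett")
        assert len(lam) == 1
        assert abs(lam[0] - abs(np.corrcoef(x[0], y[0])[0, 1])) < 1e-10


def test_self_pair_gives_unit_correlations(rng):
    A = rng.normal(size=(4, 30))
    lam, _ = cn.canonical_correlations(A, A.copy(), dim_test="bartlett")
    assert np.allclose(lam, 1.0, atol=1e-8)


def test_matches_generalized_eigenvalue_oracle(rng):
    for _ in range(25):
        p, q = rng.integers(1, 4, size=2)
        n = int(rng.integers(10, 51))
        A = rng.normal(size=(p, n))
        B = rng.normal(size=(q, n))
        lam, _ = cn.canonical_correlations(A, B, dim_test="bartlett")
        oracle = brute_force_canonical_correlations(A, B)[: len(lam)]
        assert np.allclose(lam, oracle, atol=1e-6)


def test_sample_permutation_equivariance(rng):
    A = rng.normal(size=(3, 20))
    B = rng.normal(size=(2, 20))
    perm = rng.permutation(20)
    lam1, _ = cn.canonical_correlations(A, B, dim_test="bartlett")
    lam2, _ = cn.canonical_correlations(A[:, perm], B[:, perm], dim_test="bartlett")
    assert np.allclose(lam1, lam2, atol=1e-10)


def test_feature_scale_invariance(rng):
    A = rng.normal(size=(3, 20))
    B = rng.normal(size=(4, 20))
    A2 = A * np.array([3.0, 0.01, 250.0])[:, None]
    lam1, _ = cn.canonical_correlations(A, B, dim_test="bartlett")
    lam2, _ = cn.canonical_correlations(A2, B, dim_test="bartlett")
    assert np.allclose(lam1, lam2, atol=1e-8)


def test_rank_cap_and_sorting(rng):
    A = rng.normal(size=(8, 10))  # p > n - 1
    B = rng.normal(size=(12, 10))
    lam, pv = cn.canonical_correlations(A, B, dim_test="bartlett")
    assert len(lam) == len(pv) == 8 == min(8, 12, 9)
    assert np.all(np.diff(lam) <= 1e-12)
    assert np.all((lam >= 0) & (lam <= 1))


def test_degenerate_and_mismatched_inputs(rng):
    with pytest.raises(DegeneratePairError):
        cn.canonical_correlations(np.zeros((3, 10)), rng.normal(size=(2, 10)))
    with pytest.raises(ValueError):
        cn.canonical_correlations(rng.normal(size=(2, 10)), rng.normal(size=(2, 11)))


def test_bartlett_statistic_hand_check():
    """P-values reproduce the sequential chi-square formula directly."""
    lam = np.array([0.8, 0.5, 0.2])
    n, p, q = 20, 3, 4
    pv = bartlett_lawley_pvalues(lam, n, p, q)
    mult = n - 1 - (p + q + 1) / 2
    for i in range(3):
        stat = -mult * np.sum(np.log(1 - lam[i:] ** 2))
        df = (p - i) * (q - i)
        assert pv[i] == pytest.approx(stats.chi2.sf(stat, df), rel=1e-12)


def test_first_dimension_null_calibration_gaussian(rng):
    """Independent Gaussian blocks: the first-dimension permutation test
    rejects at close to its nominal 5% level."""
    hits = 0
    n_rep = 400
    for _ in range(n_rep):
        A = rng.normal(size=(3, 50))
        B = rng.normal(size=(4, 50))
        _, pv = cn.canonical_correlations(A, B, n_perm=99, seed=rng)
        hits += pv[0] <= 0.05
    assert 0.02 <= hits / n_rep <= 0.09


# ---------------------------------------------------------------------------
# significance_weighted_score
# ---------------------------------------------------------------------------

def test_weight_single_significant_dimension():
    assert cn.significance_weighted_score([0.9, 0.5], [0.01, 0.2]) == pytest.approx(0.9)


def test_weight_two_significant_dimensions_and_log_base_invariance():
    lam, pv = [0.8, 0.6], [0.01, 0.05]
    w = cn.significance_weighted_score(lam, pv)
    expected = (0.8 * -np.log(0.01) + 0.6 * -np.log(0.05)) / (
        -np.log(0.01) - np.log(0.05)
    )
    assert w == pytest.approx(expected, abs=1e-12)
    assert w == pytest.approx(0.7212, abs=5e-4)
    w10 = (0.8 * -np.log10(0.01) + 0.6 * -np.log10(0.05)) / (
        -np.log10(0.01) - np.log10(0.05)
    )
    assert abs(w - w10) < 1e-12


def test_weight_zero_when_nothing_significant():
    assert cn.significance_weighted_score([0.99, 0.95], [0.7, 0.9]) == 0.0
    assert cn.significance_weighted_score([], []) == 0.0


def test_weight_threshold_is_inclusive():
    assert cn.significance_weighted_score([0.5], [0.05]) == pytest.approx(0.5)
    assert cn.significance_weighted_score([0.5], [0.050001]) == 0.0


def test_weight_survives_pvalue_underflow():
    w = cn.significance_weighted_score([0.9, 0.4], [0.0, 0.01])
    assert 0.4 <= w <= 0.9 and np.isfinite(w)
    # an underflowed P dominates the -log weighting
    assert w > 0.85


def test_sequential_stopping_masks_later_dimensions():
    mask = significant_dimensions(np.array([0.2, 0.01, 0.03]))
    assert not mask.any()
    mask = significant_dimensions(np.array([0.01, 0.2, 0.03]))
    assert mask.tolist() == [True, False, False]
    assert cn.significance_weighted_score([0.9, 0.8], [0.2, 0.01]) == 0.0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    lams=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6),
    pvs=st.lists(st.floats(0.0, 1.0), min_size=6, max_size=6),
)
def test_weight_is_convex_combination_of_significant_lambdas(lams, pvs):
    lam = np.sort(np.array(lams))[::-1]
    pv = np.array(pvs[: len(lam)])
    w = cn.significance_weighted_score(lam, pv)
    mask = significant_dimensions(pv)
    if not mask.any():
        assert w == 0.0
    else:
        assert lam[mask].min() - 1e-12 <= w <= lam[0] + 1e-12


# ---------------------------------------------------------------------------
# pair scoring
# ---------------------------------------------------------------------------

def test_score_pair_univariate_recovers_planted_pairs(planted_dataset):
    import itertools

    ds = planted_dataset
    mask = ds.condition_mask("case")
    mod = ds.truth["modules"][0]["genes"]
    background = ds.genes[-8:]

    def hit_rate(genes):
        hits, total = 0, 0
        for ga, gb in itertools.combinations(genes, 2):
            s = cn.score_pair_univariate(
                _fm(ga, "exon", ds.exon[ga][:, mask]),
                _fm(gb, "exon", ds.exon[gb][:, mask]),
                seed=0,
            )
            assert 0.0 <= s.weight <= (s.lambdas[0] if s.lambdas else 1.0)
            hits += s.weight > 0
            total += 1
        return hits / total

    assert hit_rate(mod) >= 0.6
    assert hit_rate(background) <= 0.25
    assert hit_rate(mod) > hit_rate(background)


def test_score_pair_symmetry(planted_dataset):
    ds = planted_dataset
    mask = ds.condition_mask("case")
    a = _fm("g0001", "exon", ds.exon["g0001"][:, mask])
    b = _fm("g0012", "exon", ds.exon["g0012"][:, mask])
    s1 = cn.score_pair_univariate(a, b, seed=3)
    s2 = cn.score_pair_univariate(b, a, seed=3)
    assert s1 == s2


def test_score_pair_degenerate_all_zero_counts():
    a = _fm("gx", "exon", np.zeros((3, 12)))
    b = _fm("gy", "exon", np.arange(24).reshape(2, 12))
    s = cn.score_pair_univariate(a, b)
    assert s.degenerate and s.weight == 0.0 and s.n_significant == 0


def test_score_pair_rejects_level_mismatch_and_self(rng):
    a = _fm("gx", "exon", rng.normal(size=(2, 10)))
    b = _fm("gy", "position", rng.normal(size=(2, 10)))
    with pytest.raises(ValueError):
        cn.score_pair_univariate(a, b)
    with pytest.raises(ValueError):
        cn.score_pair_univariate(a, _fm("gx", "exon", rng.normal(size=(2, 10))))


def test_bivariate_matches_univariate_on_duplicated_scalar(rng):
    """One SNP whose two allele rows both equal the gene total: the stacked
    bivariate problem reduces to the univariate one on the same 2xn matrix."""
    x = rng.poisson(50.0, size=12).astype(float)
    y = rng.poisson(50.0, size=12).astype(float)
    ax = np.vstack([x, x])
    ay = np.vstack([y, y])
    sb = cn.score_pair_bivariate_ase(
        _fm("ga", "allele", ax), _fm("gb", "allele", ay), dim_test="bartlett"
    )
    su = cn.score_pair_univariate(
        _fm("ga", "exon", ax), _fm("gb", "exon", ay), dim_test="bartlett"
    )
    assert sb.lambdas == pytest.approx(su.lambdas, abs=1e-10)
    assert sb.weight == pytest.approx(su.weight, abs=1e-10)


def test_bivariate_perfect_dependence(rng):
    base = rng.poisson(100.0, size=15).astype(float)
    noise = rng.normal(scale=0.5, size=(2, 15))
    a = np.vstack([base + noise[0], base + noise[1]])
    s = cn.score_pair_bivariate_ase(
        _fm("ga", "allele", a), _fm("gb", "allele", a.copy()), seed=0
    )
    assert s.lambdas[0] > 1 - 1e-6
    assert s.weight > 0


def test_bivariate_rejects_odd_row_count(rng):
    a = _fm("ga", "allele", rng.normal(size=(3, 10)))
    b = _fm("gb", "allele", rng.normal(size=(2, 10)))
    with pytest.raises(ValueError):
        cn.score_pair_bivariate_ase(a, b)
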