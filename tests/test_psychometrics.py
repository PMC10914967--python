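"""Instrument statistics against closed forms and independent oracles.

The oracles deliberately take different numerical routes: pingouin's
covariance-based alpha on z-scored columns, regression-residual partial
correlations for KMO, and an eigenvalue log-determinant for Bartlett.
"""

from __future__ import annotations

import math

import numpy as np
import pingouin as pg
import pandas as pd
import pytest
from scipy import stats

from kanokit import (
    bartlett_from_correlation,
    bartlett_sphericity,
    cronbach_alpha_standardized,
    kendall_sample_size,
    kmo,
    kmo_from_correlation,
    response_rate,
)
from kanokit.psychometrics import SingularCorrelationError


# ---------------------------------------------------------------- oracles


def alpha_oracle(m: np.ndarray) -> float:
    """Covariance-form Cronbach's alpha on z-scored columns (pingouin)."""
    z = (m - m.mean(axis=0)) / m.std(axis=0, ddof=1)
    value, _ = pg.cronbach_alpha(data=pd.DataFrame(z))
    return float(value)


def partial_corr_oracle(m: np.ndarray, i: int, j: int) -> float:
    """Partial correlation of columns i, j given all others, via residuals."""
    others = [c for c in range(m.shape[1]) if c not in (i, j)]
    x = np.column_stack([np.ones(m.shape[0]), m[:, others]])
    ri = m[:, i] - x @ np.linalg.lstsq(x, m[:, i], rcond=None)[0]
    rj = m[:, j] - x @ np.linalg.lstsq(x, m[:, j], rcond=None)[0]
    return float(np.corrcoef(ri, rj)[0, 1])


def kmo_oracle(m: np.ndarray) -> float:
    r = np.corrcoef(m, rowvar=False)
    k = r.shape[0]
    r2 = sum(r[i, j] ** 2 for i in range(k) for j in range(k) if i != j)
    p2 = sum(
        partial_corr_oracle(m, i, j) ** 2
        for i in range(k)
        for j in range(k)
        if i != j
    )
    return r2 / (r2 + p2)


def bartlett_oracle(m: np.ndarray) -> tuple[float, int, float]:
    n, k = m.shape
    r = np.corrcoef(m, rowvar=False)
    logdet = float(np.sum(np.log(np.linalg.eigvalsh(r))))
    chi2 = -(n - 1 - (2 * k + 5) / 6) * logdet
    df = k * (k - 1) // 2
    return chi2, df, float(stats.chi2.sf(chi2, df))


def random_likert_matrix(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Correlated integer Likert codes via a thresholded Gaussian factor model."""
    loadings = rng.uniform(0.3, 0.8, size=k)
    factor = rng.standard_normal((n, 1))
    latent = factor * loadings + rng.standard_normal((n, k))
    cuts = np.quantile(latent, [0.15, 0.4, 0.6, 0.85], axis=0)
    return 1.0 + np.sum(latent[None, :, :] > cuts[:, None, :], axis=0)


# ------------------------------------------------------------------ alpha


def test_alpha_identical_columns_is_one():
    col = np.array([1.0, 2, 3, 4, 5])
    m = np.column_stack([col, col + 1, col * 2])  # r = 1 pairwise
    assert cronbach_alpha_standardized(m) == pytest.approx(1.0)


def test_alpha_two_items_closed_form():
    # columns constructed with Pearson r exactly 0.5
    m = np.array([[0.0, 0.0], [1, 1], [1, 2], [2, 1]])
    r = np.corrcoef(m, rowvar=False)[0, 1]
    assert r == pytest.approx(0.5)
    assert cronbach_alpha_standardized(m) == pytest.approx(2 * 0.5 / 1.5)


def test_alpha_independent_columns_near_zero():
    rng = np.random.default_rng(20240101)
    m = rng.standard_normal((10000, 2))
    assert abs(cronbach_alpha_standardized(m)) < 0.1


def test_alpha_invariant_to_joint_linear_rescaling():
    rng = np.random.default_rng(7)
    m = random_likert_matrix(rng, 200, 5)
    a = cronbach_alpha_standardized(m)
    assert cronbach_alpha_standardized(3.5 * m + 12.0) == pytest.approx(a)


def test_alpha_excludes_zero_variance_items():
    rng = np.random.default_rng(3)
    m = random_likert_matrix(rng, 100, 3)
    with_const = np.column_stack([m, np.full(100, 2.0)])
    with pytest.warns(UserWarning, match="zero-variance"):
        a = cronbach_alpha_standardized(with_const)
    assert a == pytest.approx(cronbach_alpha_standardized(m))
    with pytest.raises(ValueError):
        cronbach_alpha_standardized(np.ones((10, 1)))


# -------------------------------------------------------------------- KMO


def test_kmo_equicorrelated_closed_form():
    # 3 items, r = 0.5: partial correlations are r/(1+r) = 1/3,
    # KMO = 6*0.25 / (6*0.25 + 6/9) = 9/13
    r = np.full((3, 3), 0.5)
    np.fill_diagonal(r, 1.0)
    assert kmo_from_correlation(r) == pytest.approx(9 / 13, abs=1e-12)


def test_kmo_block_diagonal_matches_single_block():
    block = np.array([[1.0, 0.8], [0.8, 1.0]])
    full = np.block([[block, np.zeros((2, 2))], [np.zeros((2, 2)), block]])
    assert kmo_from_correlation(full) == pytest.approx(
        kmo_from_correlation(block), abs=1e-12
    )


def test_kmo_singular_matrix_raises():
    col = np.random.default_rng(1).standard_normal(50)
    m = np.column_stack([col, 2 * col, np.random.default_rng(2).standard_normal(50)])
    with pytest.raises(SingularCorrelationError):
        kmo(m)


def test_kmo_uncorrelated_extra_item_does_not_raise_overall_kmo():
    rng = np.random.default_rng(11)
    m = random_likert_matrix(rng, 500, 4)
    extra = rng.integers(1, 6, size=(500, 1)).astype(float)
    assert kmo(np.column_stack([m, extra])) <= kmo(m) + 1e-6


# ---------------------------------------------------------------- Bartlett


def test_bartlett_identity_correlation_is_null():
    r = np.eye(4)
    res = bartlett_from_correlation(r, n=100)
    assert res.chi2 == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)
    assert res.df == 6


def test_bartlett_df_depends_only_on_k():
    rng = np.random.default_rng(5)
    m = random_likert_matrix(rng, 60, 14)
    assert bartlett_sphericity(m).df == 91


def test_bartlett_equicorrelated_closed_form():
    # det of 3x3 equicorrelation r=0.5 is (1-r)^2 (1+2r) = 0.5
    r = np.full((3, 3), 0.5)
    np.fill_diagonal(r, 1.0)
    res = bartlett_from_correlation(r, n=50)
    assert res.chi2 == pytest.approx(-(49 - 11 / 6) * math.log(0.5))
    assert res.df == 3
    assert res.p_display() == "<0.0001"


def test_bartlett_needs_more_rows_than_items():
    rng = np.random.default_rng(9)
    with pytest.raises(ValueError):
        bartlett_sphericity(rng.standard_normal((5, 6)))


# -------------------------------------------------- oracle equivalence suite


@pytest.mark.parametrize("seed", range(20))
def test_oracle_equivalence_on_seeded_matrices(seed):
    """alpha/KMO/Bartlett agree with independent references to 1e-8."""
    rng = np.random.default_rng(1_000 + seed)
    n = int(rng.integers(60, 200))
    k = int(rng.integers(3, 9))
    m = random_likert_matrix(rng, n, k)
    assert cronbach_alpha_standardized(m) == pytest.approx(
        alpha_oracle(m), abs=1e-8
    )
    assert kmo(m) == pytest.approx(kmo_oracle(m), abs=1e-8)
    chi2, df, p = bartlett_oracle(m)
    res = bartlett_sphericity(m)
    assert res.chi2 == pytest.approx(chi2, abs=1e-8)
    assert res.df == df
    assert res.p == pytest.approx(p, abs=1e-8)


# --------------------------------------------------- sample size & rates


@pytest.mark.parametrize(
    "args, expected",
    [
        ((14, 5, 10, 1.2), (84, 168)),
        ((1, 5, 10, 1.0), (5, 10)),
        ((14, 5, 10, 1.0), (70, 140)),
    ],
)
def test_kendall_sample_size(args, expected):
    plan = kendall_sample_size(*args)
    assert (plan.n_min, plan.n_max) == expected
    assert plan.n_min <= plan.n_max


def test_kendall_sample_size_validation():
    with pytest.raises(ValueError):
        kendall_sample_size(0)
    with pytest.raises(ValueError):
        kendall_sample_size(5, attrition_inflation=0.9)
    with pytest.raises(ValueError):
        kendall_sample_size(5, multiplier_low=-1)


def test_response_rate():
    assert response_rate(101, 120) == pytest.approx(0.8417, abs=5e-5)
    assert response_rate(0, 10) == 0.0
    assert response_rate(10, 10) == 1.0
    with pytest.raises(ValueError):
        response_rate(11, 10)
    with pytest.raises(ValueError):
        response_rate(1, 0)
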