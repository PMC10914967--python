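"""Instrument-quality statistics and the sample-size heuristic.

Reliability and sampling-adequacy checks conventionally reported for Kano
questionnaires, computed separately for the functional ("forward") and
dysfunctional ("reverse") instrument:

* standardized Cronbach's alpha (internal consistency),
* Kaiser-Meyer-Olkin sampling adequacy (correlations vs anti-image
  partial correlations),
* Bartlett's test of sphericity (correlation matrix = identity),

plus the Kendall rule of thumb for survey sample size (5-10 respondents per
independent variable, inflated for attrition).

All correlations are Pearson correlations on the integer Likert codes, the
standard-package convention for these statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


class SingularCorrelationError(ValueError):
    """Correlation matrix is (numerically) singular."""


def _validate_matrix(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise ValueError("item-response matrix must be 2-D (respondents x items)")
    if np.isnan(m).any():
        # complete-case: drop respondents with any missing cell
        m = m[~np.isnan(m).any(axis=1)]
    n, k = m.shape
    if k < 2:
        raise ValueError("need at least 2 items")
    if n < 3:
        raise ValueError("need at least 3 complete respondents")
    return m


def _correlation(m: np.ndarray) -> np.ndarray:
    sd = m.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.where(sd == 0)[0].tolist()
        raise ValueError(f"zero-variance items at columns {bad}")
    return np.corrcoef(m, rowvar=False)


def cronbach_alpha_standardized(m: np.ndarray, drop_constant: bool = True) -> float:
    """Standardized Cronbach's alpha: k*rbar / (1 + (k-1)*rbar).

    k is the item count and rbar the mean off-diagonal Pearson correlation.
    Zero-variance items carry no reliability information; by default they
    are excluded (with a warning) rather than poisoning the correlations.
    """
    m = _validate_matrix(m)
    sd = m.std(axis=0, ddof=1)
    if np.any(sd == 0):
        if not drop_constant:
            raise ValueError("zero-variance item present")
        import warnings

        warnings.warn(
            f"excluding {int((sd == 0).sum())} zero-variance item(s) from alpha",
            stacklevel=2,
        )
        m = m[:, sd > 0]
        if m.shape[1] < 2:
            raise ValueError("fewer than 2 items with variance")
    r = np.corrcoef(m, rowvar=False)
    k = r.shape[0]
    off = r[~np.eye(k, dtype=bool)]
    rbar = off.mean()
    return k * rbar / (1.0 + (k - 1) * rbar)


def kmo(m: np.ndarray) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum p_ij^2) over i != j, where p_ij
    are the anti-image partial correlations obtained from the inverse of
    the correlation matrix.
    """
    m = _validate_matrix(m)
    return kmo_from_correlation(_correlation(m))


def kmo_from_correlation(r: np.ndarray) -> float:
    """KMO computed directly from a correlation matrix."""
    r = np.asarray(r, dtype=float)
    k = r.shape[0]
    # invert; a singular matrix means perfectly collinear items
    if np.linalg.matrix_rank(r, tol=1e-10) < k:
        raise SingularCorrelationError(
            "correlation matrix is singular (perfectly collinear items present)"
        )
    rinv = np.linalg.inv(r)
    d = np.sqrt(np.outer(np.diag(rinv), np.diag(rinv)))
    partial = -rinv / d
    mask = ~np.eye(k, dtype=bool)
    r2 = (r[mask] ** 2).sum()
    p2 = (partial[mask] ** 2).sum()
    return float(r2 / (r2 + p2))


@dataclass(frozen=True)
class BartlettResult:
    chi2: float
    df: int
    p: float

    def p_display(self, decimals: int = 4) -> str:
        floor = 10 ** (-decimals)
        if self.p < floor:
            return f"<{floor:.{decimals}f}"
        return f"{self.p:.{decimals}f}"


def bartlett_sphericity(m: np.ndarray) -> BartlettResult:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2k + 5)/6) * ln|R|, df = k(k-1)/2, upper-tail p.
    """
    m = _validate_matrix(m)
    n, k = m.shape
    if n <= k:
        raise ValueError("Bartlett's test needs more respondents than items")
    return bartlett_from_correlation(_correlation(m), n)


def bartlett_from_correlation(r: np.ndarray, n: int) -> BartlettResult:
    """Bartlett's sphericity test from a correlation matrix and sample size."""
    r = np.asarray(r, dtype=float)
    k = r.shape[0]
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise SingularCorrelationError("correlation determinant is not positive")
    chi2 = -(n - 1 - (2 * k + 5) / 6.0) * logdet
    df = k * (k - 1) // 2
    p = float(stats.chi2.sf(chi2, df))
    return BartlettResult(chi2=float(chi2), df=int(df), p=p)


@dataclass(frozen=True)
class SampleSizePlan:
    """Kendall-rule sample-size bounds for a survey."""

    n_vars: int
    multiplier_low: float
    multiplier_high: float
    attrition_inflation: float
    n_min: int
    n_max: int


def kendall_sample_size(
    n_vars: int,
    multiplier_low: float = 5,
    multiplier_high: float = 10,
    attrition_inflation: float = 1.2,
) -> SampleSizePlan:
    """5-10 respondents per independent variable, inflated for attrition.

    Bounds are ceilings of n_vars * multiplier * inflation.
    """
    if n_vars < 1:
        raise ValueError("n_vars must be >= 1")
    if multiplier_low <= 0 or multiplier_high <= 0:
        raise ValueError("multipliers must be positive")
    if multiplier_low > multiplier_high:
        raise ValueError("multiplier_low must not exceed multiplier_high")
    if attrition_inflation < 1:
        raise ValueError("attrition_inflation must be >= 1")
    n_min = math.ceil(n_vars * multiplier_low * attrition_inflation)
    n_max = math.ceil(n_vars * multiplier_high * attrition_inflation)
    return SampleSizePlan(
        n_vars=n_vars,
        multiplier_low=multiplier_low,
        multiplier_high=multiplier_high,
        attrition_inflation=attrition_inflation,
        n_min=n_min,
        n_max=n_max,
    )


def response_rate(valid: int, collected: int) -> float:
    """Share of collected questionnaires that were valid."""
    if collected < 1:
        raise ValueError("collected must be >= 1")
    if not 0 <= valid <= collected:
        raise ValueError("need 0 <= valid <= collected")
    return valid / collected
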