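"""Shared statistical primitives: normality-gated correlation and the
Mann-Whitney U test with an exact small-sample branch.

The correlation rule used throughout the package: Shapiro-Wilk is applied to
both variables at alpha = 0.05; if both look Gaussian the association is
Pearson's r, otherwise Spearman's rho.  The test actually used is always
reported alongside the coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import scipy.stats as sps

from .errors import ValidationError


@dataclass
class CorrelationResult:
    r: float
    p: float
    test_used: str  # "pearson" or "spearman"


def shapiro_gated_correlation(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> CorrelationResult:
    """Correlate two samples, choosing Pearson vs Spearman by normality."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValidationError("need at least 3 observations to correlate")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in a correlation variable")
    with warnings.catch_warnings():
        # Shapiro-Wilk p-values above n=5000 are approximate; fine for gating.
        warnings.simplefilter("ignore")
        px = sps.shapiro(x).pvalue
        py = sps.shapiro(y).pvalue
        if px > alpha and py > alpha:
            r, p = sps.pearsonr(x, y)
            return CorrelationResult(float(r), float(p), "pearson")
        r, p = sps.spearmanr(x, y)
    return CorrelationResult(float(r), float(p), "spearman")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x: #(x_i > y_j) + 0.5 #(ties)."""
    diff = x[:, None] - y[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney_u(
    x: np.ndarray, y: np.ndarray, exact_max: int = 8
) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U test.

    When both groups have at most ``exact_max`` observations the p-value is
    computed by full enumeration of all label assignments (ties handled by
    half-counting in U); otherwise the normal approximation with tie
    correction is used.  Returns ``(U, p, method)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValidationError("both groups must be non-empty")
    u_obs = _u_statistic(x, y)
    if n1 <= exact_max and n2 <= exact_max:
        pooled = np.concatenate([x, y])
        idx = np.arange(n1 + n2)
        mu = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mu)
        hits = 0
        total = 0
        for chosen in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(chosen)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            # tolerance guards half-integer U values against float fuzz
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
            total += 1
        return u_obs, hits / total, "exact"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue), "asymptotic"
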