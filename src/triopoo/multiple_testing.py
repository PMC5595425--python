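"""q-values and QQ-plot quantities for genome-wide p-value vectors.

The q-value of a SNP is the smallest false discovery rate at which it
would be declared significant.  With p-values sorted ascending, the
step-up estimate is ``q(i) = min_{j >= i} pi0 * m * p(j) / j`` capped at
1.  The default null proportion ``pi0 = 1`` makes selection at ``q <= a``
identical to Benjamini-Hochberg at level ``a`` (conservative); a
Storey-type smoother estimate of pi0 is available as an option.

Selecting SNPs at q <= 0.1 targets an expected true-positive proportion
of at least 90% among the selected set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import beta

__all__ = ["qvalues", "estimate_pi0_smoother", "significant_at", "qq_table"]


def qvalues(p, pi0: float | str = 1.0) -> np.ndarray:
    """Step-up q-values, returned in the original order.

    ``pi0`` is the assumed proportion of true nulls (default 1) or
    ``"smoother"`` to estimate it from the p-value distribution.  NaN
    p-values propagate to NaN q-values; other values outside [0, 1] are
    rejected.
    """
    p = np.asarray(p, dtype=float)
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 == "smoother":
        pi0 = estimate_pi0_smoother(p[finite])
    if not (0 < pi0 <= 1):
        raise ValueError(f"pi0 must be in (0, 1], got {pi0}")
    q = np.full_like(p, np.nan)
    pv = p[finite]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pi0 * m * pv[order] / np.arange(1, m + 1)
    qs = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = qs
    q[finite] = out
    return q


def estimate_pi0_smoother(p, lambdas=None) -> float:
    """Storey-type smoother estimate of the null proportion pi0.

    Computes ``pi0(l) = #{p > l} / (m (1 - l))`` on a grid of tuning
    values, fits a cubic polynomial, and evaluates it at the largest grid
    point; the result is clipped to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    p = p[~np.isnan(p)]
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = p.size
    if m == 0:
        return 1.0
    pi0s = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lambdas])
    coef = np.polyfit(lambdas, pi0s, 3)
    pi0 = float(np.polyval(coef, lambdas.max()))
    return float(np.clip(pi0, 1e-8, 1.0))


def significant_at(results, q_threshold: float = 0.1):
    """Rows of a results table (or mask of a q-value vector) with
    ``q <= q_threshold``."""
    if isinstance(results, pd.DataFrame):
        return results[results["q"] <= q_threshold]
    q = np.asarray(results, dtype=float)
    return q <= q_threshold


def qq_table(p) -> pd.DataFrame:
    """Expected vs. observed -log10 p-values with 95% pointwise bands.

    Rank ``i`` of ``m`` has expected quantile ``i / (m + 1)``; the band
    comes from the Beta(i, m - i + 1) distribution of the i-th order
    statistic of m uniforms, transformed to the -log10 scale.
    """
    p = np.asarray(p, dtype=float)
    p = p[~np.isnan(p)]
    m = p.size
    if m < 1:
        raise ValueError("at least one p-value is required")
    i = np.arange(1, m + 1)
    expected = -np.log10(i / (m + 1.0))
    observed = -np.log10(np.maximum(np.sort(p), 1e-300))
    band_hi = -np.log10(beta.ppf(0.025, i, m - i + 1))
    band_lo = -np.log10(beta.ppf(0.975, i, m - i + 1))
    return pd.DataFrame(
        {
            "rank": i,
            "expected_neglog10p": expected,
            "observed_neglog10p": observed,
            "band_lo": band_lo,
            "band_hi": band_hi,
        }
    )
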