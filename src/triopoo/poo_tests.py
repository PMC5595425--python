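"""Stratified effect estimates and Wald tests for trio designs.

Four tests are provided, all built from per-stratum maximum-likelihood
fits of the trio penetrance model (see :mod:`triopoo.likelihood`):

* **child** — per-allele relative risk of the child's allele regardless
  of parental origin or exposure (reduced model, both strata pooled);
* **PoO** — parent-of-origin relative-risk ratio
  ``RRR_PoO = RR_mat / RR_pat``, both strata pooled;
* **GxE** — ratio of child-allele relative risks between exposure strata;
* **PoOxE** — the headline interaction: the ratio of stratum-specific
  parent-of-origin ratios, ``RRR = RRR_PoO(exposed) / RRR_PoO(unexposed)``.

Each test is a Wald z-test on the log scale.  The stratum-specific log
estimates come from independent fits (disjoint families), so the variance
of a between-stratum contrast is the sum of the stratum variances; within
a stratum, the covariance of (log RR_mat, log RR_pat) is kept in the
delta-method SE of log RRR_PoO.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .likelihood import (
    MISSING,
    MendelianInconsistencyError,
    MonomorphicDataError,
    NotConvergedError,
    PatternCounts,
    StratumFit,
    fit_patterns,
    rrr_poo,
)
from .trio_data import CHILD, FATHER, MOTHER, TrioDataset

__all__ = [
    "PoOxEResult",
    "WaldResult",
    "pooxe_test",
    "poo_test",
    "gxe_test",
    "child_test",
    "genome_scan",
    "SCAN_COLUMNS",
]

_Z95 = 1.96


class EmptyStratumError(ValueError):
    """A stratified test was requested but one stratum has no usable trios."""


@dataclass
class PoOxEResult:
    """PoOxE interaction estimate at one SNP: ratio of the exposed and
    unexposed parent-of-origin relative-risk ratios."""

    snp_id: str
    rrr: float
    ci_95: tuple[float, float]
    z: float
    p: float
    n_exposed: int
    n_unexposed: int
    q: float = np.nan


@dataclass
class WaldResult:
    """Generic log-scale Wald test result (child / PoO / GxE tests)."""

    estimate: float
    ci_95: tuple[float, float]
    z: float
    p: float


def _wald(log_est: float, se: float) -> tuple[float, tuple[float, float], float, float]:
    est = float(np.exp(log_est))
    ci = (est * float(np.exp(-_Z95 * se)), est * float(np.exp(_Z95 * se)))
    if se == 0.0:
        z = 0.0 if log_est == 0.0 else np.sign(log_est) * np.inf
    else:
        z = log_est / se
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return est, ci, float(z), p


def pooxe_test(fit_unexposed: StratumFit, fit_exposed: StratumFit,
               snp_id: str = "") -> PoOxEResult:
    """Wald test of equal parent-of-origin ratios across exposure strata.

    With ``L_s = log RRR_PoO(s)`` and delta-method SEs ``SE_s``, the
    statistic is ``z = (L_1 - L_0) / sqrt(SE_0^2 + SE_1^2)`` and the
    reported effect is ``RRR = exp(L_1 - L_0)`` (exposed over unexposed).
    """
    _, se0, _ = rrr_poo(fit_unexposed)
    _, se1, _ = rrr_poo(fit_exposed)
    l0 = float(fit_unexposed.theta[1] - fit_unexposed.theta[2])
    l1 = float(fit_exposed.theta[1] - fit_exposed.theta[2])
    se = float(np.sqrt(se0 ** 2 + se1 ** 2))
    est, ci, z, p = _wald(l1 - l0, se)
    return PoOxEResult(
        snp_id=snp_id,
        rrr=est,
        ci_95=ci,
        z=z,
        p=p,
        n_exposed=fit_exposed.n_trios,
        n_unexposed=fit_unexposed.n_trios,
    )


def poo_test(fit_combined: StratumFit) -> WaldResult:
    """Wald test of RRR_PoO = 1 on a pooled (both strata) fit."""
    _, se, _ = rrr_poo(fit_combined)
    l = float(fit_combined.theta[1] - fit_combined.theta[2])
    est, ci, z, p = _wald(l, se)
    return WaldResult(est, ci, z, p)


def _require_converged(fit: StratumFit) -> None:
    if not fit.converged:
        raise NotConvergedError("stratum fit did not converge")


def gxe_test(fit_unexposed: StratumFit, fit_exposed: StratumFit) -> WaldResult:
    """Wald test on the ratio of child-allele relative risks between
    strata (reduced single-RR model per stratum)."""
    for f in (fit_unexposed, fit_exposed):
        if f.model != "child":
            raise ValueError("gxe_test requires reduced (child-model) fits")
        _require_converged(f)
    l = fit_exposed.log_rr - fit_unexposed.log_rr
    se = float(np.sqrt(fit_exposed.var_log_rr + fit_unexposed.var_log_rr))
    est, ci, z, p = _wald(l, se)
    return WaldResult(est, ci, z, p)


def child_test(fit: StratumFit) -> WaldResult:
    """Wald test of the child's per-allele relative risk (pooled reduced
    model)."""
    if fit.model != "child":
        raise ValueError("child_test requires a reduced (child-model) fit")
    _require_converged(fit)
    est, ci, z, p = _wald(fit.log_rr, float(np.sqrt(fit.var_log_rr)))
    return WaldResult(est, ci, z, p)


# ---------------------------------------------------------------------------
# Genome scan
# ---------------------------------------------------------------------------

SCAN_COLUMNS = [
    "snp_id", "chr", "pos", "allele_ref", "allele_alt",
    "n0", "n1", "rrr", "ci_lo", "ci_hi", "z", "p", "q", "reason",
]

TESTS = ("pooxe", "poo", "gxe", "child")


def _snp_member_arrays(dataset: TrioDataset, j: int):
    g = dataset.genotypes[:, :, j]
    return g[:, MOTHER], g[:, FATHER], g[:, CHILD]


def _stratum_patterns(dataset: TrioDataset, j: int, stratum: int) -> PatternCounts:
    m, f, c = _snp_member_arrays(dataset, j)
    keep = dataset.exposures == stratum
    fids = np.asarray(dataset.families, dtype=object)[keep]
    return PatternCounts.from_arrays(m[keep], f[keep], c[keep], family_ids=fids)


def _pooled_patterns(dataset: TrioDataset, j: int) -> PatternCounts:
    m, f, c = _snp_member_arrays(dataset, j)
    return PatternCounts.from_arrays(
        m, f, c, family_ids=np.asarray(dataset.families, dtype=object)
    )


def scan_snp(dataset: TrioDataset, j: int, test: str):
    """Run one test at SNP index ``j``; returns (estimate, ci, z, p,
    n_unexposed, n_exposed)."""
    n0 = int(((dataset.exposures == 0) & (dataset.genotypes[:, CHILD, j] != MISSING)).sum())
    n1 = int(((dataset.exposures == 1) & (dataset.genotypes[:, CHILD, j] != MISSING)).sum())
    if test in ("pooxe", "gxe"):
        model = "poo" if test == "pooxe" else "child"
        pd0 = _stratum_patterns(dataset, j, 0)
        pd1 = _stratum_patterns(dataset, j, 1)
        if pd0.n_trios == 0 or pd1.n_trios == 0:
            raise EmptyStratumError("no analyzable trios in one exposure stratum")
        fit0 = fit_patterns(pd0, model=model)
        fit1 = fit_patterns(pd1, model=model)
        _require_converged(fit0)
        _require_converged(fit1)
        if test == "pooxe":
            r = pooxe_test(fit0, fit1)
            return r.rrr, r.ci_95, r.z, r.p, n0, n1
        r = gxe_test(fit0, fit1)
        return r.estimate, r.ci_95, r.z, r.p, n0, n1
    model = "poo" if test == "poo" else "child"
    fit = fit_patterns(_pooled_patterns(dataset, j), model=model)
    _require_converged(fit)
    r = poo_test(fit) if test == "poo" else child_test(fit)
    return r.estimate, r.ci_95, r.z, r.p, n0, n1


def genome_scan(dataset: TrioDataset, test: str = "pooxe") -> pd.DataFrame:
    """Per-SNP scan over the dataset; one row per SNP in map order.

    SNPs that cannot be fitted (monomorphic, empty stratum, Mendelian
    inconsistency, non-convergence) carry NA statistics and a reason code.
    The ``q`` column is NaN here; fill it with
    :func:`triopoo.multiple_testing.qvalues` on the ``p`` column.
    """
    if test not in TESTS:
        raise ValueError(f"test must be one of {TESTS}, got {test!r}")
    if dataset.n_snps == 0:
        raise ValueError("cannot scan an empty dataset")
    rows = []
    for j, snp in enumerate(dataset.snps):
        base = dict(
            snp_id=snp.snp_id, chr=snp.chromosome, pos=snp.position_bp,
            allele_ref=snp.allele_ref, allele_alt=snp.allele_alt,
            n0=np.nan, n1=np.nan, rrr=np.nan, ci_lo=np.nan, ci_hi=np.nan,
            z=np.nan, p=np.nan, q=np.nan, reason="",
        )
        try:
            est, ci, z, p, n0, n1 = scan_snp(dataset, j, test)
            base.update(n0=n0, n1=n1, rrr=est, ci_lo=ci[0], ci_hi=ci[1], z=z, p=p)
        except EmptyStratumError:
            base["reason"] = "empty_stratum"
        except MonomorphicDataError:
            base["reason"] = "monomorphic"
        except MendelianInconsistencyError:
            base["reason"] = "mendelian_inconsistency"
        except NotConvergedError:
            base["reason"] = "nonconverged"
        rows.append(base)
    return pd.DataFrame(rows, columns=SCAN_COLUMNS)
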