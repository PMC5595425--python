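"""Quality-control filters for trio GWAS datasets.

Filters follow the usual trio-GWAS pipeline, in this order:

1. individuals with a genotype missing rate above ``indiv_missing_max``
   are removed first (a removed parent turns the family into a duo; a
   removed proband removes the family), so that SNP statistics are not
   distorted by poorly genotyped samples;
2. SNP filters, each evaluated independently on the surviving individuals
   and combined as a union (a SNP may fail several): call-rate,
   founder minor allele frequency, exact Hardy-Weinberg test on founders,
   per-SNP Mendelian error rate, and adjacent-pair pruning of SNPs in
   complete LD (r^2 = 1);
3. families whose Mendelian error rate across retained SNPs exceeds
   ``family_mendel_max`` are removed last.

The per-SNP Mendelian-error threshold defaults to 0.10 but is
configurable (see docs/methods.md for why a 0.01 alternative is also
plausible).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihood import MISSING
from .trio_data import CHILD, FATHER, MOTHER, TrioDataset, mendelian_consistent

__all__ = [
    "QCThresholds",
    "QCReport",
    "UndefinedValueError",
    "snp_missingness",
    "minor_allele_frequency",
    "hwe_exact_test",
    "snp_mendel_error_rate",
    "ld_r2_adjacent",
    "apply_qc",
]


class UndefinedValueError(ValueError):
    """A QC statistic has no defined value on this data (e.g. MAF with no
    genotyped founders)."""


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds; a SNP/individual/family failing any criterion
    is removed.  ``ld_prune=False`` disables complete-LD pruning."""

    snp_missing_max: float = 0.05
    maf_min: float = 0.05
    hwe_p_min: float = 0.001
    snp_mendel_max: float = 0.10
    indiv_missing_max: float = 0.10
    family_mendel_max: float = 0.05
    ld_prune: bool = True

    def __post_init__(self):
        for name in ("snp_missing_max", "maf_min", "hwe_p_min",
                     "snp_mendel_max", "indiv_missing_max", "family_mendel_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class QCReport:
    """Per-criterion exclusion counts.  SNP criteria overlap (one SNP may
    fail several), so the per-criterion counts need not sum to the number
    removed."""

    n_snps_total: int = 0
    snp_failures: dict = field(default_factory=dict)  # criterion -> count
    n_snps_removed: int = 0
    n_snps_remaining: int = 0
    n_individuals_total: int = 0
    n_individuals_removed: int = 0
    n_families_total: int = 0
    n_families_removed: int = 0
    n_families_remaining: int = 0

    def as_frame(self) -> pd.DataFrame:
        rows = [("snps_total", self.n_snps_total)]
        rows += [(f"snps_failed_{k}", v) for k, v in self.snp_failures.items()]
        rows += [
            ("snps_removed", self.n_snps_removed),
            ("snps_remaining", self.n_snps_remaining),
            ("individuals_total", self.n_individuals_total),
            ("individuals_removed_callrate", self.n_individuals_removed),
            ("families_total", self.n_families_total),
            ("families_removed_mendel", self.n_families_removed),
            ("families_remaining", self.n_families_remaining),
        ]
        return pd.DataFrame(rows, columns=["statistic", "count"])


# ---------------------------------------------------------------------------
# Per-SNP statistics
# ---------------------------------------------------------------------------


def snp_missingness(dataset: TrioDataset, snp) -> float:
    """Fraction of present individuals with a MISSING call at the SNP."""
    j = dataset.snp_index(snp) if isinstance(snp, str) else snp
    g = dataset.genotypes[:, :, j][dataset.present]
    if g.size == 0:
        raise UndefinedValueError("no genotyped individuals")
    return float((g == MISSING).mean())


def minor_allele_frequency(dataset: TrioDataset, snp) -> float:
    """Frequency of the alternative allele among non-missing founder
    (parental) alleles; <= 0.5 by the reference-allele convention."""
    d = dataset.founder_dosages(snp)
    d = d[d != MISSING]
    if d.size == 0:
        raise UndefinedValueError("no genotyped founders at this SNP")
    return float(d.sum() / (2.0 * d.size))


def hwe_exact_test(counts) -> float:
    """Two-sided exact Hardy-Weinberg test on founder genotype counts
    ``(n0, n1, n2)`` (hom-ref, het, hom-alt).

    Conditional on the observed allele counts, the heterozygote count n1
    follows a known distribution; the p-value sums the probabilities of
    all heterozygote counts whose probability does not exceed that of the
    observed count.  Monomorphic data gives p = 1.
    """
    n0, n1, n2 = (int(c) for c in counts)
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("at least one genotyped founder is required")
    n_alt = n1 + 2 * n2  # alt-allele count; parity fixes feasible n1 values
    n_ref = 2 * n - n_alt
    rare = min(n_alt, n_ref)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(n1 = h | allele counts) up to a constant:
    #   log n! - log n0! - log h! - log n2! + h log 2
    from scipy.special import gammaln

    homs_rare = (rare - hets) // 2
    homs_common = n - hets - homs_rare
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(homs_rare + 1)
        - gammaln(homs_common + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[np.flatnonzero(hets == n1)[0]]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def snp_mendel_error_rate(dataset: TrioDataset, snp) -> float:
    """Fraction of fully genotyped families whose trio violates Mendelian
    transmission at the SNP."""
    j = dataset.snp_index(snp) if isinstance(snp, str) else snp
    g = dataset.genotypes[:, :, j]
    complete = (g != MISSING).all(axis=1)
    if not complete.any():
        raise UndefinedValueError("no family with all three members genotyped")
    bad = [
        not mendelian_consistent(int(m), int(f), int(c))
        for m, f, c in g[complete]
    ]
    return float(np.mean(bad))


def ld_r2_adjacent(dataset: TrioDataset, snp_a, snp_b) -> float:
    """Squared Pearson correlation (composite r^2) of founder dosages at
    two SNPs on the same chromosome, over pairwise-complete founders."""
    ja = dataset.snp_index(snp_a) if isinstance(snp_a, str) else snp_a
    jb = dataset.snp_index(snp_b) if isinstance(snp_b, str) else snp_b
    if dataset.snps[ja].chromosome != dataset.snps[jb].chromosome:
        raise ValueError("LD r^2 is only computed within a chromosome")
    da = dataset.founder_dosages(ja).astype(float)
    db = dataset.founder_dosages(jb).astype(float)
    ok = (da != MISSING) & (db != MISSING)
    if ok.sum() < 2:
        raise UndefinedValueError("fewer than two founders genotyped at both SNPs")
    da, db = da[ok], db[ok]
    if da.std() == 0 or db.std() == 0:
        raise UndefinedValueError("zero dosage variance at one SNP")
    r = np.corrcoef(da, db)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# Dataset-level filtering
# ---------------------------------------------------------------------------


def _family_mendel_rate(dataset: TrioDataset, i: int) -> float:
    g = dataset.genotypes[i]  # (3, n_snps)
    complete = (g != MISSING).all(axis=0)
    if not complete.any():
        return 0.0
    bad = [
        not mendelian_consistent(int(m), int(f), int(c))
        for m, f, c in g[:, complete].T
    ]
    return float(np.mean(bad))


def apply_qc(dataset: TrioDataset, thresholds: QCThresholds = QCThresholds()):
    """Apply all filters; returns ``(filtered dataset, QCReport)``."""
    th = thresholds
    report = QCReport(
        n_snps_total=dataset.n_snps,
        n_individuals_total=int(dataset.present.sum()),
        n_families_total=dataset.n_families,
    )

    # (vi) individual call rate ------------------------------------------
    ds = dataset.subset_snps(np.ones(dataset.n_snps, dtype=bool))  # deep-ish copy
    drop_fams = []
    n_indiv_removed = 0
    if ds.n_snps > 0:
        miss = (ds.genotypes == MISSING).mean(axis=2)  # (n_fam, 3)
        for i, fid in enumerate(ds.families):
            for mem in (MOTHER, FATHER):
                if ds.present[i, mem] and miss[i, mem] > th.indiv_missing_max:
                    ds.mask_member(i, mem)
                    n_indiv_removed += 1
            if ds.present[i, CHILD] and miss[i, CHILD] > th.indiv_missing_max:
                drop_fams.append(fid)
                n_indiv_removed += 1
    if drop_fams:
        ds = ds.drop_families(drop_fams)
    report.n_individuals_removed = n_indiv_removed

    # (i)-(v) SNP filters -------------------------------------------------
    n_snps = ds.n_snps
    fail = {k: np.zeros(n_snps, dtype=bool)
            for k in ("missingness", "maf", "hwe", "mendel", "ld")}
    for j in range(n_snps):
        try:
            fail["missingness"][j] = snp_missingness(ds, j) > th.snp_missing_max
        except UndefinedValueError:
            fail["missingness"][j] = True
        try:
            fail["maf"][j] = minor_allele_frequency(ds, j) < th.maf_min
        except UndefinedValueError:
            fail["maf"][j] = True
        d = ds.founder_dosages(j)
        d = d[d != MISSING]
        if d.size:
            cnt = (int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))
            fail["hwe"][j] = hwe_exact_test(cnt) < th.hwe_p_min
        try:
            fail["mendel"][j] = snp_mendel_error_rate(ds, j) > th.snp_mendel_max
        except UndefinedValueError:
            pass
    if th.ld_prune:
        prev = None  # nearest earlier unflagged SNP on the same chromosome
        for j in range(n_snps):
            if prev is not None and ds.snps[prev].chromosome == ds.snps[j].chromosome:
                try:
                    if ld_r2_adjacent(ds, prev, j) >= 1.0 - 1e-12:
                        fail["ld"][j] = True
                except UndefinedValueError:
                    pass
            if prev is None or ds.snps[prev].chromosome != ds.snps[j].chromosome:
                prev = j
            elif not fail["ld"][j]:
                prev = j

    report.snp_failures = {k: int(v.sum()) for k, v in fail.items()}
    any_fail = np.logical_or.reduce(list(fail.values()))
    report.n_snps_removed = int(any_fail.sum())
    ds = ds.subset_snps(~any_fail)
    report.n_snps_remaining = ds.n_snps

    # (vii) family Mendelian rate ----------------------------------------
    bad_fams = [
        fid for i, fid in enumerate(ds.families)
        if _family_mendel_rate(ds, i) > th.family_mendel_max
    ]
    if bad_fams:
        ds = ds.drop_families(bad_fams)
    report.n_families_removed = len(bad_fams)
    report.n_families_remaining = ds.n_families
    return ds, report
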