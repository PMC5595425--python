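"""Trio dataset simulation and power estimation for PoOxE designs.

Trios are drawn directly from the ascertained case-trio distribution: for
each family a stratum is drawn (Bernoulli with the exposed fraction), and
the observable (mother, father, child) genotype configuration is then
sampled from the exact 15-category multinomial implied by the stratum's
penetrance parameters (see :func:`triopoo.likelihood.config_probability`).
This is mathematically identical to prospective simulation with case
ascertainment for a pure case-trio design, and much faster.  Parents can
subsequently be masked to MISSING at configurable rates to emulate
incomplete trios.

The default power-curve scenario varies the maternal relative risk in the
exposed stratum only (``rr_mat_1 = RRR``, all other relative risks 1), so
the implied interaction ratio equals ``RRR``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import poo_tests
from .likelihood import (
    MISSING,
    ModelParams,
    MonomorphicDataError,
    NotConvergedError,
    OBSERVABLE_CONFIGS,
    PatternCounts,
    config_probabilities,
    fit_patterns,
)
from .trio_data import SnpInfo, TrioDataset

__all__ = ["SimulationSpec", "PowerResult", "sample_trios", "sample_dataset",
           "power_estimate", "pooxe_scenario"]

_CONFIGS = np.array(OBSERVABLE_CONFIGS)  # (15, 3)


@dataclass(frozen=True)
class SimulationSpec:
    """Full parameterization of the trio-generating process.

    Defaults mirror the reference power-study conditions: 500 trios,
    MAF 0.20, equally-sized exposed and unexposed groups, complete
    genotyping, and no effects (all relative risks 1).
    """

    n_trios: int = 500
    maf: float = 0.2
    exposed_fraction: float = 0.5
    rr_mat_0: float = 1.0
    rr_pat_0: float = 1.0
    rr_mat_1: float = 1.0
    rr_pat_1: float = 1.0
    missing_mother_rate: float = 0.0
    missing_father_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")
        if self.n_trios < 1:
            raise ValueError("n_trios must be positive")
        if not (0.0 <= self.exposed_fraction <= 1.0):
            raise ValueError("exposed_fraction must be in [0,1]")
        for name in ("rr_mat_0", "rr_pat_0", "rr_mat_1", "rr_pat_1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("missing_mother_rate", "missing_father_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0,1]")

    def params(self, stratum: int) -> ModelParams:
        if stratum == 0:
            return ModelParams(self.maf, self.rr_mat_0, self.rr_pat_0)
        return ModelParams(self.maf, self.rr_mat_1, self.rr_pat_1)

    @property
    def implied_rrr(self) -> float:
        """The PoOxE ratio of relative-risk ratios implied by the spec."""
        return (self.rr_mat_1 / self.rr_pat_1) / (self.rr_mat_0 / self.rr_pat_0)


def pooxe_scenario(rrr: float, **kwargs) -> SimulationSpec:
    """Power-curve scenario: the maternal relative risk in the exposed
    stratum is set to ``rrr``, all other relative risks stay at 1."""
    return SimulationSpec(rr_mat_1=rrr, **kwargs)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _sample_stratum_members(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    return rng.binomial(1, spec.exposed_fraction, size=spec.n_trios).astype(np.int8)


def _sample_configs(spec, strata, rng) -> np.ndarray:
    """(n_trios, 3) observable genotype configs, one row per trio."""
    out = np.empty((len(strata), 3), dtype=np.int8)
    for s in (0, 1):
        idx = np.flatnonzero(strata == s)
        if idx.size == 0:
            continue
        probs = config_probabilities(spec.params(s))
        cats = rng.choice(len(_CONFIGS), size=idx.size, p=probs)
        out[idx] = _CONFIGS[cats]
    return out


def _mask_parents(geno, spec, rng) -> None:
    n = geno.shape[0]
    if spec.missing_mother_rate > 0:
        geno[rng.random(n) < spec.missing_mother_rate, 0] = MISSING
    if spec.missing_father_rate > 0:
        geno[rng.random(n) < spec.missing_father_rate, 1] = MISSING


def sample_trios(spec: SimulationSpec, rng=None) -> TrioDataset:
    """Simulate a single-SNP trio dataset with exposures (reproducible
    given ``spec.seed`` or an explicit generator)."""
    return sample_dataset(spec, n_null_snps=0, rng=rng)


def sample_dataset(spec: SimulationSpec, n_null_snps: int = 0, rng=None) -> TrioDataset:
    """Simulate a dataset with one effect SNP (named ``snp_effect``, drawn
    under the spec's relative risks) plus ``n_null_snps`` independent null
    SNPs at the same allele frequency.  Exposure strata are shared across
    SNPs within a family."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    strata = _sample_stratum_members(spec, rng)
    null_spec = replace(spec, rr_mat_0=1.0, rr_pat_0=1.0, rr_mat_1=1.0, rr_pat_1=1.0)

    n_snps = 1 + n_null_snps
    geno = np.empty((spec.n_trios, 3, n_snps), dtype=np.int8)
    snps = []
    for j in range(n_snps):
        s = spec if j == 0 else null_spec
        g = _sample_configs(s, strata, rng)
        _mask_parents(g, spec, rng)
        geno[:, :, j] = g
        name = "snp_effect" if j == 0 else f"snp_null_{j:04d}"
        snps.append(SnpInfo(name, "1", 100_000 * (j + 1), "A", "B"))

    families = [f"fam{i:05d}" for i in range(spec.n_trios)]
    present = np.ones((spec.n_trios, 3), dtype=bool)
    # parents missing at every SNP are treated as absent members
    for mem in (0, 1):
        present[:, mem] = (geno[:, mem, :] != MISSING).any(axis=1)
    return TrioDataset(snps, families, geno, present, strata.copy())


# ---------------------------------------------------------------------------
# Power estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PowerResult:
    power: float
    mc_se: float
    n_replicates: int
    n_nonconverged: int
    alpha: float
    test: str


def _replicate_pvalue(spec: SimulationSpec, test: str, rng) -> float:
    """Simulate one replicate and return the test p-value.

    Uses a counts-level fast path when genotyping is complete; with
    parental missingness the per-trio path (pattern aggregation with
    MISSING wildcards) is used instead.
    """
    strata = _sample_stratum_members(spec, rng)
    n1 = int(strata.sum())
    n0 = spec.n_trios - n1
    complete = spec.missing_mother_rate == 0 and spec.missing_father_rate == 0

    def stratum_pdata(s: int, n_s: int) -> PatternCounts:
        if complete:
            counts = rng.multinomial(n_s, config_probabilities(spec.params(s)))
            return PatternCounts.from_complete_counts(counts)
        sub = replace(spec, n_trios=max(n_s, 1))
        g = _sample_configs(sub, np.full(n_s, s, dtype=np.int8), rng)
        _mask_parents(g, spec, rng)
        return PatternCounts.from_arrays(g[:, 0], g[:, 1], g[:, 2])

    if test in ("pooxe", "gxe"):
        if n0 == 0 or n1 == 0:
            raise MonomorphicDataError("empty stratum in replicate")
        model = "poo" if test == "pooxe" else "child"
        fit0 = fit_patterns(stratum_pdata(0, n0), model=model)
        fit1 = fit_patterns(stratum_pdata(1, n1), model=model)
        if not (fit0.converged and fit1.converged):
            raise NotConvergedError
        if test == "pooxe":
            return poo_tests.pooxe_test(fit0, fit1).p
        return poo_tests.gxe_test(fit0, fit1).p
    # pooled tests: merge stratum draws
    pdata0 = stratum_pdata(0, n0) if n0 else None
    pdata1 = stratum_pdata(1, n1) if n1 else None
    pdata = _merge_patterns([p for p in (pdata0, pdata1) if p is not None])
    model = "poo" if test == "poo" else "child"
    fit = fit_patterns(pdata, model=model)
    if not fit.converged:
        raise NotConvergedError
    if test == "poo":
        return poo_tests.poo_test(fit).p
    return poo_tests.child_test(fit).p


def _merge_patterns(parts: list[PatternCounts]) -> PatternCounts:
    from collections import Counter

    from .likelihood import _pattern_mask

    tally: Counter = Counter()
    for part in parts:
        for pat, n in zip(part.patterns, part.counts):
            tally[pat] += n
    pats = sorted(tally)
    counts = np.array([tally[p] for p in pats], dtype=float)
    masks = np.array([_pattern_mask(*p) for p in pats], dtype=float)
    return PatternCounts(pats, counts, masks)


def power_estimate(spec: SimulationSpec, n_replicates: int = 1000,
                   alpha: float = 0.05, test: str = "pooxe",
                   seed=None) -> PowerResult:
    """Monte-Carlo power: fraction of replicates with p < alpha.

    Replicates that fail to converge (or are degenerate) count as
    non-rejections and are reported separately.  Each replicate draws from
    its own child seed of the master seed (``seed`` argument, falling back
    to ``spec.seed``), so runs are reproducible.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if test not in poo_tests.TESTS:
        raise ValueError(f"unknown test {test!r}")
    master = seed if seed is not None else spec.seed
    ss = np.random.SeedSequence(master)
    n_reject = 0
    n_noncon = 0
    for child_ss in ss.spawn(n_replicates):
        rng = np.random.default_rng(child_ss)
        try:
            p = _replicate_pvalue(spec, test, rng)
        except (NotConvergedError, MonomorphicDataError):
            n_noncon += 1
            continue
        if p < alpha:
            n_reject += 1
    power = n_reject / n_replicates
    mc_se = float(np.sqrt(power * (1.0 - power) / n_replicates))
    return PowerResult(power, mc_se, n_replicates, n_noncon, alpha, test)
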