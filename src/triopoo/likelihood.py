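"""Log-linear multinomial likelihood for case-parent trios with
parent-of-origin penetrance.

The model describes the genotype distribution of ascertained case-parent
trios at one biallelic SNP.  Founders (the parents) are assumed to be in
Hardy-Weinberg equilibrium with variant-allele frequency ``q`` and to mate
at random.  The child's disease risk is multiplicative in allele dose, with
a separate relative risk for the maternally inherited variant allele
(``RR_mat``) and the paternally inherited one (``RR_pat``); a child carrying
both has relative risk ``RR_mat * RR_pat`` (no extra double-dose
parameter).  Conditional on the child being a case, the probability of a
*latent* trio configuration -- parental genotypes plus the origin-resolved
transmitted alleles ``(x_m, x_p)`` -- is proportional to

    HWE(mother; q) * HWE(father; q)
      * T(x_m | mother) * T(x_p | father)
      * RR_mat^{x_m} * RR_pat^{x_p},

where ``T`` is Mendelian transmission (1/2 per heterozygous parent).
Summing the 16 latent configurations by their observable (mother, father,
child) genotypes yields a multinomial over 15 observable trio categories.
Missing parental genotypes are handled by marginalizing the latent sum over
the unobserved parent, so the fit maximizes the observed-data likelihood
directly; the observed-data information matrix then provides standard
errors already corrected for the missingness.

Two penetrance models are supported:

* ``"poo"``  -- distinct maternal/paternal relative risks (3 parameters:
  allele frequency, RR_mat, RR_pat);
* ``"child"`` -- a single per-allele relative risk regardless of origin
  (2 parameters), used for child-effect and GxE tests.

Optimization runs on the unconstrained scale
``(logit q, log RR_mat, log RR_pat)``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import comb, expit

#: Sentinel for a missing genotype call or missing exposure.
MISSING = -1

__all__ = [
    "MISSING",
    "ModelParams",
    "StratumFit",
    "PatternCounts",
    "MonomorphicDataError",
    "MendelianInconsistencyError",
    "NotConvergedError",
    "OBSERVABLE_CONFIGS",
    "config_probability",
    "observed_data_loglik",
    "fit_patterns",
    "fit_stratum",
    "rrr_poo",
]


class MonomorphicDataError(ValueError):
    """Raised when only one allele is present in the data to be fitted."""


class MendelianInconsistencyError(ValueError):
    """Raised when an observed trio genotype pattern admits no Mendelian
    transmission (e.g. two homozygous-reference parents with a het child)."""


class NotConvergedError(RuntimeError):
    """Raised when a downstream quantity is requested from a fit that did
    not converge."""


# ---------------------------------------------------------------------------
# Latent configuration tables
# ---------------------------------------------------------------------------

# (parent genotype, transmitted-variant indicator, transmission probability)
_PARENT_TRANS = ((0, 0, 1.0), (1, 0, 0.5), (1, 1, 0.5), (2, 1, 1.0))

_lat = [
    (m, f, xm, xp, tm * tp)
    for (m, xm, tm) in _PARENT_TRANS
    for (f, xp, tp) in _PARENT_TRANS
]
LAT_M = np.array([r[0] for r in _lat])
LAT_F = np.array([r[1] for r in _lat])
LAT_XM = np.array([r[2] for r in _lat])
LAT_XP = np.array([r[3] for r in _lat])
_LAT_T = np.array([r[4] for r in _lat])
LAT_C = LAT_XM + LAT_XP

# constant weight factor: HWE binomial coefficients times transmission prob
_COEF = comb(2, LAT_M) * comb(2, LAT_F) * _LAT_T
_GSUM = LAT_M + LAT_F  # exponent of q in the founder HWE term

#: The 15 observable (mother, father, child) genotype categories.
OBSERVABLE_CONFIGS = sorted({(m, f, c) for m, f, c in zip(LAT_M, LAT_F, LAT_C)})
assert len(OBSERVABLE_CONFIGS) == 15


def _pattern_mask(m: int, f: int, c: int) -> np.ndarray:
    """Boolean mask over the 16 latent configurations compatible with an
    observed (possibly MISSING-parent) genotype pattern."""
    mask = LAT_C == c
    if m != MISSING:
        mask = mask & (LAT_M == m)
    if f != MISSING:
        mask = mask & (LAT_F == f)
    return mask


_COMPLETE_MASKS = np.array(
    [_pattern_mask(m, f, c) for m, f, c in OBSERVABLE_CONFIGS], dtype=float
)


# ---------------------------------------------------------------------------
# Parameters and fits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelParams:
    """Penetrance-model parameters on the natural scale.

    q
        Variant (a1) allele frequency among founders, strictly in (0, 1).
    rr_mat, rr_pat
        Relative risk per maternally / paternally inherited variant allele.
    """

    q: float
    rr_mat: float
    rr_pat: float

    def __post_init__(self) -> None:
        if not (0.0 < self.q < 1.0):
            raise ValueError(f"allele frequency q must be in (0,1), got {self.q}")
        if self.rr_mat <= 0 or self.rr_pat <= 0:
            raise ValueError("relative risks must be positive")
        if not np.all(np.isfinite([self.q, self.rr_mat, self.rr_pat])):
            raise ValueError("parameters must be finite")


@dataclass
class StratumFit:
    """Maximum-likelihood fit of one penetrance model in one stratum.

    ``theta`` is the MLE on the unconstrained scale — ``(logit q,
    log RR_mat, log RR_pat)`` for the ``"poo"`` model, ``(logit q, log RR)``
    for the ``"child"`` model — and ``cov`` the corresponding observed-data
    covariance matrix (inverse negative Hessian of the marginal
    log-likelihood), so standard errors account for marginalized missing
    parents.
    """

    model: str
    theta: np.ndarray
    cov: np.ndarray
    loglik: float
    n_trios: int
    converged: bool

    @property
    def q(self) -> float:
        return float(expit(self.theta[0]))

    @property
    def params(self) -> ModelParams:
        if self.model == "poo":
            return ModelParams(self.q, float(np.exp(self.theta[1])),
                               float(np.exp(self.theta[2])))
        rr = float(np.exp(self.theta[1]))
        return ModelParams(self.q, rr, rr)

    @property
    def log_rr(self) -> float:
        """Single-allele log relative risk (child model only)."""
        if self.model != "child":
            raise ValueError("log_rr is defined for the child model")
        return float(self.theta[1])

    @property
    def var_log_rr(self) -> float:
        if self.model != "child":
            raise ValueError("var_log_rr is defined for the child model")
        return float(self.cov[1, 1])


# ---------------------------------------------------------------------------
# Pattern counts (sufficient statistics)
# ---------------------------------------------------------------------------


@dataclass
class PatternCounts:
    """Aggregated observed genotype patterns at one SNP.

    A *pattern* is an observed (mother, father, child) genotype triple in
    which either parent may be MISSING; the child genotype is always
    observed.  ``masks`` holds, per pattern, the indicator vector of
    compatible latent configurations.
    """

    patterns: list[tuple[int, int, int]]
    counts: np.ndarray
    masks: np.ndarray = field(repr=False)  # (P, 16) float

    @property
    def n_trios(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_arrays(cls, mothers, fathers, children, family_ids=None) -> "PatternCounts":
        """Aggregate per-trio genotype calls; trios with a MISSING child
        genotype are dropped.  Raises :class:`MendelianInconsistencyError`
        if a pattern admits no Mendelian transmission, naming the offending
        families when ``family_ids`` is given."""
        mothers = np.asarray(mothers)
        fathers = np.asarray(fathers)
        children = np.asarray(children)
        keep = children != MISSING
        tally: Counter = Counter(
            zip(mothers[keep].tolist(), fathers[keep].tolist(), children[keep].tolist())
        )
        patterns, counts, masks = [], [], []
        for pat, n in sorted(tally.items()):
            mask = _pattern_mask(*pat)
            if not mask.any():
                if family_ids is not None:
                    fids = np.asarray(family_ids)[keep]
                    bad = [
                        str(f)
                        for f, m, fa, c in zip(fids, mothers[keep], fathers[keep], children[keep])
                        if (m, fa, c) == pat
                    ]
                    raise MendelianInconsistencyError(
                        f"genotype pattern {pat} is Mendelian-inconsistent "
                        f"(families: {', '.join(bad)})"
                    )
                raise MendelianInconsistencyError(
                    f"genotype pattern {pat} is Mendelian-inconsistent"
                )
            patterns.append(pat)
            counts.append(n)
            masks.append(mask)
        return cls(patterns, np.asarray(counts, dtype=float),
                   np.asarray(masks, dtype=float))

    @classmethod
    def from_complete_counts(cls, counts) -> "PatternCounts":
        """Counts aligned with :data:`OBSERVABLE_CONFIGS` (complete trios)."""
        counts = np.asarray(counts, dtype=float)
        nz = counts > 0
        return cls(
            [cfg for cfg, k in zip(OBSERVABLE_CONFIGS, nz) if k],
            counts[nz],
            _COMPLETE_MASKS[nz],
        )

    def allele_freq(self) -> float:
        """Crude variant-allele frequency over all observed calls, used to
        initialize the optimizer.  Raises MonomorphicDataError if only one
        allele is observed."""
        alt = 0.0
        tot = 0.0
        for (m, f, c), n in zip(self.patterns, self.counts):
            for g in (m, f, c):
                if g != MISSING:
                    alt += n * g
                    tot += n * 2
        if tot == 0 or alt == 0 or alt == tot:
            raise MonomorphicDataError(
                "only one allele observed; penetrance parameters are not identifiable"
            )
        return alt / tot


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _latent_weights(q: float, betas: np.ndarray, dose: np.ndarray) -> np.ndarray:
    """Unnormalized latent-configuration weights; ``dose`` is (k, 16)."""
    return _COEF * q ** _GSUM * (1.0 - q) ** (4 - _GSUM) * np.exp(betas @ dose)


_DOSE_POO = np.vstack([LAT_XM, LAT_XP]).astype(float)
_DOSE_CHILD = LAT_C[None, :].astype(float)


def _dose_matrix(model: str) -> np.ndarray:
    if model == "poo":
        return _DOSE_POO
    if model == "child":
        return _DOSE_CHILD
    raise ValueError(f"unknown model {model!r}")


def config_probability(params: ModelParams, config: tuple[int, int, int]) -> float:
    """Probability of one observable (mother, father, child) genotype
    configuration in the ascertained case-trio population.

    The probabilities over the 15 observable configurations sum to 1.
    """
    betas = np.array([np.log(params.rr_mat), np.log(params.rr_pat)])
    w = _latent_weights(params.q, betas, _DOSE_POO)
    mask = _pattern_mask(*config)
    return float(w[mask].sum() / w.sum())


def config_probabilities(params: ModelParams) -> np.ndarray:
    """Vector of probabilities aligned with :data:`OBSERVABLE_CONFIGS`."""
    betas = np.array([np.log(params.rr_mat), np.log(params.rr_pat)])
    w = _latent_weights(params.q, betas, _DOSE_POO)
    return (_COMPLETE_MASKS @ w) / w.sum()


def _nll_and_grad(theta: np.ndarray, pdata: PatternCounts, dose: np.ndarray):
    """Negative marginal log-likelihood and its analytic gradient on the
    unconstrained scale.  d log w / d logit(q) = (g_m + g_f) - 4q."""
    q = expit(theta[0])
    betas = theta[1:]
    w = _latent_weights(q, betas, dose)
    S = w.sum()
    Wp = pdata.masks @ w
    n = pdata.counts.sum()
    ll = pdata.counts @ np.log(Wp) - n * np.log(S)

    facs = np.vstack([_GSUM - 4.0 * q, dose])  # (k+1, 16)
    wf = w * facs  # (k+1, 16)
    G = pdata.masks @ wf.T  # (P, k+1)
    g_all = wf.sum(axis=1)  # (k+1,)
    grad = pdata.counts @ (G / Wp[:, None]) - n * g_all / S
    return -ll, -grad


def observed_data_loglik(params: ModelParams, trios) -> float:
    """Marginal log-likelihood of trio records at one SNP.

    ``trios`` is an iterable of objects with ``mother``, ``father`` and
    ``child`` genotype attributes (or (m, f, c) triples); MISSING parents
    are marginalized over.  Mendelian-inconsistent complete patterns raise
    :class:`MendelianInconsistencyError`.
    """
    m, f, c = _trio_arrays(trios)
    pdata = PatternCounts.from_arrays(m, f, c)
    theta = np.array(
        [np.log(params.q) - np.log1p(-params.q),
         np.log(params.rr_mat), np.log(params.rr_pat)]
    )
    nll, _ = _nll_and_grad(theta, pdata, _DOSE_POO)
    return -float(nll)


def _trio_arrays(trios):
    ms, fs, cs = [], [], []
    for t in trios:
        if hasattr(t, "mother"):
            ms.append(t.mother)
            fs.append(t.father)
            cs.append(t.child)
        else:
            m, f, c = t
            ms.append(m)
            fs.append(f)
            cs.append(c)
    return np.array(ms), np.array(fs), np.array(cs)


def _numeric_hessian(fun_grad, x: np.ndarray, pdata, dose) -> np.ndarray:
    k = len(x)
    H = np.empty((k, k))
    for i in range(k):
        h = 1e-5 * max(1.0, abs(x[i]))
        e = np.zeros(k)
        e[i] = h
        gp = fun_grad(x + e, pdata, dose)[1]
        gm = fun_grad(x - e, pdata, dose)[1]
        H[:, i] = (gp - gm) / (2.0 * h)
    return (H + H.T) / 2.0


def fit_patterns(pdata: PatternCounts, model: str = "poo") -> StratumFit:
    """Maximize the observed-data likelihood over aggregated patterns.

    The optimizer runs BFGS with the analytic gradient from
    (logit of the crude allele frequency, 0, ...); convergence requires the
    gradient inf-norm to fall below ``1e-6 * max(1, n_trios)`` (the
    log-likelihood and its gradient scale linearly with the trio count).
    """
    dose = _dose_matrix(model)
    q0 = np.clip(pdata.allele_freq(), 1e-3, 1 - 1e-3)
    x0 = np.zeros(1 + dose.shape[0])
    x0[0] = np.log(q0) - np.log1p(-q0)
    res = minimize(
        _nll_and_grad,
        x0,
        args=(pdata, dose),
        jac=True,
        method="BFGS",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    gtol = 1e-6 * max(1.0, pdata.counts.sum())
    converged = bool(np.isfinite(res.fun) and np.max(np.abs(res.jac)) < gtol)
    H = _numeric_hessian(_nll_and_grad, res.x, pdata, dose)
    try:
        cov = np.linalg.inv(H)
        if not np.all(np.diag(cov) >= 0):
            converged = False
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        converged = False
    return StratumFit(
        model=model,
        theta=res.x,
        cov=cov,
        loglik=-float(res.fun),
        n_trios=pdata.n_trios,
        converged=converged,
    )


def fit_stratum(trios, model: str = "poo") -> StratumFit:
    """Fit one exposure stratum from per-trio records (see
    :func:`observed_data_loglik` for the accepted forms)."""
    m, f, c = _trio_arrays(trios)
    fids = [t.family_id for t in trios] if trios and hasattr(trios[0], "family_id") else None
    pdata = PatternCounts.from_arrays(m, f, c, family_ids=fids)
    return fit_patterns(pdata, model=model)


def rrr_poo(fit: StratumFit) -> tuple[float, float, tuple[float, float]]:
    """Parent-of-origin relative-risk ratio RR_mat / RR_pat for one fit.

    Returns ``(estimate, SE of log estimate, 95% CI)``.  The SE comes from
    the delta method on the correlated (log RR_mat, log RR_pat) estimates:
    ``sqrt(var_mat + var_pat - 2 cov)``.
    """
    if fit.model != "poo":
        raise ValueError("rrr_poo requires a parent-of-origin model fit")
    if not fit.converged:
        raise NotConvergedError("cannot form RRR_PoO from a non-converged fit")
    log_rrr = float(fit.theta[1] - fit.theta[2])
    var = float(fit.cov[1, 1] + fit.cov[2, 2] - 2.0 * fit.cov[1, 2])
    se = float(np.sqrt(max(var, 0.0)))
    est = float(np.exp(log_rrr))
    ci = (est * float(np.exp(-1.96 * se)), est * float(np.exp(1.96 * se)))
    return est, se, ci
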