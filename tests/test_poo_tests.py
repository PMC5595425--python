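"""Wald tests (child, PoO, GxE, PoOxE) and the per-SNP genome scan."""

import numpy as np
import pytest
from scipy.stats import norm

from conftest import make_dataset
from triopoo import (
    MISSING,
    SimulationSpec,
    child_test,
    fit_stratum,
    genome_scan,
    gxe_test,
    poo_test,
    pooxe_scenario,
    pooxe_test,
    sample_dataset,
    sample_trios,
)
from triopoo.likelihood import fit_patterns
from triopoo.simulator import _sample_configs


def stratum_fits(spec, seed, model="poo"):
    ds = sample_trios(SimulationSpec(**{**spec.__dict__, "seed": seed}))
    trios = ds.trios_at(0)
    f0 = fit_stratum([t for t in trios if t.exposure == 0], model=model)
    f1 = fit_stratum([t for t in trios if t.exposure == 1], model=model)
    return f0, f1


class TestPoOxE:
    def test_identical_fits_give_null_result(self):
        spec = SimulationSpec(n_trios=2000, maf=0.3, seed=1)
        f0, _ = stratum_fits(spec, 1)
        r = pooxe_test(f0, f0)
        assert r.rrr == pytest.approx(1.0)
        assert r.z == 0.0
        assert r.p == pytest.approx(1.0)

    def test_wald_arithmetic(self):
        """L1 - L0 = log 2 with SE0 = SE1 = 0.25 gives z = 1.960, p ~ 0.05."""
        spec = SimulationSpec(n_trios=2000, maf=0.3, seed=4)
        f0, f1 = stratum_fits(spec, 4)
        # force exact log-RRR and covariances
        f0.theta[1], f0.theta[2] = 0.0, 0.0
        f1.theta[1], f1.theta[2] = np.log(2.0), 0.0
        for f in (f0, f1):
            f.cov = np.diag([0.1, 0.0625, 0.0]).astype(float)  # var log RRR = 0.0625
        r = pooxe_test(f0, f1)
        assert r.rrr == pytest.approx(2.0)
        assert r.z == pytest.approx(np.log(2.0) / np.sqrt(2 * 0.0625), abs=1e-9)
        assert r.z == pytest.approx(1.9605, abs=1e-3)
        assert r.p == pytest.approx(2 * norm.sf(r.z), abs=1e-12)
        assert r.p == pytest.approx(0.05, abs=2e-3)

    def test_stratum_swap_antisymmetry(self):
        spec = pooxe_scenario(2.0, n_trios=3000, maf=0.25)
        f0, f1 = stratum_fits(spec, 8)
        a = pooxe_test(f0, f1)
        b = pooxe_test(f1, f0)
        assert a.rrr == pytest.approx(1.0 / b.rrr, rel=1e-10)
        assert a.z == pytest.approx(-b.z, abs=1e-10)
        assert a.p == pytest.approx(b.p, abs=1e-10)

    def test_reference_allele_flip_inverts_rrr(self):
        """Recoding genotypes g -> 2 - g (swapping which allele is the
        reference) inverts the RRR and leaves the p-value unchanged."""
        spec = pooxe_scenario(3.0, n_trios=2000, maf=0.3, seed=21)
        ds = sample_trios(spec)
        trios = ds.trios_at(0)

        def fits(flip):
            out = []
            for s in (0, 1):
                sub = [t for t in trios if t.exposure == s]
                arr = [(2 - t.mother, 2 - t.father, 2 - t.child) if flip
                       else (t.mother, t.father, t.child) for t in sub]
                out.append(fit_stratum(arr))
            return out

        a = pooxe_test(*fits(False))
        b = pooxe_test(*fits(True))
        assert a.rrr == pytest.approx(1.0 / b.rrr, rel=1e-5)
        assert a.p == pytest.approx(b.p, rel=1e-5)


class TestPooledTests:
    def test_poo_null_at_mle(self):
        spec = SimulationSpec(n_trios=5000, maf=0.3, seed=5)
        fit = fit_stratum(sample_trios(spec).trios_at(0))
        r = poo_test(fit)
        assert r.ci_95[0] < r.estimate < r.ci_95[1]
        assert r.p > 0.001  # null data should rarely reject

    def test_child_effect_recovery(self):
        spec = SimulationSpec(n_trios=100_000, maf=0.2, rr_mat_0=1.5,
                              rr_pat_0=1.5, rr_mat_1=1.5, rr_pat_1=1.5, seed=6)
        fit = fit_stratum(sample_trios(spec).trios_at(0), model="child")
        r = child_test(fit)
        assert r.estimate == pytest.approx(1.5, rel=0.05)
        assert r.p < 1e-10

    def test_child_mle_invariant_to_parent_relabel(self):
        spec = SimulationSpec(n_trios=2000, maf=0.3, rr_mat_0=1.4,
                              rr_pat_0=1.4, rr_mat_1=1.4, rr_pat_1=1.4, seed=14)
        trios = sample_trios(spec).trios_at(0)
        a = fit_stratum([(t.mother, t.father, t.child) for t in trios], model="child")
        b = fit_stratum([(t.father, t.mother, t.child) for t in trios], model="child")
        assert a.log_rr == pytest.approx(b.log_rr, abs=1e-6)

    def test_gxe_recovery(self):
        spec = SimulationSpec(n_trios=100_000, maf=0.2, rr_mat_1=2.0,
                              rr_pat_1=2.0, seed=10)
        f0, f1 = stratum_fits(spec, 10, model="child")
        r = gxe_test(f0, f1)
        assert r.estimate == pytest.approx(2.0, rel=0.07)
        assert r.p < 1e-10

    def test_gxe_equal_strata_null(self):
        spec = SimulationSpec(n_trios=3000, maf=0.3, seed=12)
        f0, _ = stratum_fits(spec, 12, model="child")
        r = gxe_test(f0, f0)
        assert r.estimate == pytest.approx(1.0)
        assert r.p == pytest.approx(1.0)


class TestGenomeScan:
    def test_planted_effect_has_smallest_p(self):
        spec = pooxe_scenario(8.0, n_trios=600, maf=0.3, seed=17)
        ds = sample_dataset(spec, n_null_snps=20)
        res = genome_scan(ds, test="pooxe")
        assert res.loc[res["p"].idxmin(), "snp_id"] == "snp_effect"

    def test_scan_is_order_independent(self):
        spec = SimulationSpec(n_trios=300, maf=0.3, seed=23)
        ds = sample_dataset(spec, n_null_snps=5)
        res = genome_scan(ds, test="pooxe")
        perm = [3, 0, 5, 1, 4, 2]
        ds_perm = ds.subset_snps(np.array(perm))
        res_perm = genome_scan(ds_perm, test="pooxe")
        merged = res_perm.set_index("snp_id").loc[res["snp_id"]]
        np.testing.assert_allclose(merged["p"].to_numpy(), res["p"].to_numpy(), rtol=1e-12)

    def test_monomorphic_snp_gets_reason(self):
        geno = np.zeros((40, 3, 1), dtype=np.int8)
        ds = make_dataset(geno, exposures=[i % 2 for i in range(40)])
        res = genome_scan(ds, test="pooxe")
        assert res.loc[0, "reason"] == "monomorphic"
        assert np.isnan(res.loc[0, "p"])

    def test_missing_exposure_trios_excluded_from_stratified_fit(self):
        spec = SimulationSpec(n_trios=400, maf=0.3, seed=31)
        ds = sample_trios(spec)
        ds.exposures[:50] = MISSING
        res = genome_scan(ds, test="pooxe")
        assert res.loc[0, "n0"] + res.loc[0, "n1"] == 350

    def test_empty_dataset_refused(self):
        geno = np.zeros((4, 3, 1), dtype=np.int8)
        ds = make_dataset(geno).subset_snps(np.zeros(1, dtype=bool))
        with pytest.raises(ValueError):
            genome_scan(ds, test="pooxe")


class TestCalibrationAndPowerOrdering:
    def test_null_scan_rejects_about_five_percent(self):
        spec = SimulationSpec(n_trios=400, maf=0.3, seed=29)
        ds = sample_dataset(spec, n_null_snps=99)
        res = genome_scan(ds, test="pooxe")
        frac = (res["p"] < 0.05).mean()
        # binomial(100, 0.05): 3 SE band around 0.05
        assert frac < 0.05 + 3 * np.sqrt(0.05 * 0.95 / 100)

    def test_pooxe_matches_likelihood_ratio_oracle(self):
        """The Wald PoOxE test and an independently coded likelihood-ratio
        test (full vs. equal-RRR-across-strata model, both maximized by a
        generic optimizer) must agree on rejections at alpha = 0.05."""
        from scipy.optimize import minimize
        from scipy.stats import chi2

        from triopoo.likelihood import PatternCounts, _DOSE_POO, _nll_and_grad

        def lrt_pvalue(counts0, counts1):
            pd0 = PatternCounts.from_complete_counts(counts0)
            pd1 = PatternCounts.from_complete_counts(counts1)

            def nll_free(x):
                return (_nll_and_grad(x[:3], pd0, _DOSE_POO)[0]
                        + _nll_and_grad(x[3:], pd1, _DOSE_POO)[0])

            def nll_constrained(x):
                # common log RRR d: parameterize stratum 1 with bm1 = bp1 + d
                a0, bm0, bp0, a1, bp1 = x
                d = bm0 - bp0
                f0 = _nll_and_grad(np.array([a0, bm0, bp0]), pd0, _DOSE_POO)[0]
                f1 = _nll_and_grad(np.array([a1, bp1 + d, bp1]), pd1, _DOSE_POO)[0]
                return f0 + f1

            x0 = np.zeros(6)
            free = minimize(nll_free, x0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
            con = minimize(nll_constrained, np.zeros(5), method="Nelder-Mead",
                           options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
            lam = 2 * (con.fun - free.fun)
            return chi2.sf(max(lam, 0.0), df=1)

        from triopoo.likelihood import config_probabilities, fit_patterns
        from triopoo.poo_tests import pooxe_test

        spec = pooxe_scenario(2.0, n_trios=1000, maf=0.2)
        rng = np.random.default_rng(77)
        wald_rej, lrt_rej, n_rep = 0, 0, 40
        for _ in range(n_rep):
            c0 = rng.multinomial(500, config_probabilities(spec.params(0)))
            c1 = rng.multinomial(500, config_probabilities(spec.params(1)))
            f0 = fit_patterns(PatternCounts.from_complete_counts(c0))
            f1 = fit_patterns(PatternCounts.from_complete_counts(c1))
            p_wald = pooxe_test(f0, f1).p
            p_lrt = lrt_pvalue(c0, c1)
            wald_rej += p_wald < 0.05
            lrt_rej += p_lrt < 0.05
            # asymptotically equivalent tests: p-values close on each draw
            assert abs(p_wald - p_lrt) < 0.05 or (p_wald < 1e-3 and p_lrt < 1e-3)
        assert abs(wald_rej - lrt_rej) <= 4
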