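"""Stratified Cox fitting, LRT, the pair scan and signature derivation."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from stromascan import (
    ClinicalTable,
    ComputationError,
    SearchConfig,
    ValidationError,
    derive_prognostic_sets,
    evaluate_gene_adjusted,
    evaluate_signature_pair,
    fit_cox_ph,
    likelihood_ratio_test,
    pairwise_scan,
)
from stromascan.coxsearch import CoxData, PairScanResult
from stromascan.metagene import GeneSignature
from stromascan.synthetic_data import SimulationConfig, generate_cohort

from conftest import make_expr


def survival_frame(rng, n=300, beta=(0.5, -0.5), with_ties=True, n_strata=3):
    X = rng.standard_normal((n, len(beta)))
    rates = 0.1 * np.exp(X @ np.asarray(beta))
    T = rng.exponential(1 / rates)
    if with_ties:
        T = np.ceil(T * 2) / 2  # heavy ties
    C = rng.exponential(20, n)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    strata = rng.integers(0, n_strata, n)
    return X, time, event, strata


def make_clinical(time, event, er=None, node=None):
    n = len(time)
    df = pd.DataFrame({
        "time": time, "event": event,
        "er_status": er if er is not None else ["pos"] * n,
        "node_status": node if node is not None else ["neg"] * n,
    }, index=[f"S{i+1:04d}" for i in range(n)])
    return ClinicalTable(df, time_unit="months")


class TestCoxFitter:
    def test_matches_lifelines_with_ties_and_strata(self, rng):
        X, time, event, strata = survival_frame(rng)
        fit = CoxData(time, event, strata).fit(X, names=["a", "b"])
        df = pd.DataFrame({"T": time, "E": event, "a": X[:, 0], "b": X[:, 1],
                           "s": strata})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E", strata=["s"])
        assert fit.converged
        assert np.allclose(fit.coef, cph.params_.values, atol=1e-5)
        assert np.allclose(fit.se, cph.standard_errors_.values, atol=1e-5)
        assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_matches_grid_search_oracle_tiny(self):
        # n=6, one binary covariate, distinct event times, no censoring
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.ones(6, dtype=int)
        x = np.array([1.0, 0.0, 1.0, 0.0, 0.0, 1.0])

        def partial_loglik(b):
            order = np.argsort(time)
            ll = 0.0
            for i, idx in enumerate(order):
                risk = order[i:]
                ll += b * x[idx] - np.log(np.exp(b * x[risk]).sum())
            return ll

        grid = np.arange(-5, 5, 1e-4)
        lls = [partial_loglik(b) for b in grid]
        b_star = grid[int(np.argmax(lls))]
        fit = CoxData(time, event).fit(x.reshape(-1, 1))
        assert fit.coef[0] == pytest.approx(b_star, abs=2e-4)

    def test_location_invariance(self, rng):
        X, time, event, strata = survival_frame(rng, beta=(0.7,))
        f1 = CoxData(time, event, strata).fit(X)
        f2 = CoxData(time, event, strata).fit(X + 123.4)
        assert np.allclose(f1.coef, f2.coef, atol=1e-8)
        assert np.allclose(f1.se, f2.se, atol=1e-8)
        assert f1.lrt_p == pytest.approx(f2.lrt_p, rel=1e-6)

    def test_hr_and_ci_consistency(self, rng):
        X, time, event, strata = survival_frame(rng)
        fit = CoxData(time, event, strata).fit(X)
        assert np.allclose(fit.hr, np.exp(fit.coef))
        assert (fit.ci_low < fit.hr).all() and (fit.hr < fit.ci_high).all()
        assert 0.0 <= fit.lrt_p <= 1.0

    def test_constant_covariate_is_error(self, rng):
        X, time, event, _ = survival_frame(rng, beta=(0.5,))
        clin = make_clinical(time, event)
        with pytest.raises(ValidationError, match="constant"):
            fit_cox_ph({"flat": np.ones(len(time))}, clin, strata=())
        fit = fit_cox_ph(pd.DataFrame({"x": X[:, 0], "flat": np.ones(len(time))},
                                      index=clin.data.index),
                         clin, strata=(), drop_constant=True)
        assert fit.names == ["x"]

    def test_missing_strata_samples_excluded(self, rng):
        X, time, event, _ = survival_frame(rng, beta=(0.5,))
        er = ["pos"] * len(time)
        er[:25] = ["missing"] * 25
        clin = make_clinical(time, event, er=er)
        fit = fit_cox_ph({"x": pd.Series(X[:, 0], index=clin.data.index)},
                         clin, strata=("er_status",))
        assert fit.n == len(time) - 25


class TestStratification:
    def test_stratified_nominal_pooled_inflated(self):
        """With strata-specific baselines and a stratum-linked covariate,
        stratified fits keep nominal type-I error while pooling inflates it."""
        rng = np.random.default_rng(7)
        n, reps = 200, 150
        rej_strat = rej_pool = 0
        for _ in range(reps):
            stratum = rng.integers(0, 2, n)
            x = stratum + 0.5 * rng.standard_normal(n)  # linked, no true effect
            rates = 0.05 * np.exp(1.5 * stratum)
            T = rng.exponential(1 / rates)
            C = rng.exponential(1 / 0.02, n)
            time = np.minimum(T, C)
            event = (T <= C).astype(int)
            f_s = CoxData(time, event, stratum).fit(x.reshape(-1, 1))
            f_p = CoxData(time, event).fit(x.reshape(-1, 1))
            rej_strat += f_s.converged and f_s.lrt_p < 0.05
            rej_pool += f_p.converged and f_p.lrt_p < 0.05
        assert rej_pool > rej_strat
        assert rej_strat / reps < 0.12
        assert rej_pool / reps > 0.5


class TestLikelihoodRatioTest:
    def test_equal_logliks_give_p_one(self):
        assert likelihood_ratio_test(-100.0, -100.0, df=1) == pytest.approx(1.0)

    def test_chi_square_quantile(self):
        p = likelihood_ratio_test(-98.0795, -100.0, df=1)  # stat = 3.841
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_negative_statistic_is_error(self):
        with pytest.raises(ComputationError):
            likelihood_ratio_test(-101.0, -100.0, df=1)

    def test_null_calibration_df1(self, rng):
        reject = 0
        for _ in range(1000):
            n = 200
            x = rng.standard_normal(n)
            T = rng.exponential(10, n)
            C = rng.exponential(25, n)
            time = np.minimum(T, C)
            event = (T <= C).astype(int)
            fit = CoxData(time, event).fit(x.reshape(-1, 1))
            reject += fit.lrt_p < 0.05
        assert 0.03 <= reject / 1000 <= 0.07


class TestPairwiseScan:
    def _cohort(self, seed=3, n=400):
        cfg = SimulationConfig(n_samples=n, n_block_genes=0, n_endo_genes=0,
                               n_noise_genes=8, n_good_genes=1, n_poor_genes=1,
                               beta_good=-0.6, beta_poor=0.6, seed=seed)
        return generate_cohort(cfg)

    def test_pair_count_is_n_choose_2(self):
        cohort = self._cohort()
        genes = cohort.expression.gene_ids[:5]
        results = pairwise_scan(cohort.expression, genes, cohort.clinical)
        assert len(results) == 10
        pairs = {frozenset((r.gene_a, r.gene_b)) for r in results}
        assert len(pairs) == 10  # a permutation, no dropped pairs

    def test_planted_opposing_pair_ranks_top(self):
        top3 = 0
        for seed in range(20):
            cohort = self._cohort(seed=seed, n=800)
            genes = (cohort.truth.good_genes + cohort.truth.poor_genes
                     + cohort.truth.noise_genes)
            results = pairwise_scan(cohort.expression, genes, cohort.clinical)
            planted = frozenset(cohort.truth.good_genes + cohort.truth.poor_genes)
            rank = next(i for i, r in enumerate(results)
                        if frozenset((r.gene_a, r.gene_b)) == planted)
            top3 += rank < 3
        assert top3 >= 18  # >= 90% of seeds

    def test_symmetric_in_gene_order(self):
        cohort = self._cohort()
        genes = cohort.expression.gene_ids[:4]
        fwd = pairwise_scan(cohort.expression, genes, cohort.clinical)
        rev = pairwise_scan(cohort.expression, genes[::-1], cohort.clinical)
        f = {frozenset((r.gene_a, r.gene_b)): r.lrt_p for r in fwd}
        r = {frozenset((r.gene_a, r.gene_b)): r.lrt_p for r in rev}
        for key in f:
            assert f[key] == pytest.approx(r[key], rel=1e-8)

    def test_fewer_than_two_genes_is_error(self):
        cohort = self._cohort()
        with pytest.raises(ValidationError):
            pairwise_scan(cohort.expression, ["GOOD01"], cohort.clinical)


def _mk_result(a, b, hr_a, hr_b, p, conv=True):
    return PairScanResult(a, b, hr_a, hr_b, p, conv)


class TestDerivePrognosticSets:
    def test_count_threshold_strict_and_sides(self):
        ranked = []
        # gene A appears 6x with HR>1, gene B 6x with HR<1, gene C 5x
        for i in range(6):
            ranked.append(_mk_result("A", "B", 1.5, 0.7, 1e-8 * (i + 1)))
        for i in range(5):
            ranked.append(_mk_result("C", f"D{i}", 1.2, 0.9, 1e-6 * (i + 1)))
        sets = derive_prognostic_sets(ranked, SearchConfig(top_k=100, min_count=5))
        assert sets.poor.genes == ["A"]
        assert sets.good.genes == ["B"]
        assert "C" not in sets.counts  # exactly 5 appearances -> excluded
        assert sets.counts == {"A": 6, "B": 6}

    def test_majority_sign_and_tie_exclusion(self):
        ranked = ([_mk_result("A", f"X{i}", 1.5, 0.9, 1e-9) for i in range(4)]
                  + [_mk_result("A", f"Y{i}", 0.6, 1.1, 1e-8) for i in range(4)]
                  + [_mk_result("B", f"Z{i}", 1.4, 0.8, 1e-7) for i in range(7)])
        with pytest.warns(UserWarning, match="tied"):
            sets = derive_prognostic_sets(ranked, SearchConfig())
        assert sets.excluded_ties == ["A"]
        assert sets.poor.genes == ["B"]

    def test_unconverged_pairs_skipped_and_determinism(self):
        ranked = ([_mk_result("A", "B", 2.0, 0.5, float("nan"), conv=False)]
                  + [_mk_result("C", f"N{i}", 1.5, 0.9, 1e-8) for i in range(6)])
        s1 = derive_prognostic_sets(ranked, SearchConfig())
        s2 = derive_prognostic_sets(ranked, SearchConfig())
        assert "A" not in s1.counts and "B" not in s1.counts
        assert s1.poor.genes == s2.poor.genes == ["C"]
        assert not set(s1.good.genes) & set(s1.poor.genes)


class TestSignatureEvaluation:
    def test_identical_signatures_flagged_collinear(self, default_cohort):
        sig = GeneSignature("g", default_cohort.truth.good_genes)
        sig2 = GeneSignature("p", default_cohort.truth.good_genes)
        _, _, multi = evaluate_signature_pair(
            sig, sig2, default_cohort.expression, default_cohort.clinical)
        assert not multi.converged

    def test_amplification_on_planted_cohort(self):
        wins = 0
        for seed in range(10):
            cohort = generate_cohort(SimulationConfig(
                n_samples=800, n_block_genes=0, n_endo_genes=0,
                n_noise_genes=0, seed=seed))
            good = GeneSignature("good", cohort.truth.good_genes)
            poor = GeneSignature("poor", cohort.truth.poor_genes)
            uni_g, uni_p, multi = evaluate_signature_pair(
                good, poor, cohort.expression, cohort.clinical)
            wins += (abs(multi.coef[0]) > abs(uni_g.coef[0])
                     and abs(multi.coef[1]) > abs(uni_p.coef[0]))
        assert wins > 5

    def test_null_signatures_cover_one(self):
        covered = 0
        for seed in range(40):
            cohort = generate_cohort(SimulationConfig(
                n_samples=300, n_block_genes=0, n_endo_genes=0,
                n_noise_genes=0, beta_good=0.0, beta_poor=0.0, seed=100 + seed))
            good = GeneSignature("good", cohort.truth.good_genes)
            poor = GeneSignature("poor", cohort.truth.poor_genes)
            uni_g, uni_p, _ = evaluate_signature_pair(
                good, poor, cohort.expression, cohort.clinical)
            covered += int(uni_g.ci_low[0] <= 1 <= uni_g.ci_high[0])
            covered += int(uni_p.ci_low[0] <= 1 <= uni_p.ci_high[0])
        # ~95% nominal; the two signature scores are correlated, so misses
        # cluster in pairs and the bound is set below the binomial band
        assert covered / 80 >= 0.87


class TestGeneAdjusted:
    def test_empty_opposing_reduces_to_univariate(self, default_cohort):
        uni, adj = evaluate_gene_adjusted(
            "GOOD01", GeneSignature("empty", []),
            default_cohort.expression, default_cohort.clinical)
        assert adj.names == uni.names
        assert np.allclose(adj.coef, uni.coef)
        assert any("empty" in w for w in adj.warnings)

    def test_adjusted_amplifies_planted_gene(self):
        wins = 0
        for seed in range(10):
            cohort = generate_cohort(SimulationConfig(
                n_samples=800, n_block_genes=0, n_endo_genes=0,
                n_noise_genes=0, seed=seed))
            poor = GeneSignature("poor", cohort.truth.poor_genes)
            uni, adj = evaluate_gene_adjusted(
                "GOOD01", poor, cohort.expression, cohort.clinical)
            wins += abs(adj.coef[0]) > abs(uni.coef[0])
        assert wins > 5

    def test_orthogonal_opposing_changes_little(self, rng):
        n = 2000
        x = rng.standard_normal(n)
        opp = rng.standard_normal(n)  # independent of gene and survival
        T = rng.exponential(np.exp(-0.5 * x) / 0.05)
        C = rng.exponential(1 / 0.02, n)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
        em = make_expr(np.vstack([8 + x, 8 + opp]), genes=["GENE", "OPP"],
                       samples=[f"S{i+1:04d}" for i in range(n)])
        clin = make_clinical(time, event)
        uni, adj = evaluate_gene_adjusted(
            "GENE", GeneSignature("opp", ["OPP"]), em, clin, strata=())
        assert abs(adj.coef[0] - uni.coef[0]) < 0.05
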