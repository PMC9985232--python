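"""EWAS: GEE route cross-checks, BH FDR oracle, tiers, and null calibration."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import twinewas as tw
from twinewas.ewas import build_design


def brute_force_bh(p):
    """Step-up q-values by direct enumeration of the BH definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


class TestBhFdr:
    def test_single_p_identity(self):
        assert tw.bh_fdr([0.01])[0] == pytest.approx(0.01)

    def test_stepup_example(self):
        np.testing.assert_allclose(tw.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-8, 1.0, 200)
        np.testing.assert_allclose(tw.bh_fdr(p), brute_force_bh(p), rtol=1e-12)

    def test_monotone_in_sorted_p(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=500)
        q = tw.bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tw.bh_fdr([])
        with pytest.raises(ValueError):
            tw.bh_fdr([0.0, 0.5])


class TestTiers:
    @pytest.mark.parametrize("p,q,tier", [
        (5.764e-8, 0.010, "genomewide"),             # strongest WNT3A-type row
        (5.756e-6, 0.161, "weaker_than_suggestive"),  # SRRM1P2-type row
        (9.845e-5, 0.450, "top"),                    # weakest reported top CpG
        (5e-7, 0.20, "suggestive"),
        (2e-4, 0.60, "ns"),
        (np.nan, np.nan, "ns"),
    ])
    def test_threshold_labels(self, p, q, tier):
        rows = pd.DataFrame({"p_value": [p], "fdr_q": [q]})
        assert tw.classify_tiers(rows)["tier"].iloc[0] == tier

    def test_tiers_mutually_exclusive_first_match_wins(self):
        # strong p but controlled q: genomewide takes precedence over suggestive
        rows = pd.DataFrame({"p_value": [1e-9], "fdr_q": [0.01]})
        assert tw.classify_tiers(rows)["tier"].iloc[0] == "genomewide"


class TestFitGeeCpg:
    def _sim(self, seed=0, **kw):
        sc = tw.SimScenario(name="bp_causal", n_pairs=100, n_cpgs=10,
                            n_signal_cpgs=10, seed=seed, **kw)
        out = tw.simulate_twin_cohort(sc)
        coh = tw.derive_bp(out.cohort, "SBP")
        return tw.beta_to_m(out.matrix), coh

    def test_matches_statsmodels_gee(self):
        mat, coh = self._sim()
        m = mat.m_values.iloc[0]
        coef, se, p = tw.fit_gee_cpg(m, coh, "SBP", cov_type="robust")
        design = build_design(coh, "SBP",
                              individual_ids=list(coh.individual_ids))
        y = m.loc[design.individual_ids].to_numpy()
        ref = sm.GEE(y, design.X, groups=design.clusters,
                     cov_struct=sm.cov_struct.Exchangeable(),
                     family=sm.families.Gaussian()).fit(ctol=1e-10, maxiter=200)
        assert coef == pytest.approx(ref.params[1], rel=1e-8)
        assert se == pytest.approx(ref.bse[1], rel=1e-8)

    def test_independence_working_equals_ols_oracle(self):
        """Zero within-pair correlation: the GEE point estimate collapses to
        ordinary least squares exactly under the independence working model."""
        mat, coh = self._sim(intra_pair_rho=0.0, familial_load_bp=0.0)
        m = mat.m_values.iloc[0]
        coef, _, _ = tw.fit_gee_cpg(m, coh, "SBP", working="independence")
        design = build_design(coh, "SBP",
                              individual_ids=list(coh.individual_ids))
        ols = sm.OLS(m.loc[design.individual_ids].to_numpy(), design.X).fit()
        assert coef == pytest.approx(ols.params[1], rel=1e-9)

    def test_robust_ci_covers_true_slope(self):
        """Nominal-level coverage of the +-2 robust-SE interval on a cleanly
        causal simulation (true slope 0.01 M-units per mmHg, 100 pairs)."""
        covered = 0
        for seed in range(100):
            sc = tw.SimScenario(name="bp_causal", n_pairs=100, n_cpgs=10,
                                n_signal_cpgs=10, causal_effect=0.01,
                                familial_load_bp=0.0, cell_bp_coupling=0.0,
                                seed=seed)
            out = tw.simulate_twin_cohort(sc)
            coh = tw.derive_bp(out.cohort, "SBP")
            mat = tw.beta_to_m(out.matrix)
            coef, se, _ = tw.fit_gee_cpg(mat.m_values.iloc[0], coh, "SBP")
            covered += abs(coef - 0.01) <= 2 * se
        assert covered >= 93

    def test_too_few_pairs_flagged_not_crashed(self):
        mat, coh = self._sim()
        m = mat.m_values.iloc[0].copy()
        m.iloc[25:] = np.nan                      # leaves < 10 complete pairs
        coef, se, p = tw.fit_gee_cpg(m, coh, "SBP", min_pairs=20)
        assert np.isnan(coef) and np.isnan(p)


class TestRunEwas:
    def test_output_contract(self, null_sim, null_cohort):
        mat, _ = tw.qc_filter_cpgs(null_sim.matrix)
        mat = tw.beta_to_m(mat)
        rows = tw.run_ewas(mat, null_cohort, "SBP")
        assert len(rows) == mat.n_cpgs            # one row per post-QC CpG
        p = rows["p_value"].to_numpy()
        assert np.all(np.diff(p[np.isfinite(p)]) >= 0)   # ascending p
        assert set(rows.columns) >= {"chrom", "pos", "coefficient",
                                     "robust_se", "p_value", "fdr_q",
                                     "tier", "gene_symbols"}

    def test_batch_path_equals_per_cpg_route(self, null_sim, null_cohort):
        mat, _ = tw.qc_filter_cpgs(null_sim.matrix)
        mat = tw.beta_to_m(mat)
        rows = tw.run_ewas(mat, null_cohort, "SBP")
        sample = rows.iloc[[0, 100, 400]]
        for _, r in sample.iterrows():
            m = mat.m_values.loc[(r["chrom"], r["pos"])]
            coef, se, p = tw.fit_gee_cpg(m, null_cohort, "SBP")
            assert r["coefficient"] == pytest.approx(coef, rel=1e-8)
            assert r["p_value"] == pytest.approx(p, rel=1e-6)

    def test_permuted_phenotype_p_values_uniform(self):
        """Breaking the pair-to-phenotype link leaves uniform p-values."""
        sc = tw.SimScenario(name="meth_causal", n_pairs=100, n_cpgs=2000,
                            seed=33)
        out = tw.simulate_twin_cohort(sc)
        coh = tw.derive_bp(out.cohort, "SBP")
        t = coh.table.copy()
        rng = np.random.default_rng(0)
        pairs = t["pair_id"].unique()
        by_pair = {p: t.loc[t.pair_id == p, "sbp"].to_numpy() for p in pairs}
        for p, q in zip(pairs, rng.permutation(pairs)):
            t.loc[t.pair_id == p, "sbp"] = by_pair[q]
        permuted = tw.TwinCohort(t.reset_index())
        mat, _ = tw.qc_filter_cpgs(out.matrix)
        mat = tw.beta_to_m(mat)
        comp = tw.refactor_components(mat, t=500)
        rows = tw.run_ewas(mat, permuted, "SBP", comp)
        ks = stats.kstest(rows["p_value"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_null_inflation_factor_near_one(self):
        sc = tw.SimScenario(name="null", n_pairs=100, n_cpgs=2000, seed=3)
        out = tw.simulate_twin_cohort(sc)
        coh = tw.derive_bp(out.cohort, "SBP")
        mat, _ = tw.qc_filter_cpgs(out.matrix)
        mat = tw.beta_to_m(mat)
        comp = tw.refactor_components(mat, t=500)
        rows = tw.run_ewas(mat, coh, "SBP", comp)
        p = rows["p_value"].dropna()
        lam = np.median(stats.norm.isf(p / 2) ** 2) / stats.chi2.ppf(0.5, 1)
        assert 0.9 <= lam <= 1.1
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_missing_entries_use_pairwise_deletion(self, null_sim, null_cohort):
        mat, _ = tw.qc_filter_cpgs(null_sim.matrix)
        mat = tw.beta_to_m(mat)
        m_values = mat.m_values.copy()
        m_values.iloc[0, :6] = np.nan
        mat2 = mat.replace(m_values=m_values)
        rows = tw.run_ewas(mat2, null_cohort, "SBP")
        assert len(rows) == mat2.n_cpgs
        assert rows["p_value"].notna().all()
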