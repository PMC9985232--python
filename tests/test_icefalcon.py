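"""ICE FALCON: pair reshaping, change arithmetic, verdict rules, recovery."""
import numpy as np
import pandas as pd
import pytest

import twinewas as tw
from twinewas.icefalcon import classify_causality, ice_falcon_fit, reshape_pairs


def _cov(cohort):
    return pd.DataFrame({
        "age": cohort.table["age_years"].astype(float),
        "sex_male": (cohort.table["sex"].astype(str) == "M").astype(float),
    }, index=cohort.table.index)


def _fit_on_signal(scenario_name, seed, n_boot=300, **kw):
    sc = tw.SimScenario(name=scenario_name, n_pairs=100, n_cpgs=20,
                        n_signal_cpgs=5, seed=seed, **kw)
    out = tw.simulate_twin_cohort(sc)
    coh = tw.derive_bp(out.cohort, "SBP")
    mat = tw.beta_to_m(out.matrix)
    locus = out.truth.index[out.truth["is_signal"]][0]
    cov = _cov(coh)
    table = reshape_pairs(coh, x=mat.m_values.loc[locus], y=coh.table["sbp"],
                          covariates=cov)
    return ice_falcon_fit(table, "meth_to_bp", list(cov.columns),
                          n_boot=n_boot, seed=seed)


class TestReshapePairs:
    def test_two_rows_per_pair(self, null_cohort):
        x = null_cohort.table["bmi"]
        y = null_cohort.table["sbp"]
        table = reshape_pairs(null_cohort, x=x, y=y)
        t1, t2 = null_cohort.pair_rows()
        complete = (t1["sbp"].notna() & t2["sbp"].notna()).sum()
        assert len(table) == 2 * complete           # two rows per usable pair

    def test_cotwin_column_is_within_pair_swap(self, null_cohort):
        x = null_cohort.table["bmi"]
        table = reshape_pairs(null_cohort, x=x, y=null_cohort.table["sbp"])
        by_pair = table.groupby("pair_id")
        for _, g in list(by_pair)[:10]:
            assert g["x_self"].iloc[0] == g["x_cotwin"].iloc[1]
            assert g["x_self"].iloc[1] == g["x_cotwin"].iloc[0]

    def test_twin_label_swap_leaves_fit_unchanged(self, null_cohort):
        cov = _cov(null_cohort)
        x = null_cohort.table["bmi"]
        y = null_cohort.table["sbp"]
        t1 = reshape_pairs(null_cohort, x=x, y=y, covariates=cov)
        swapped = null_cohort.table.copy()
        swapped["twin_index"] = 3 - swapped["twin_index"]
        coh2 = tw.TwinCohort(swapped.reset_index())
        t2 = reshape_pairs(coh2, x=x, y=y, covariates=cov)
        f1 = ice_falcon_fit(t1, "meth_to_bp", list(cov.columns),
                            n_boot=50, seed=1)
        f2 = ice_falcon_fit(t2, "meth_to_bp", list(cov.columns),
                            n_boot=50, seed=1)
        assert f1.beta_self == pytest.approx(f2.beta_self, rel=1e-9)
        assert f1.beta_cotwin == pytest.approx(f2.beta_cotwin, rel=1e-9)

    def test_incomplete_pair_dropped(self, null_cohort):
        x = null_cohort.table["bmi"].copy()
        base = len(reshape_pairs(null_cohort, x=x, y=null_cohort.table["sbp"]))
        kept_ids = reshape_pairs(null_cohort, x=x,
                                 y=null_cohort.table["sbp"])["individual_id"]
        x.loc[kept_ids.iloc[0]] = np.nan            # blank one usable twin
        table = reshape_pairs(null_cohort, x=x, y=null_cohort.table["sbp"])
        assert len(table) == base - 2


class TestChangeArithmetic:
    """The printed worked example: self change 0.640, co-twin change −2.869
    gives |−2.869|/|0.640| = 4.483 and, with a significant co-twin change,
    a causal verdict."""

    def test_printed_ratio_reproduced(self):
        verdict, ratio = classify_causality(
            cotwin_change=-2.869, self_change=0.640, p_cotwin_change=0.046)
        assert f"{ratio:.3f}" == "4.483"
        assert verdict == "causal"

    def test_nonsignificant_cotwin_change_undefined_ratio(self):
        verdict, ratio = classify_causality(
            cotwin_change=0.001, self_change=-0.001, p_cotwin_change=0.198)
        assert verdict == "inconclusive" and np.isnan(ratio)

    def test_similar_changes_read_as_confounding(self):
        verdict, ratio = classify_causality(
            cotwin_change=1.2, self_change=1.0, p_cotwin_change=0.01)
        assert verdict == "familial_confounding"
        assert ratio == pytest.approx(1.2)

    def test_zero_self_change_gives_infinite_ratio(self):
        verdict, ratio = classify_causality(
            cotwin_change=2.0, self_change=0.0, p_cotwin_change=0.001)
        assert np.isinf(ratio) and verdict == "causal"


class TestIceFalconFit:
    def test_ratio_consistent_with_stored_coefficients(self):
        f = _fit_on_signal("meth_causal", seed=1)
        if np.isfinite(f.ratio):
            recomputed = (abs(f.beta_cotwin - f.beta_cotwin_full)
                          / abs(f.beta_self - f.beta_self_full))
            assert f.ratio == pytest.approx(recomputed, abs=1e-12)

    def test_deterministic_given_seed(self):
        a = _fit_on_signal("meth_causal", seed=4, n_boot=100)
        b = _fit_on_signal("meth_causal", seed=4, n_boot=100)
        assert a == b

    def test_verdict_invariant_to_affine_rescaling(self, null_cohort):
        cov = _cov(null_cohort)
        x = null_cohort.table["bmi"]
        y = null_cohort.table["sbp"]
        t1 = reshape_pairs(null_cohort, x=x, y=y, covariates=cov)
        t2 = reshape_pairs(null_cohort, x=1000.0 * x + 3.0, y=0.1 * y - 7.0,
                           covariates=cov)
        f1 = ice_falcon_fit(t1, "meth_to_bp", list(cov.columns),
                            n_boot=200, seed=2)
        f2 = ice_falcon_fit(t2, "meth_to_bp", list(cov.columns),
                            n_boot=200, seed=2)
        assert f1.verdict == f2.verdict
        if np.isfinite(f1.ratio):
            assert f1.ratio == pytest.approx(f2.ratio, rel=1e-6)

    def test_too_few_pairs_rejected(self, null_cohort):
        cov = _cov(null_cohort)
        table = reshape_pairs(null_cohort, x=null_cohort.table["bmi"],
                              y=null_cohort.table["sbp"], covariates=cov)
        small = table[table["pair_id"].isin(table["pair_id"].unique()[:5])]
        with pytest.raises(ValueError, match="pairs"):
            ice_falcon_fit(small, covariate_cols=list(cov.columns))


class TestRunIceFalcon:
    def test_two_fits_per_top_cpg(self):
        sc = tw.SimScenario(name="meth_causal", n_pairs=60, n_cpgs=30,
                            n_signal_cpgs=5, seed=2)
        out = tw.simulate_twin_cohort(sc)
        coh = tw.derive_bp(out.cohort, "SBP")
        mat = tw.beta_to_m(out.matrix)
        rows = tw.run_ewas(mat, coh, "SBP")
        top = rows.head(3)
        fits = tw.run_ice_falcon(mat, coh, "SBP", top, n_boot=50, seed=0)
        assert len(fits) == 6
        assert set(fits["direction"]) == {"meth_to_bp", "bp_to_meth"}

    def test_direction_asymmetry_recovered_on_bp_causal_data(self):
        """With a strong BP-to-methylation effect, the correctly oriented
        fit wins more causal verdicts than the reverse across seeds."""
        correct = wrong = 0
        for seed in range(1, 31):
            sc = tw.SimScenario(name="bp_causal", n_pairs=100, n_cpgs=20,
                                n_signal_cpgs=5, causal_effect=0.03, seed=seed)
            out = tw.simulate_twin_cohort(sc)
            coh = tw.derive_bp(out.cohort, "SBP")
            mat = tw.beta_to_m(out.matrix)
            locus = out.truth.index[out.truth["is_signal"]][0]
            rows = tw.run_ewas(mat, coh, "SBP")
            row = rows[(rows["chrom"] == locus[0]) & (rows["pos"] == locus[1])]
            fits = tw.run_ice_falcon(mat, coh, "SBP", row, n_boot=300,
                                     seed=seed)
            verdicts = dict(zip(fits["direction"], fits["verdict"]))
            correct += verdicts["bp_to_meth"] == "causal"
            wrong += verdicts["meth_to_bp"] == "causal"
        assert correct > wrong

    def test_null_rarely_yields_causal_verdicts(self):
        """Absent any methylation-BP link, causal verdicts stay near the
        bootstrap test's false-positive rate (both directions pooled)."""
        causal = total = 0
        for seed in range(12):
            sc = tw.SimScenario(name="null", n_pairs=100, n_cpgs=10, seed=seed)
            out = tw.simulate_twin_cohort(sc)
            coh = tw.derive_bp(out.cohort, "SBP")
            mat = tw.beta_to_m(out.matrix)
            rows = tw.run_ewas(mat, coh, "SBP")
            first_locus = rows.sort_values(["chrom", "pos"]).head(1)
            fits = tw.run_ice_falcon(mat, coh, "SBP", first_locus,
                                     n_boot=200, seed=seed)
            causal += (fits["verdict"] == "causal").sum()
            total += len(fits)
        assert causal / total <= 0.10 + 1e-9
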