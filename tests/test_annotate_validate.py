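"""Nearest-gene annotation, rank-sum/logistic validation, partial correlation."""
import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

import twinewas as tw
from twinewas.validation import logistic_assoc, wilcoxon_case_control

GENES = pd.DataFrame({
    "chrom": ["chr1", "chr1", "chr1", "chr2"],
    "start": [1000, 5000, 5500, 100],
    "end": [2000, 6000, 6500, 200],
    "strand": ["+", "-", "+", "+"],
    "symbol": ["A1", "B1", "B2", "C1"],
    "ensembl_id": ["ENSG1", "ENSG2", "ENSG3", "ENSG4"],
})


class TestNearestGene:
    def test_inside_single_gene_distance_zero(self):
        hits, d = tw.nearest_gene("chr1", 1500, GENES)
        assert hits == ["A1"] and d == 0

    def test_inside_two_overlapping_genes_returns_both(self):
        hits, d = tw.nearest_gene("chr1", 5800, GENES)
        assert hits == ["B1", "B2"] and d == 0

    def test_empty_chromosome_gives_no_gene(self):
        hits, d = tw.nearest_gene("chrX", 1234, GENES)
        assert hits == [] and np.isinf(d)

    def test_between_genes_picks_closer(self):
        hits, d = tw.nearest_gene("chr1", 2500, GENES)   # 500 from A1, 2500 from B1
        assert hits == ["A1"] and d == 500

    def test_invariant_to_gene_table_order(self):
        shuffled = GENES.sample(frac=1.0, random_state=3)
        assert tw.nearest_gene("chr1", 5800, shuffled) == \
            tw.nearest_gene("chr1", 5800, GENES)

    def test_bed_and_gff_round_trip(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("chr1\t999\t2000\tA1\t0\t+\n")      # 0-based half-open
        loaded = tw.read_gene_models(bed)
        assert loaded.loc[0, "start"] == 1000 and loaded.loc[0, "end"] == 2000
        gff = tmp_path / "genes.gff3"
        gff.write_text("##gff-version 3\n"
                       "chr1\tsrc\tgene\t1000\t2000\t.\t+\t.\t"
                       "ID=ENSG1;Name=A1;gene_id=ENSG1\n"
                       "chr1\tsrc\texon\t1000\t1200\t.\t+\t.\tID=e1\n")
        loaded = tw.read_gene_models(gff)
        assert len(loaded) == 1                            # exon rows ignored
        assert loaded.loc[0, "symbol"] == "A1"

    def test_annotate_ewas_fills_symbols(self):
        rows = pd.DataFrame({"chrom": ["chr1", "chr9"], "pos": [1500, 777]})
        out = tw.annotate_ewas(rows, GENES)
        assert list(out["gene_symbols"]) == ["A1", "NA"]


class TestWilcoxon:
    def test_identical_groups_p_one(self):
        assert wilcoxon_case_control([1, 2, 2], [2, 1, 2]) == 1.0

    def test_exact_matches_enumeration(self):
        """Separated groups of 3: exact two-sided p by full enumeration of
        all C(6,3)=20 label assignments of the pooled ranks."""
        case, control = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        p = wilcoxon_case_control(case, control)
        pooled = np.array(case + control)
        ranks = pooled.argsort().argsort() + 1
        observed = ranks[:3].sum()
        sums = [sum(c) for c in itertools.combinations(ranks, 3)]
        mean_sum = np.mean(sums)
        extreme = np.mean([abs(s - mean_sum) >= abs(observed - mean_sum) - 1e-9
                           for s in sums])
        assert p == pytest.approx(extreme)               # = 0.1 two-sided
        assert p == pytest.approx(0.1)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        assert wilcoxon_case_control(x, y) == pytest.approx(
            wilcoxon_case_control(np.exp(x), np.exp(y)))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_case_control([], [1.0])


class TestLogistic:
    def test_constant_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(0)
        meth = rng.uniform(0.2, 0.8, 200)
        status = rng.random(200) < 1 / (1 + np.exp(-(meth - 0.5) * 4))
        covs = pd.DataFrame({"bmi": np.full(200, 24.0)})
        with pytest.warns(UserWarning, match="constant"):
            beta, p, flag = logistic_assoc(meth, status, covs)
        assert np.isfinite(beta) and flag == ""

    def test_null_calibration(self):
        """Methylation independent of status: |beta| within 2 SE of zero in
        the large majority of replicates."""
        rng = np.random.default_rng(1)
        ok = 0
        for _ in range(60):
            meth = rng.uniform(0.2, 0.8, 300)
            status = rng.random(300) < 0.45
            beta, p, flag = logistic_assoc(meth, status)
            ok += p > 0.0455 or flag != ""       # |beta| <= 2 SE
        assert ok >= 52                          # >= ~87% at nominal 95.4%

    def test_log_odds_recovery(self):
        rng = np.random.default_rng(2)
        estimates = []
        for _ in range(50):
            meth = rng.normal(0.5, 0.15, 500)
            logit = 1.0 * (meth - 0.5) / 0.15        # log-OR 1 per SD unit
            status = rng.random(500) < 1 / (1 + np.exp(-logit))
            beta, _, _ = logistic_assoc((meth - 0.5) / 0.15, status)
            estimates.append(beta)
        assert abs(np.median(estimates) - 1.0) <= 0.3

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            logistic_assoc([0.1, 0.2], [True, True])

    def test_validate_cpgs_direction_and_shape(self):
        sc = tw.SimScenario(name="null", n_pairs=60, n_cpgs=20, seed=6)
        out = tw.simulate_twin_cohort(sc)
        res = tw.validate_cpgs(out.matrix, out.cohort,
                               loci=list(out.matrix.loci[:5]))
        assert len(res) == 5
        assert set(res["direction"]) <= {"hyper", "hypo", "NA"}


class TestPartialCorrelation:
    def _setup(self, seed=9):
        sc = tw.SimScenario(name="meth_causal", n_pairs=100, n_cpgs=20,
                            n_signal_cpgs=5, seed=seed)
        out = tw.simulate_twin_cohort(sc)
        coh = tw.derive_bp(out.cohort, "SBP")
        return coh, tw.beta_to_m(out.matrix), out

    def test_no_covariates_equals_pearson(self):
        coh, mat, out = self._setup()
        locus = out.truth.index[out.truth["is_signal"]][0]
        r0 = tw.intrapair_partial_correlation(coh, mat, loci=[locus],
                                              covariates=()).iloc[0]
        # plain Pearson of the differences
        t = coh.table
        ids1 = t.index[t["twin_index"] == 1]
        ids2 = t.index[t["twin_index"] == 2]
        m = mat.m_values.loc[locus]
        dm = m.loc[ids1].to_numpy() - m.loc[ids2].to_numpy()
        dbp = t.loc[ids1, "sbp"].to_numpy() - t.loc[ids2, "sbp"].to_numpy()
        assert r0 == pytest.approx(np.corrcoef(dm, dbp)[0, 1], abs=1e-12)

    def test_matches_pingouin_partial_corr(self):
        pingouin = pytest.importorskip("pingouin")
        coh, mat, out = self._setup()
        locus = out.truth.index[out.truth["is_signal"]][0]
        r = tw.intrapair_partial_correlation(coh, mat, loci=[locus]).iloc[0]
        t = coh.table
        ids1 = t.index[t["twin_index"] == 1]
        ids2 = t.index[t["twin_index"] == 2]
        m = mat.m_values.loc[locus]
        df = pd.DataFrame({
            "dm": m.loc[ids1].to_numpy() - m.loc[ids2].to_numpy(),
            "dbp": (t.loc[ids1, "sbp"].to_numpy()
                    - t.loc[ids2, "sbp"].to_numpy()),
            "age": t.loc[ids1, "age_years"].to_numpy(),
            "sex": (t.loc[ids1, "sex"] == "M").to_numpy(float),
        })
        ref = pingouin.partial_corr(df, x="dm", y="dbp", covar=["age", "sex"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)

    def test_antisymmetric_under_single_flip(self):
        coh, mat, out = self._setup()
        locus = out.truth.index[out.truth["is_signal"]][0]
        r = tw.intrapair_partial_correlation(coh, mat, loci=[locus]).iloc[0]
        flipped = coh.table.copy()
        flipped["twin_index"] = 3 - flipped["twin_index"]
        coh2 = tw.TwinCohort(flipped.reset_index())
        # flipping BOTH variables (the twin ordering) leaves r unchanged
        r2 = tw.intrapair_partial_correlation(coh2, mat, loci=[locus]).iloc[0]
        assert r2 == pytest.approx(r, abs=1e-12)
        # flipping only the BP ordering negates it
        t = coh.table.copy()
        swapped_bp = t["sbp"].copy()
        for _, g in t.groupby("pair_id"):
            i1, i2 = g.index[g["twin_index"] == 1][0], g.index[g["twin_index"] == 2][0]
            swapped_bp.loc[i1], swapped_bp.loc[i2] = t.loc[i2, "sbp"], t.loc[i1, "sbp"]
        coh3 = tw.TwinCohort(t.assign(sbp=swapped_bp).reset_index())
        r3 = tw.intrapair_partial_correlation(coh3, mat, loci=[locus]).iloc[0]
        assert r3 == pytest.approx(-r, abs=1e-12)

    def test_recovery_of_designed_correlation(self):
        from twinewas.simulate import expected_intrapair_partial_corr
        sc = tw.SimScenario(name="meth_causal", n_pairs=200, n_cpgs=20,
                            n_signal_cpgs=5, seed=14)
        target = expected_intrapair_partial_corr(sc)
        out = tw.simulate_twin_cohort(sc)
        coh = tw.derive_bp(out.cohort, "SBP")
        mat = tw.beta_to_m(out.matrix)
        sig = out.truth.index[out.truth["is_signal"]]
        r = tw.intrapair_partial_correlation(coh, mat, loci=list(sig))
        assert abs(r.abs().median() - target) <= 0.1

    def test_too_few_pairs_rejected(self, tiny_cohort):
        coh = tw.derive_bp(tiny_cohort, "SBP")
        ids = list(coh.individual_ids)
        from tests.conftest import make_matrix
        mat = tw.beta_to_m(make_matrix([np.linspace(0.3, 0.7, len(ids))], ids))
        with pytest.raises(ValueError, match="pairs"):
            tw.intrapair_partial_correlation(coh.subset_pairs(["p1", "p2", "p3"]),
                                             mat)
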