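"""QC a methylome, adjust for cell composition, and run the pair-clustered EWAS.

Prints the top associations with their robust p-values and significance
tiers; on this BP-responsive simulation the top hits should be true signal
CpGs.
"""
import twinewas as tw

out = tw.simulate_twin_cohort(
    tw.SimScenario(name="bp_causal", n_pairs=100, n_cpgs=2000, seed=7))
cohort = tw.derive_bp(out.cohort, "SBP")
cohort, _ = tw.select_discordant_pairs(cohort, "SBP")

matrix = out.matrix.subset_individuals(cohort.individual_ids)
matrix = tw.cap_coverage(matrix, quantile=0.9)
matrix, qc = tw.qc_filter_cpgs(matrix)
print(f"QC: kept {qc.n_cpgs_kept}/{qc.n_cpgs_in} CpGs "
      f"({qc.n_dropped_low_beta} low-beta, {qc.n_dropped_missing} gappy)")
matrix = tw.beta_to_m(matrix)

components = tw.refactor_components(matrix, k=5, t=500, d=5)
rows = tw.run_ewas(matrix, cohort, "SBP", components)

top = rows.head(8)[["chrom", "pos", "coefficient", "p_value", "fdr_q", "tier"]]
print(top.to_string(index=False))
truth = out.truth.loc[list(zip(top["chrom"], top["pos"]))]
print(f"true signal among the top 8: {int(truth['is_signal'].sum())}")
# coefficients are M-value units per mmHg; tiers follow FDR<0.05 (genomewide),
# p<1e-6 (suggestive), p<1e-5 (weaker-than-suggestive), p<1e-4 (top)
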