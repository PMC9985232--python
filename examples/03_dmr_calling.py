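"""Implant a differentially methylated region and recover it with comb-p
style region calling (ACF-weighted Stouffer-Liptak smoothing, peak finding,
SLK region p with Sidak correction)."""
import twinewas as tw

out = tw.simulate_twin_cohort(
    tw.SimScenario(name="null", n_pairs=60, n_cpgs=2000, seed=11))
cohort = tw.derive_bp(out.cohort, "SBP")

# ten probes, 30 bp apart, sharing a strong BP-linked methylation shift
matrix = tw.implant_dmr(out.matrix, cohort, chrom="chr1", start_bp=400_000,
                        n_probes=10, spacing_bp=30, effect=1.0, seed=11)
matrix, _ = tw.qc_filter_cpgs(matrix)
rows = tw.run_ewas(tw.beta_to_m(matrix), cohort, "SBP")

dmrs = tw.call_dmrs(rows)
print(dmrs[["chrom", "start", "end", "n_probes", "slk_p", "sidak_p",
            "significant"]].to_string(index=False))
# the implanted region spans chr1:400,000-400,270; the slk_p column is the
# correlation-aware Stouffer-Liptak combination of its probes' p-values and
# sidak_p corrects it for the number of same-sized regions the genome holds
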