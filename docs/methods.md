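# Methods

This note documents the statistical models behind each stage of the
pipeline, the assumptions of the synthetic twin-cohort generator, and the
numerical and design choices that were genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The discordant-MZ-twin design

Monozygotic co-twins share their genome and, to a large extent, their
rearing environment. Within a pair, methylation–trait associations are
therefore free of genetic and shared-environment confounding. The design's
power is governed by two quantities: the within-pair correlation of the
methylation background, ρ_ε (shared genetic/environmental influence on
methylation), and the magnitude of trait discordance available within
pairs. Pairs are included when the intra-pair blood-pressure difference
reaches 2 mmHg (SBP) or 1 mmHg (DBP), boundary inclusive.

## Phenotype preparation

Each individual contributes three repeated sphygmomanometer readings per
trait; the derived value is their arithmetic mean. The outlier rule is
applied to the derived means across the cohort: values beyond mean ± 3 SD
become missing. We chose the derived scale (rather than per-reading)
because averaging precedes analysis and a single discrepant reading should
not void an individual. A missing derived value excludes the whole pair
from that trait's analysis — the pairwise design needs both members.

## Methylation QC and the M-value scale

Coverage capping is per sample at that sample's 90th percentile (the
convention of smoothing-based RRBS pipelines; a global quantile is a
configuration switch away). CpGs are dropped when their mean β over
non-missing entries is below 0.01 or when more than 10 observations are
missing; both rules are boundary-exact, the missing rule strict.

Analysis happens on M-values, M = log₂(β/(1−β)) — the variance-stabilizing
logit₂ scale. A bare log₂(β) would map fully methylated sites to 0 and is
not an M-value. β is clipped to [0.001, 0.999] (configurable) before the
transform so boundary values keep finite M.

## Reference-free cell-type components

Whole-blood methylation is a mixture over cell types, and composition can
correlate with the trait; unadjusted, this inflates the null. With k
assumed cell types, t retained sites and d returned components (defaults
k = d = 5, t = 500): standardize each site, form the rank-k SVD
reconstruction, score sites by reconstruction distance, keep the t best
(ties resolved to the lowest genomic coordinate after quantizing distances
at 1e-9, making the exact-low-rank case deterministic), and return the
first d principal-component scores of the retained sub-matrix. Missing
entries are mean-imputed per site inside this operation only.

Components are computed once on the analyzed individuals, not per-trait
subsamples. A caution demonstrated by the test suite: when a large
fraction of CpGs shares one strong trait-linked factor, a reference-free
method will absorb part of that factor. At realistic per-site effect
shares (a few percent of site variance) the selection step prefers genuine
cell-structure sites and the trait signal survives adjustment.

## Pair-clustered GEE association

Per CpG we fit the marginal Gaussian model
`M ~ BP + age + sex + PC1..PCd` by generalized estimating equations with
an exchangeable working correlation within twin pairs (independence
available). Methylation is the outcome because the adjusted covariates —
cell composition above all — confound methylation; the reverse orientation
(`BP ~ M + ...`) is a configuration switch, and printed coefficients of
similar studies (~0.01 M per mmHg) read the same either way.

Inference is by the cluster sandwich with Wald (normal) p-values; with
~60–100 clusters the normal/t distinction is negligible. The **default
covariance is the Mancl–DeRouen bias-reduced sandwich**: the plain
sandwich uses fitted residuals, which are shrunk at high-leverage
clusters, and with a cluster-correlated regressor and outcome this
produces genuine miscalibration at this design size (the test suite
measures genomic inflation ~1.18 plain vs ~1.04 bias-reduced on a null
methylome of 2,000 CpGs × 100 pairs). The plain sandwich remains available
(`cov_type="robust"`).

The genome-wide map is solved by a vectorized pair-cluster GEE: with
methylation as the outcome the design matrix is shared across CpGs, and
the exchangeable 2×2 working blocks reduce the weighted cross-products to
two shared Gram matrices, so all CpGs are iterated simultaneously. The
solver replicates statsmodels' estimating equations, moment estimator and
both covariance estimators; the test suite asserts agreement to ~1e-8.
CpGs with missing values fall back to a per-CpG fit with pairwise deletion
(the co-twin of a missing individual is removed too); CpGs with fewer than
10 complete pairs, or singular designs, yield flagged rows rather than
exceptions.

Multiple testing uses Benjamini–Hochberg q-values; tiers are mutually
exclusive, first match wins: genome-wide (q < 0.05), suggestive
(p < 1e−6), weaker-than-suggestive (1e−6 ≤ p < 1e−5), top (p < 1e−4),
else non-significant.

## Region detection (comb-p machinery)

1. **ACF** — for distance bins of 50 bp out to 500 bp, the Pearson
   correlation of probit-transformed p-values, z = Φ⁻¹(1−p), over all
   same-chromosome probe pairs in the bin; empty bins and negative
   estimates contribute zero correlation to the weighting.
2. **Smoothing** — each probe is replaced by the Stouffer–Liptak
   combination of probes within ±200 bp, z_c = Σz / √(1ᵀΣ1), Σ from the
   ACF at pairwise distances (diagonal 1). If flooring breaks positive
   semidefiniteness, Σ is repaired by eigenvalue clipping with diagonal
   renormalization (logged).
3. **Seeding** — maximal runs of probes with smoothed p below `seed_p`
   and inter-probe gaps ≤ 200 bp; singletons are discarded.
4. **Scoring** — the region's `slk_p` combines the members' *original*
   p-values under Σ; `sidak_p = 1 − (1 − slk_p)^(covered/region_len)`
   corrects for the number of same-length regions the covered genome
   (one base per probe) could host, floored at exponent 1 so
   `sidak_p ≥ slk_p` always.

Two defaults differ from common comb-p practice, for calibration reasons
established analytically and by simulation in the test suite. First, the
**`significant` flag uses the Šidák-corrected p** (< 0.05): the raw SLK p
of a seed-selected region is conditioned on small p-values by the seeding
step and is not uniform under the null. Second, **`seed_p` defaults to
1e-4**: for point probes, two-probe candidate regions are so short that
the length-based Šidák exponent under-counts the genome's capacity for
them, and any seed threshold ≳1e-3 admits about one false significant
region per 5,000-probe genome; at 1e-4 the uniform-null false-region rate
is ~0.05 per genome while a strongly shifted 10-probe region is still
recovered essentially always. Both parameters are configurable.

## ICE FALCON causal inference

For exposure x and outcome y over pairs, three pair-clustered GEE models:

* M1: y_self ~ x_self (+ covariates) → β_self
* M2: y_self ~ x_cotwin (+ covariates) → β_co-twin
* M3: y_self ~ x_self + x_cotwin (+ covariates) → β′_self, β′_co-twin

Each twin serves once as "self", giving two rows per pair with the pair as
the GEE cluster. β_co-twin captures only the familial share of the
association; if conditioning on x_self collapses it
(|β_co-twin − β′_co-twin| more than 1.5× |β_self − β′_self|, with the
co-twin change significant) the association is causal in the modeled
direction; similar changes indicate familial confounding; otherwise the
fit is inconclusive and the ratio is reported as undefined (the "–"
convention). The ratio is only reported when the co-twin change is
significant at 0.05 — reconstructed from the printing convention of
published twin analyses, where every undefined ratio coincides with a
non-significant co-twin change.

Coefficient-change p-values come from a pair-level nonparametric bootstrap
(default B = 1000; the simulation studies use B = 300–500): resample pairs
with replacement, refit the three models, and take a two-sided normal
p-value from the bootstrap SE of each change. A degenerate bootstrap
(zero variance) yields an inconclusive verdict with a diagnostic.
Covariates are age and sex, plus the cell components when methylation is
the outcome (they confound methylation, not BP). Methylation enters as
M-value, blood pressure in mmHg, so meth→BP changes are mmHg per M-unit
and the reverse M-units per mmHg.

Properties the test suite verifies: the ratio equals the quotient of the
stored coefficient changes to 1e-12; verdicts are invariant to affine
rescaling of x and y and to swapping twin labels; under a global null,
causal verdicts occur at about the bootstrap test's false-positive rate.

Two behaviors worth knowing. Direction discrimination requires the
exposure to carry familial correlation — with an exposure that is nearly
independent within pairs the co-twin proxy is uninformative, and with very
strong familial noise on the outcome the bootstrap loses power in both
directions. And selecting the test CpG by its EWAS rank induces
winner's-curse asymmetry in the coefficient changes; the calibration
studies therefore evaluate truth-designated CpGs, while real analyses of
top CpGs (the published protocol) should read borderline ratios
cautiously.

## Synthetic cohort generator

The generator encodes the structure the analysis assumes; its defaults are
the study conditions of the calibration suite.

* **Familial factor.** Each pair draws F ~ N(0,1), a single latent
  standing in for genetic plus shared-environment influence.
* **Signal score.** D = λ_m F + √(1−λ_m²) u per individual, with
  λ_m = √ρ_ε so corr(D₁, D₂) = ρ_ε. Default ρ_ε = 0.8, the favorable end
  of the discordant-twin power range and appropriate for MZ methylation.
* **Blood pressure.** SBP = 130 + 0.25(age−52) + 4·male + λ_bp F +
  coupling·(w₁−E[w₁]) + ε, ε ~ N(0, 18.4²), so the median intra-pair
  |ΔSBP| sits near 18 mmHg (familial terms cancel in pair differences).
  λ_bp resolves per scenario: 22.5 mmHg/SD for `confounded`/`null`
  (implying an MZ BP correlation near the trait's heritability, ~0.6) and
  8.0 for the causal scenarios, which model causation-dominated
  associations. Three readings per trait add N(0, 3²) measurement noise;
  DBP tracks SBP with its own noise. BMI, triglycerides and fasting
  glucose are familially correlated fillers; case status is
  SBP ≥ 140 and DBP ≥ 90 on derived means.
* **Scenarios.** `meth_causal` adds c·D to BP (default c = 25 mmHg per
  M-unit — strong relative to the 18.4 mmHg noise, as a causal-recovery
  study requires); `bp_causal` adds c·BP (default c = 0.01 M/mmHg,
  matching printed top-CpG coefficients) to each responsive CpG
  *conditionally independently given BP* — a shared latent across
  responsive CpGs would be a low-rank structure that the reference-free
  adjustment absorbs; `confounded` wires both loadings with c = 0;
  `null` carries no signal at all.
* **Methylome.** Baselines are bimodal (Beta(0.4, 0.4)) except at signal
  CpGs, which draw intermediate baselines (Beta(5, 5)) — trait-variable
  methylation lives away from 0/1, where the logistic squash would
  otherwise destroy an M-scale effect. Cell structure: Dirichlet fractions
  (α = (5, 3, 1.5, 1, 0.5), neutrophil-like dominance) times N(0, 3²)
  cell-type profiles at 30% of CpGs, in M space; the first fraction also
  couples to BP (30 mmHg per unit deviation) so omitting the components
  genuinely inflates the null. Every CpG adds pair-correlated background
  (SD 0.5 M, correlation ρ_ε). Observation: β = logistic₂(M) plus
  truncated-Gaussian noise (SD 0.02, ±2.5 SD), clipped to (0.001, 0.999).
  Coverage is Poisson with per-sample depth and per-site propensity.
* **Determinism.** One integer seed; all substreams spawn from it.

What the generator does **not** emulate: read-level RRBS artifacts
(bisulfite conversion, strand effects), realistic CpG-island spacing
(gaps are exponential, mean 500 bp on one chromosome), genomic missingness
patterns (a uniform missing-rate knob exists but claims no realism), age
trends in methylation, and probe-level annotation biology. Passing
calibration here shows the *statistics* behave as designed, not that real
RRBS data will be as clean.

`implant_dmr` inserts a run of consecutive probes sharing a BP-linked
shift (`effect` in M-units per BP SD) plus a regional latent (half
familial) that correlates neighbouring probes; it refuses overlaps with
previously implanted regions and position collisions.

## Problem sizes of the bundled studies

The calibration studies run at desk scale by design: 2,000 CpGs × 100
pairs for EWAS calibration and FDR control (50 replicates), 20–50 CpGs per
replicate for ICE FALCON studies (50 replicates, B = 300–500 bootstrap),
5,000-probe genomes for DMR null calibration (20 replicates). These sizes
put every study within minutes on one CPU while leaving Monte-Carlo error
well inside the asserted tolerances.

## Known limitations

* The Gaussian GEE treats BP as continuous and homoscedastic; no
  binary-trait (hypertension) EWAS route is provided.
* The DMR Šidák correction treats probes as 1-bp intervals; array-style
  probe footprints would need a different covered-bases count.
* ICE FALCON inference is bootstrap-only; the analytic (delta-method)
  alternative is not implemented, so change p-values on tiny samples
  inherit bootstrap granularity.
* The nearest-gene annotator imposes no search radius and reports all
  tied genes; it does not model strand-aware promoter distance.
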