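"""Synthetic discordant MZ twin cohorts with cell-type-mixed methylomes.

The generator realizes the statistical structure the analysis assumes:

* each pair ``i`` shares a standard-normal familial factor ``F_i`` that
  stands in for both genetic and shared-environment influences;
* a per-individual latent *signal score* ``D_ij = λ_m F_i + √(1−λ_m²) u_ij``
  has within-pair correlation ``λ_m² = intra_pair_rho`` (the ρ_ε of
  discordant-twin power calculations);
* blood pressure combines age/sex effects, a familial loading, independent
  noise sized so the median intra-pair |ΔSBP| sits near 18 mmHg, and — in
  the ``meth_causal`` scenario — a causal contribution of the signal score;
* observed β-values arise from a Dirichlet-weighted mixture over cell-type
  specific methylomes (in M space), squashed through the logistic and
  perturbed with truncated-Gaussian noise, then clipped to (0.001, 0.999);
* scenarios: ``null`` (no signal), ``meth_causal`` (M → BP),
  ``bp_causal`` (BP → M), ``confounded`` (familial path only).

Everything is deterministic given the scenario seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import TwinCohort
from .methylation import CpgMatrix

SCENARIOS = ("null", "meth_causal", "bp_causal", "confounded")

#: default causal effect by scenario: mmHg per M-unit for meth_causal,
#: M-units per mmHg for bp_causal (strong, clearly detectable at 100 pairs)
DEFAULT_CAUSAL_EFFECT = {"null": 0.0, "meth_causal": 25.0, "bp_causal": 0.01,
                         "confounded": 0.0}

#: default familial loading of blood pressure (mmHg per familial-factor SD).
#: The confounded and null scenarios use the value implied by an MZ
#: within-pair BP correlation near the trait's heritability (~0.6 given
#: the 18.4 mmHg residual); the causal scenarios represent
#: causation-dominated associations, with a weaker familial BP path.
DEFAULT_FAMILIAL_LOAD_BP = {"null": 22.5, "confounded": 22.5,
                            "meth_causal": 8.0, "bp_causal": 8.0}


def sigmoid2(m: np.ndarray) -> np.ndarray:
    """Inverse of the logit2 M-value transform: β = 2^M / (1 + 2^M)."""
    return 1.0 / (1.0 + np.exp2(-m))


@dataclass(frozen=True)
class SimScenario:
    """Study conditions for one simulated twin cohort."""

    name: str = "null"
    n_pairs: int = 60
    n_cpgs: int = 2000
    n_signal_cpgs: int | None = None          # default: 10% of n_cpgs
    causal_effect: float | None = None        # resolved per scenario when None
    familial_load_m: float | None = None      # default sqrt(intra_pair_rho)
    familial_load_bp: float | None = None     # mmHg per familial-factor SD
    intra_pair_rho: float = 0.8               # within-pair corr of the signal score
    n_cell_types: int = 5
    dirichlet_alpha: tuple[float, ...] = (5.0, 3.0, 1.5, 1.0, 0.5)
    cell_bp_coupling: float = 30.0            # mmHg per unit dev. of 1st cell fraction
    bp_noise_sd: float = 18.4                 # tuned so median |dSBP| ~ 18 mmHg
    reading_noise_sd: float = 3.0             # per-measurement sphygmomanometer noise
    background_m_sd: float = 0.5              # per-CpG biological variation (M units)
    signal_cpg_noise_sd: float = 0.3          # extra CpG-level noise on signal CpGs
    cell_profile_sd: float = 3.0              # cell-type profile spread (M units)
    cell_informative_frac: float = 0.3        # CpGs carrying cell-type structure
    beta_noise_sd: float = 0.02               # truncated-Gaussian noise on beta
    missing_rate: float = 0.0
    mean_spacing_bp: float = 500.0
    include_coverage: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}; expected {SCENARIOS}")
        for fname in ("n_pairs", "n_cpgs", "n_cell_types"):
            if getattr(self, fname) <= 0:
                raise ValueError(f"{fname} must be positive")
        if self.n_signal_cpgs is not None and not 0 <= self.n_signal_cpgs <= self.n_cpgs:
            raise ValueError("n_signal_cpgs must lie in [0, n_cpgs]")
        if not 0.0 <= self.intra_pair_rho < 1.0:
            raise ValueError("intra_pair_rho must lie in [0, 1)")
        if len(self.dirichlet_alpha) != self.n_cell_types:
            raise ValueError("dirichlet_alpha length must equal n_cell_types")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ValueError("dirichlet_alpha entries must be positive")
        for fname in ("familial_load_m", "familial_load_bp", "causal_effect"):
            v = getattr(self, fname)
            if v is not None and not np.isfinite(v):
                raise ValueError(f"{fname} must be finite")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def resolved_n_signal_cpgs(self) -> int:
        if self.n_signal_cpgs is not None:
            return int(self.n_signal_cpgs)
        return self.n_cpgs // 10

    @property
    def resolved_causal_effect(self) -> float:
        if self.causal_effect is not None:
            return float(self.causal_effect)
        return DEFAULT_CAUSAL_EFFECT[self.name]

    @property
    def resolved_familial_load_bp(self) -> float:
        if self.familial_load_bp is not None:
            return float(self.familial_load_bp)
        return DEFAULT_FAMILIAL_LOAD_BP[self.name]

    @property
    def resolved_familial_load_m(self) -> float:
        if self.familial_load_m is not None:
            return float(self.familial_load_m)
        return float(np.sqrt(self.intra_pair_rho))

    def replace(self, **kw) -> "SimScenario":
        return replace(self, **kw)


@dataclass
class SimOutput:
    matrix: CpgMatrix
    cohort: TwinCohort
    truth: pd.DataFrame                 # per-CpG: is_signal, true_effect, true_direction
    cell_fractions: pd.DataFrame        # individuals × cell types, rows on the simplex
    signal_score: pd.Series = field(default=None)  # latent D per individual
    latent_m: pd.DataFrame | None = None           # pre-squash M (CpGs × individuals)


def expected_intrapair_partial_corr(scenario: SimScenario) -> float:
    """Analytic corr(ΔM, ΔBP) at a signal CpG under ``meth_causal``.

    Pair differencing removes the familial factor, so
    ΔM = ΔD + Δe + Δbg and ΔBP = c·ΔD + Δε with Var(ΔD) = 2(1 − ρ),
    Var(Δe) = 2σ_e², Var(Δbg) = 2(1 − ρ)σ_bg² (the background's familial
    share cancels too), Var(Δε) = 2σ_ε² + 2σ_r²/3 from reading noise.
    β-space squashing attenuates this slightly; it is a design target,
    not an exact observable.
    """
    c = scenario.resolved_causal_effect
    vdd = 2.0 * (1.0 - scenario.intra_pair_rho)
    vde = (2.0 * scenario.signal_cpg_noise_sd**2
           + 2.0 * (1.0 - scenario.intra_pair_rho) * scenario.background_m_sd**2)
    vdeps = 2.0 * scenario.bp_noise_sd**2 + 2.0 * scenario.reading_noise_sd**2 / 3.0
    return c * vdd / np.sqrt((vdd + vde) * (c**2 * vdd + vdeps))


def simulate_twin_cohort(scenario: SimScenario) -> SimOutput:
    """Generate one cohort + methylome under the scenario's causal structure."""
    s = scenario
    root = np.random.SeedSequence(s.seed)
    streams = [np.random.default_rng(ss) for ss in root.spawn(8)]
    rng_pheno, rng_cells, rng_profiles, rng_meth, rng_noise, rng_miss, rng_cov, rng_loci = streams

    n_pairs, n_ind = s.n_pairs, 2 * s.n_pairs
    pair_ids = np.repeat([f"pair{i:04d}" for i in range(n_pairs)], 2)
    twin_index = np.tile([1, 2], n_pairs)
    ind_ids = [f"{p}_t{t}" for p, t in zip(pair_ids, twin_index)]

    # --- familial factor and signal score --------------------------------
    F_pair = rng_pheno.standard_normal(n_pairs)
    F = np.repeat(F_pair, 2)
    lam_m = s.resolved_familial_load_m
    u = rng_pheno.standard_normal(n_ind)
    D = lam_m * F + np.sqrt(max(0.0, 1.0 - lam_m**2)) * u

    # --- demographics -----------------------------------------------------
    age = np.repeat(np.clip(rng_pheno.normal(52.0, 6.6, n_pairs), 30, 80), 2)
    male = np.repeat(rng_pheno.random(n_pairs) < 0.5, 2)
    sex = np.where(male, "M", "F")

    # --- cell-type composition -------------------------------------------
    W = rng_cells.dirichlet(s.dirichlet_alpha, size=n_ind)          # (n, T)
    w1_dev = W[:, 0] - s.dirichlet_alpha[0] / sum(s.dirichlet_alpha)

    # --- blood pressure ---------------------------------------------------
    c = s.resolved_causal_effect
    eps = rng_pheno.normal(0.0, s.bp_noise_sd, n_ind)
    sbp_true = (130.0 + 0.25 * (age - 52.0) + 4.0 * male
                + s.resolved_familial_load_bp * F + s.cell_bp_coupling * w1_dev + eps)
    if s.name == "meth_causal":
        sbp_true = sbp_true + c * D
    dbp_true = 80.0 + 0.4 * (sbp_true - 130.0) + rng_pheno.normal(0.0, 6.0, n_ind)
    readings = {}
    for prefix, true in (("sbp", sbp_true), ("dbp", dbp_true)):
        for r in (1, 2, 3):
            readings[f"{prefix}{r}"] = true + rng_pheno.normal(0.0, s.reading_noise_sd, n_ind)

    bmi = 24.0 + 1.2 * F + rng_pheno.normal(0.0, 2.5, n_ind)
    tg = np.exp(rng_pheno.normal(np.log(1.4), 0.4, n_ind))
    fbg = 5.2 + 0.3 * F + rng_pheno.normal(0.0, 0.6, n_ind)
    sbp_mean = np.mean([readings[f"sbp{r}"] for r in (1, 2, 3)], axis=0)
    dbp_mean = np.mean([readings[f"dbp{r}"] for r in (1, 2, 3)], axis=0)
    case_status = (sbp_mean >= 140.0) & (dbp_mean >= 90.0)

    cohort = TwinCohort(pd.DataFrame({
        "individual_id": ind_ids,
        "pair_id": pair_ids,
        "twin_index": twin_index,
        "sex": sex,
        "age_years": np.round(age, 1),
        **readings,
        "bmi": bmi,
        "tg": tg,
        "fbg": fbg,
        "case_status": case_status,
    }))

    # --- genomic loci -----------------------------------------------------
    gaps = np.maximum(2, np.round(rng_loci.exponential(s.mean_spacing_bp, s.n_cpgs))).astype(np.int64)
    pos = 10_000 + np.cumsum(gaps)
    loci = pd.MultiIndex.from_arrays([np.repeat("chr1", s.n_cpgs), pos],
                                     names=["chrom", "pos"])

    # --- latent methylation (M space) ------------------------------------
    # bulk CpGs are bimodal (near 0 or 1); signal CpGs get intermediate
    # baselines below, where methylation can actually vary with the trait
    base_beta = np.clip(rng_profiles.beta(0.4, 0.4, s.n_cpgs), 0.03, 0.97)

    informative = rng_profiles.random(s.n_cpgs) < s.cell_informative_frac
    L = np.zeros((s.n_cell_types, s.n_cpgs))
    L[:, informative] = rng_profiles.normal(
        0.0, s.cell_profile_sd, (s.n_cell_types, int(informative.sum())))
    cell_dev = W @ L                                                 # (n, C)
    cell_dev -= cell_dev.mean(axis=0, keepdims=True)

    is_signal = np.zeros(s.n_cpgs, dtype=bool)
    true_effect = np.zeros(s.n_cpgs)
    direction = np.full(s.n_cpgs, "none", dtype=object)
    sig_idx = np.empty(0, dtype=int)
    n_signal = s.resolved_n_signal_cpgs
    if s.name != "null" and n_signal > 0:
        sig_idx = rng_meth.choice(s.n_cpgs, n_signal, replace=False)
        sig_idx.sort()
        is_signal[sig_idx] = True
        # variably-methylated baselines keep the logistic squash near its
        # linear range, so the M-scale effect survives observation
        base_beta[sig_idx] = rng_meth.beta(5.0, 5.0, n_signal)
    mu_m = np.log2(base_beta / (1.0 - base_beta))                    # (C,)

    g_pair = rng_meth.standard_normal((n_pairs, s.n_cpgs))
    h_ind = rng_meth.standard_normal((n_ind, s.n_cpgs))
    sr = np.sqrt(s.intra_pair_rho)
    background = s.background_m_sd * (sr * np.repeat(g_pair, 2, axis=0)
                                      + np.sqrt(1.0 - s.intra_pair_rho) * h_ind)

    M = mu_m[None, :] + cell_dev + background                        # (n, C)

    if len(sig_idx):
        e_sig = rng_meth.normal(0.0, s.signal_cpg_noise_sd, (n_ind, n_signal))
        if s.name in ("meth_causal", "confounded"):
            M[:, sig_idx] += D[:, None] + e_sig
            true_effect[sig_idx] = c if s.name == "meth_causal" else 0.0
            direction[sig_idx] = "meth_to_bp" if s.name == "meth_causal" else "confounded"
        else:  # bp_causal: methylation responds to realized blood pressure.
            # No shared latent here: each responsive CpG is conditionally
            # independent given BP (its twin correlation comes from the
            # per-CpG familial background), so the trait signal is not a
            # low-rank structure the cell-composition step could absorb.
            bp_centered = sbp_true - sbp_true.mean()
            M[:, sig_idx] += c * bp_centered[:, None] + e_sig
            true_effect[sig_idx] = c
            direction[sig_idx] = "bp_to_meth"

    # --- observe: squash, add bounded noise, clip ------------------------
    beta = sigmoid2(M)
    noise = np.clip(rng_noise.normal(0.0, s.beta_noise_sd, beta.shape),
                    -2.5 * s.beta_noise_sd, 2.5 * s.beta_noise_sd)
    beta = np.clip(beta + noise, 0.001, 0.999)
    if s.missing_rate > 0:
        beta[rng_miss.random(beta.shape) < s.missing_rate] = np.nan

    beta_df = pd.DataFrame(beta.T, index=loci, columns=ind_ids)
    coverage = None
    if s.include_coverage:
        depth = rng_cov.uniform(20.0, 50.0, n_ind)                  # per-sample depth
        site_factor = rng_cov.gamma(2.0, 0.5, s.n_cpgs)             # per-site propensity
        lam = np.outer(site_factor, depth)                          # (C, n)
        coverage = pd.DataFrame(
            np.maximum(1, rng_cov.poisson(lam)), index=loci, columns=ind_ids)

    matrix = CpgMatrix(beta_df, coverage=coverage)
    truth = pd.DataFrame(
        {"is_signal": is_signal, "true_effect": true_effect,
         "true_direction": direction},
        index=loci,
    )
    return SimOutput(
        matrix=matrix,
        cohort=cohort,
        truth=truth,
        cell_fractions=pd.DataFrame(
            W, index=pd.Index(ind_ids, name="individual_id"),
            columns=[f"cell{t+1}" for t in range(s.n_cell_types)]),
        signal_score=pd.Series(D, index=pd.Index(ind_ids, name="individual_id"),
                               name="signal_score"),
        latent_m=pd.DataFrame(M.T, index=loci, columns=ind_ids),
    )


def implant_dmr(
    matrix: CpgMatrix,
    cohort: TwinCohort,
    chrom: str,
    start_bp: int,
    n_probes: int,
    spacing_bp: int,
    effect: float,
    trait: str = "SBP",
    region_latent_sd: float = 0.5,
    probe_noise_sd: float = 0.3,
    beta_noise_sd: float = 0.02,
    seed: int = 0,
) -> CpgMatrix:
    """Insert a run of BP-associated, mutually correlated probes.

    ``n_probes`` consecutive CpGs spaced ``spacing_bp`` apart at
    ``chrom:start_bp`` receive a shared methylation shift of ``effect``
    M-units per SD of the trait, plus a shared per-individual regional
    latent term (half familial) that correlates neighbouring probes.
    With ``effect=0`` existing probes are untouched and the inserted run
    carries no BP association.
    """
    if n_probes < 1 or spacing_bp < 1 or start_bp < 1:
        raise ValueError("n_probes, spacing_bp and start_bp must be positive")
    end_bp = start_bp + spacing_bp * (n_probes - 1)
    for (rc, rs, re) in matrix.implanted_regions:
        if rc == chrom and start_bp <= re and end_bp >= rs:
            raise ValueError(
                f"requested region {chrom}:{start_bp}-{end_bp} overlaps an "
                f"existing implanted region {rc}:{rs}-{re}")

    from .cohort import reading_columns
    ids = list(matrix.individual_ids)
    table = cohort.table.loc[ids]
    bp = table[reading_columns(trait)].mean(axis=1).to_numpy()
    z = (bp - bp.mean()) / bp.std(ddof=0)
    pair_codes = pd.factorize(table["pair_id"])[0]
    n_pairs = pair_codes.max() + 1

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    g_pair = rng.standard_normal(n_pairs)[pair_codes]
    h_ind = rng.standard_normal(len(ids))
    regional = region_latent_sd * np.sqrt(0.5) * (g_pair + h_ind)

    positions = start_bp + spacing_bp * np.arange(n_probes, dtype=np.int64)
    new_loci = pd.MultiIndex.from_arrays(
        [np.repeat(str(chrom), n_probes), positions], names=["chrom", "pos"])
    if len(matrix.beta.index.intersection(new_loci)):
        raise ValueError("implanted probe positions collide with existing CpGs")

    M_new = (effect * z[:, None]
             + regional[:, None]
             + rng.normal(0.0, probe_noise_sd, (len(ids), n_probes)))
    beta_new = sigmoid2(M_new)
    noise = np.clip(rng.normal(0.0, beta_noise_sd, beta_new.shape),
                    -2.5 * beta_noise_sd, 2.5 * beta_noise_sd)
    beta_new = np.clip(beta_new + noise, 0.001, 0.999)
    new_rows = pd.DataFrame(beta_new.T, index=new_loci, columns=ids)

    beta_all = pd.concat([matrix.beta, new_rows])
    coverage = None
    if matrix.coverage is not None:
        cov_new = pd.DataFrame(
            np.maximum(1, rng.poisson(30.0, (n_probes, len(ids)))),
            index=new_loci, columns=ids)
        coverage = pd.concat([matrix.coverage, cov_new])
    return CpgMatrix(
        beta_all, coverage=coverage,
        implanted_regions=matrix.implanted_regions + [(str(chrom), int(start_bp), int(end_bp))],
    )


def write_simulation(out: SimOutput, outdir, prefix: str = "sim") -> dict:
    """Write the pipeline's standard input files (TSV/CSV) plus truth."""
    from pathlib import Path

    from .methylation import write_methylation_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "methylation": outdir / f"{prefix}_methylation.tsv",
        "coverage": outdir / f"{prefix}_coverage.tsv",
        "phenotypes": outdir / f"{prefix}_phenotypes.csv",
        "truth": outdir / f"{prefix}_truth.tsv",
        "cell_fractions": outdir / f"{prefix}_cell_fractions.csv",
    }
    write_methylation_tsv(out.matrix, paths["methylation"],
                          coverage_path=paths["coverage"] if out.matrix.coverage is not None else None)
    if out.matrix.coverage is None:
        paths.pop("coverage")
    out.cohort.to_csv(paths["phenotypes"])
    out.truth.reset_index().to_csv(paths["truth"], sep="\t", index=False)
    out.cell_fractions.reset_index().to_csv(paths["cell_fractions"], index=False)
    return {k: str(v) for k, v in paths.items()}
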