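"""Per-CpG EWAS: pair-clustered GEE, BH FDR, and significance tiers.

Each CpG's M-value is regressed on blood pressure with age, sex and the
cell-composition components as covariates, in a marginal (GEE) linear
model whose working correlation is exchangeable within twin pairs and
whose inference uses cluster-robust sandwich standard errors — twins are
correlated observations, not independent ones.

Significance tiers follow the usual discordant-twin EWAS convention:
``genomewide`` when BH FDR q < 0.05; otherwise ``suggestive`` when
p < 1e-6; ``weaker_than_suggestive`` when 1e-6 ≤ p < 1e-5; ``top`` when
p < 1e-4; else ``ns``.  First match wins, so the tiers are mutually
exclusive.

The default model orientation regresses M on BP ("m_on_bp"): the adjusted
covariates (cell composition) confound methylation, which reads naturally
with methylation as the outcome.  The reverse orientation ("bp_on_m") is
available as a switch.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cellmix import CellComponents
from .cohort import TwinCohort, derived_column
from .gee import batch_paired_gee, fit_paired_gee
from .methylation import CpgMatrix

logger = logging.getLogger(__name__)

TIER_ORDER = ("genomewide", "suggestive", "weaker_than_suggestive", "top", "ns")

#: tier thresholds: FDR for genome-wide, raw p for the rest
FDR_GENOMEWIDE = 0.05
P_SUGGESTIVE = 1e-6
P_WEAKER = 1e-5
P_TOP = 1e-4


@dataclass
class EwasDesign:
    """Aligned design pieces shared by every CpG fit."""

    X: np.ndarray                # (n, p): intercept, bp, age, sex, components...
    bp: np.ndarray               # trait values per individual (mmHg)
    clusters: np.ndarray         # pair codes per individual
    individual_ids: list[str]
    columns: list[str]


def build_design(
    cohort: TwinCohort,
    trait: str,
    components: CellComponents | None = None,
    individual_ids=None,
) -> EwasDesign:
    """Assemble the shared covariate design aligned to the given individuals."""
    col = derived_column(trait)
    if col not in cohort.table.columns:
        raise ValueError(f"derived {trait} missing; run preprocess.derive_bp first")
    ids = list(individual_ids) if individual_ids is not None else list(cohort.individual_ids)
    table = cohort.table.loc[ids]
    if table[col].isna().any():
        raise ValueError("individuals with missing derived BP in design; "
                         "select discordant pairs first")
    cols = {"intercept": np.ones(len(ids)), "bp": table[col].to_numpy(float)}
    cols["age"] = table["age_years"].to_numpy(float)
    cols["sex_male"] = (table["sex"].astype(str).str.upper() == "M").to_numpy(float)
    if components is not None:
        comp = components.components.loc[ids]
        for name in comp.columns:
            cols[name] = comp[name].to_numpy(float)
    X = np.column_stack(list(cols.values()))
    clusters = pd.factorize(table["pair_id"])[0]
    return EwasDesign(X=X, bp=cols["bp"], clusters=clusters,
                      individual_ids=ids, columns=list(cols))


def _complete_bp_pairs(cohort: TwinCohort, trait: str) -> TwinCohort:
    """Drop pairs where either co-twin lacks a derived BP value."""
    col = derived_column(trait)
    if col not in cohort.table.columns:
        raise ValueError(f"derived {trait} missing; run preprocess.derive_bp first")
    t1, t2 = cohort.pair_rows()
    ok = t1[col].notna() & t2[col].notna()
    if ok.all():
        return cohort
    return cohort.subset_pairs(t1.index[ok])


def fit_gee_cpg(
    m: pd.Series,
    cohort: TwinCohort,
    trait: str = "SBP",
    components: CellComponents | None = None,
    orientation: str = "m_on_bp",
    working: str = "exchangeable",
    cov_type: str = "bias_reduced",
    min_pairs: int = 10,
) -> tuple[float, float, float]:
    """Fit one CpG's marginal association; returns (coefficient, robust SE, p).

    Individuals with missing M are removed pairwise (the co-twin goes too,
    keeping clusters intact), as are pairs with a missing derived BP;
    fewer than ``min_pairs`` complete pairs, or a singular design, yields
    NaNs rather than an exception.
    """
    cohort = _complete_bp_pairs(cohort, trait)
    ids = [i for i in cohort.individual_ids if i in m.index and pd.notna(m.loc[i])]
    pair_of = cohort.table["pair_id"]
    complete = pair_of.loc[ids].value_counts()
    keep_pairs = set(complete[complete == 2].index)
    ids = [i for i in ids if pair_of.loc[i] in keep_pairs]
    if len(keep_pairs) < min_pairs:
        logger.info("CpG skipped: only %d complete pairs (< %d)", len(keep_pairs), min_pairs)
        return (np.nan, np.nan, np.nan)
    design = build_design(cohort, trait, components, individual_ids=ids)
    y_m = m.loc[ids].to_numpy(float)
    if orientation == "m_on_bp":
        y, X = y_m, design.X
        target = design.columns.index("bp")
    elif orientation == "bp_on_m":
        y = design.bp
        X = design.X.copy()
        X[:, design.columns.index("bp")] = y_m      # swap trait column for M
        target = design.columns.index("bp")
    else:
        raise ValueError("orientation must be 'm_on_bp' or 'bp_on_m'")
    try:
        res = fit_paired_gee(y, X, design.clusters, working=working,
                             cov_type=cov_type)
    except np.linalg.LinAlgError:
        logger.info("CpG skipped: singular design")
        return (np.nan, np.nan, np.nan)
    se = res.robust_se[target]
    if not np.isfinite(se) or se == 0:
        return (np.nan, np.nan, np.nan)
    coef = res.params[target]
    p = 2.0 * stats.norm.sf(abs(coef / se))
    return (float(coef), float(se), float(max(p, np.finfo(float).tiny)))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.nanmin(p) <= 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in (0, 1]")
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def classify_tiers(rows: pd.DataFrame) -> pd.DataFrame:
    """Attach the mutually-exclusive significance tier per CpG."""
    p = rows["p_value"].to_numpy(float)
    q = rows["fdr_q"].to_numpy(float)
    tier = np.full(len(rows), "ns", dtype=object)
    with np.errstate(invalid="ignore"):
        tier[p < P_TOP] = "top"
        tier[p < P_WEAKER] = "weaker_than_suggestive"
        tier[p < P_SUGGESTIVE] = "suggestive"
        tier[q < FDR_GENOMEWIDE] = "genomewide"
    tier[~np.isfinite(p)] = "ns"
    out = rows.copy()
    out["tier"] = pd.Categorical(tier, categories=list(TIER_ORDER))
    return out


def run_ewas(
    matrix: CpgMatrix,
    cohort: TwinCohort,
    trait: str = "SBP",
    components: CellComponents | None = None,
    orientation: str = "m_on_bp",
    working: str = "exchangeable",
    cov_type: str = "bias_reduced",
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Genome-wide per-CpG association map, sorted by ascending p.

    Complete CpGs (no missing M) share the covariate design, so they are
    solved in one vectorized GEE pass; CpGs with missing entries fall back
    to the per-CpG route with pairwise deletion.  Output has one row per
    input CpG (flagged rows carry NaN statistics) with columns chrom, pos,
    coefficient, robust_se, p_value, fdr_q, tier, gene_symbols.
    """
    M = matrix.require_m_values()
    cohort = _complete_bp_pairs(cohort, trait)
    ids = [i for i in cohort.individual_ids if i in M.columns]
    if len(ids) < len(cohort.individual_ids):
        missing = set(cohort.individual_ids) - set(ids)
        raise ValueError(f"matrix lacks columns for cohort individuals: {sorted(missing)[:5]}")
    Mv = M[ids]

    coef = np.full(len(Mv), np.nan)
    se = np.full(len(Mv), np.nan)
    pval = np.full(len(Mv), np.nan)

    complete = ~Mv.isna().any(axis=1).to_numpy()
    if orientation == "m_on_bp" and complete.any():
        design = build_design(cohort, trait, components, individual_ids=ids)
        target = design.columns.index("bp")
        Y = Mv.to_numpy(float).T[:, complete]       # (n_ind, n_complete_cpgs)
        res = batch_paired_gee(Y, design.X, design.clusters, working=working,
                               cov_type=cov_type)
        c = res.params[:, target]
        s = res.robust_se[:, target]
        good = np.isfinite(s) & (s > 0)
        pv = np.full(len(c), np.nan)
        pv[good] = 2.0 * stats.norm.sf(np.abs(c[good] / s[good]))
        pv = np.maximum(pv, np.finfo(float).tiny)
        coef[complete], se[complete], pval[complete] = c, s, pv
    incomplete_idx = np.nonzero(~complete)[0] if orientation == "m_on_bp" \
        else np.arange(len(Mv))
    for j in incomplete_idx:
        coef[j], se[j], pval[j] = fit_gee_cpg(
            Mv.iloc[j], cohort, trait, components,
            orientation=orientation, working=working, cov_type=cov_type,
            min_pairs=min_pairs)

    rows = pd.DataFrame({
        "chrom": Mv.index.get_level_values("chrom"),
        "pos": Mv.index.get_level_values("pos"),
        "coefficient": coef,
        "robust_se": se,
        "p_value": pval,
    })
    rows["fdr_q"] = bh_fdr(rows["p_value"]) if np.isfinite(pval).any() else np.nan
    rows = classify_tiers(rows)
    rows["gene_symbols"] = "NA"
    # ascending p with stable (chrom, pos) tie order; NaN p sorts last
    rows = rows.sort_values(["p_value", "chrom", "pos"], kind="stable",
                            na_position="last").reset_index(drop=True)
    return rows


def write_ewas_tsv(rows: pd.DataFrame, path) -> None:
    out = rows.rename(columns={"pos": "position_bp"})
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
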