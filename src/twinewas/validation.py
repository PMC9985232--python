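"""Candidate-CpG case–control validation and intra-pair power statistics.

Two independent checks complement the twin EWAS:

* in an unrelated case–control sample, candidate CpGs are compared by the
  Wilcoxon rank-sum test and by logistic regression of case status on
  methylation, adjusted for BMI, triglycerides and fasting glucose;
* within the twin sample itself, the correlation between intra-pair
  blood-pressure differences and intra-pair methylation differences
  (partial, given pair-level age and sex) gauges how much trait-linked
  methylation variance the discordant design can see — the quantity that
  drives its statistical power.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import TwinCohort, derived_column
from .methylation import CpgMatrix

logger = logging.getLogger(__name__)


def wilcoxon_case_control(case_values, control_values) -> float:
    """Two-sided rank-sum p: exact for min(n) ≤ 8 without ties, else normal
    approximation with continuity correction."""
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("each group needs at least one value")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def logistic_assoc(
    methylation,
    case_status,
    covariates: pd.DataFrame | None = None,
) -> tuple[float, float, str]:
    """Log-odds of case status per methylation unit, Wald p, and a flag.

    Constant covariates are dropped with a warning; perfect separation or a
    non-converged fit returns NaNs with a diagnostic flag instead of an
    estimate.
    """
    meth = np.asarray(methylation, dtype=float)
    status = np.asarray(case_status).astype(float)
    classes = np.unique(status)
    if len(classes) < 2:
        raise ValueError("both outcome classes must be present")
    cols = {"intercept": np.ones(len(meth)), "methylation": meth}
    if covariates is not None:
        for name in covariates.columns:
            v = np.asarray(covariates[name], dtype=float)
            if np.nanstd(v) == 0:
                warnings.warn(f"covariate {name!r} is constant; dropped", stacklevel=2)
                continue
            cols[name] = v
    X = np.column_stack(list(cols.values()))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(status, X).fit(disp=0, maxiter=200)
        beta = fit.params[1]
        se = fit.bse[1]
        if not (np.isfinite(beta) and np.isfinite(se)) or se > 1e4:
            return float("nan"), float("nan"), "separation_or_unstable"
        p = 2.0 * stats.norm.sf(abs(beta / se))
        return float(beta), float(p), ""
    except (np.linalg.LinAlgError, PerfectSeparationError):
        return float("nan"), float("nan"), "perfect_separation"


@dataclass
class ValidationResult:
    cpg: str
    wilcoxon_p: float
    logistic_beta: float
    logistic_p: float
    direction: str            # hyper / hypo in cases
    flag: str = ""


def validate_cpgs(
    matrix: CpgMatrix,
    cohort: TwinCohort,
    loci=None,
    covariate_names: tuple[str, ...] = ("bmi", "tg", "fbg"),
) -> pd.DataFrame:
    """Wilcoxon + adjusted logistic association for each candidate CpG."""
    if "case_status" not in cohort.table.columns:
        raise ValueError("cohort lacks case_status")
    status = cohort.table["case_status"].astype(bool)
    ids = [i for i in cohort.individual_ids if i in matrix.beta.columns]
    covs = cohort.table.loc[ids, list(covariate_names)].astype(float)
    beta = matrix.beta[ids]
    loci = list(loci) if loci is not None else list(beta.index)
    out = []
    for locus in loci:
        vals = beta.loc[locus]
        vals = vals if isinstance(vals, pd.Series) else vals.iloc[0]
        keep = vals.notna()
        v = vals[keep]
        s = status.reindex(v.index).astype(bool)
        case, ctrl = v[s.to_numpy()], v[~s.to_numpy()]
        if len(case) == 0 or len(ctrl) == 0:
            out.append(ValidationResult(f"{locus[0]}:{locus[1]}", np.nan, np.nan,
                                        np.nan, "NA", "single_class"))
            continue
        wp = wilcoxon_case_control(case, ctrl)
        lb, lp, flag = logistic_assoc(v.to_numpy(), s.to_numpy(),
                                      covs.reindex(v.index))
        direction = "hyper" if case.median() >= ctrl.median() else "hypo"
        out.append(ValidationResult(f"{locus[0]}:{locus[1]}", wp, lb, lp,
                                    direction, flag))
    return pd.DataFrame([r.__dict__ for r in out])


def _residualize(v: np.ndarray, Z: np.ndarray | None) -> np.ndarray:
    if Z is None:
        return v - v.mean()
    coef, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ coef


def intrapair_partial_correlation(
    cohort: TwinCohort,
    matrix: CpgMatrix,
    loci=None,
    trait: str = "SBP",
    covariates: tuple[str, ...] = ("age", "sex"),
) -> pd.Series:
    """Partial corr of (ΔBP, ΔM) per CpG given pair-level age and sex.

    Differences are twin 1 minus twin 2 (fixed ordering); both difference
    vectors are residualized on the pair-level covariates (with intercept)
    and the Pearson correlation of the residuals is returned.  With no
    covariates this is the plain Pearson correlation of the differences.
    """
    col = derived_column(trait)
    if col not in cohort.table.columns:
        raise ValueError(f"derived {trait} missing; run preprocess.derive_bp first")
    table = cohort.table
    ids1 = table.index[table["twin_index"] == 1]
    ids2_by_pair = pd.Series(table.index[table["twin_index"] == 2].to_numpy(),
                             index=table.loc[table["twin_index"] == 2, "pair_id"].to_numpy())
    pair_order = table.loc[ids1, "pair_id"].to_numpy()
    ids2 = ids2_by_pair.loc[pair_order].to_numpy()

    dbp = (table.loc[ids1, col].to_numpy(float)
           - table.loc[ids2, col].to_numpy(float))
    M = matrix.require_m_values()
    loci = list(loci) if loci is not None else list(M.index)

    Z = None
    if covariates:
        zcols = [np.ones(len(ids1))]
        if "age" in covariates:
            zcols.append(table.loc[ids1, "age_years"].to_numpy(float))
        if "sex" in covariates:
            zcols.append((table.loc[ids1, "sex"].astype(str).str.upper() == "M")
                         .to_numpy(float))
        Z = np.column_stack(zcols)

    out = {}
    for locus in loci:
        row = M.loc[locus]
        row = row if isinstance(row, pd.Series) else row.iloc[0]
        dm = row.reindex(ids1).to_numpy(float) - row.reindex(ids2).to_numpy(float)
        ok = np.isfinite(dm) & np.isfinite(dbp)
        if ok.sum() < 4:
            raise ValueError("need at least 4 complete pairs for a partial correlation")
        rb = _residualize(dbp[ok], Z[ok] if Z is not None else None)
        rm = _residualize(dm[ok], Z[ok] if Z is not None else None)
        denom = np.linalg.norm(rb) * np.linalg.norm(rm)
        out[locus] = float(rb @ rm / denom) if denom > 0 else float("nan")
    s = pd.Series(out, name="partial_r")
    s.index = pd.MultiIndex.from_tuples(s.index, names=["chrom", "pos"])
    return s
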