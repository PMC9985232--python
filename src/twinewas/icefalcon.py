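"""ICE FALCON bidirectional causal inference for twin pairs.

Inference about Causation through Examination of Familial Confounding
compares three pair-clustered GEE models per (exposure x, outcome y):

* Model 1: y_self ~ x_self            → β_self  (causal + familial share)
* Model 2: y_self ~ x_cotwin          → β_cotwin (familial share only)
* Model 3: y_self ~ x_self + x_cotwin → β′_self, β′_cotwin (joint)

If conditioning on the self exposure collapses the co-twin coefficient
(|β_cotwin − β′_cotwin| much larger than |β_self − β′_self|, ratio > 1.5)
the association is causal in the modeled direction; if both coefficients
attenuate similarly, familial confounding explains the association.
Coefficient-change p-values come from a pair-level nonparametric bootstrap
(resample pairs with replacement, normal-approximation two-sided p from
the bootstrap SE).  The ratio is reported only when the co-twin change is
significant, matching the convention of printing "–" otherwise.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cellmix import CellComponents
from .cohort import TwinCohort, derived_column
from .gee import fit_paired_gee
from .methylation import CpgMatrix

logger = logging.getLogger(__name__)

DIRECTIONS = ("meth_to_bp", "bp_to_meth")
VERDICTS = ("causal", "familial_confounding", "inconclusive")

ICEFALCON_COLUMNS = [
    "cpg", "chrom", "pos", "gene", "direction", "beta_self", "beta_cotwin",
    "self_change", "p_self_change", "cotwin_change", "p_cotwin_change",
    "ratio", "verdict",
]


@dataclass
class IceFalconFit:
    direction: str
    beta_self: float
    beta_cotwin: float
    beta_self_full: float
    beta_cotwin_full: float
    self_change: float
    cotwin_change: float
    p_self_change: float
    p_cotwin_change: float
    ratio: float                       # NaN when undefined ("–")
    verdict: str
    n_pairs: int
    diagnostics: str = ""


def reshape_pairs(
    cohort: TwinCohort,
    x: pd.Series,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pair-long table: two rows per pair, each twin serving once as self.

    Row r carries (y_self, x_self, x_cotwin) plus per-individual covariates;
    the cluster id is the pair.  Pairs with any missing x or y are dropped;
    an individual without a co-twin in the data is an error.
    """
    table = cohort.table
    ids1 = table.index[table["twin_index"] == 1]
    ids2 = table.index[table["twin_index"] == 2]
    p1 = table.loc[ids1, "pair_id"].to_numpy()
    p2 = table.loc[ids2, "pair_id"].to_numpy()
    order2 = pd.Series(ids2, index=p2).loc[p1].to_numpy()
    missing_partner = pd.isna(order2)
    if missing_partner.any():
        raise ValueError(f"unpaired individuals for pairs {list(p1[missing_partner][:5])}")

    def grab(series, ids):
        return series.reindex(ids).to_numpy(float)

    frames = []
    for self_ids, co_ids in ((ids1.to_numpy(), order2), (order2, ids1.to_numpy())):
        block = pd.DataFrame({
            "pair_id": p1,
            "individual_id": self_ids,
            "y_self": grab(y, self_ids),
            "x_self": grab(x, self_ids),
            "x_cotwin": grab(x, co_ids),
        })
        if covariates is not None:
            for c in covariates.columns:
                block[c] = covariates[c].reindex(self_ids).to_numpy(float)
        frames.append(block)
    long = pd.concat(frames, ignore_index=True)
    value_cols = [c for c in long.columns if c not in ("pair_id", "individual_id")]
    complete_rows = long[value_cols].notna().all(axis=1)
    complete_pairs = long.loc[complete_rows, "pair_id"].value_counts()
    keep = set(complete_pairs[complete_pairs == 2].index)
    long = long[long["pair_id"].isin(keep)]
    return long.sort_values(["pair_id", "individual_id"], kind="stable").reset_index(drop=True)


def classify_causality(
    cotwin_change: float,
    self_change: float,
    p_cotwin_change: float,
    ratio_threshold: float = 1.5,
    alpha: float = 0.05,
) -> tuple[str, float]:
    """Verdict and reported ratio from the coefficient changes.

    The ratio |Δ co-twin| / |Δ self| is reported only when the co-twin
    change is significant; then ratio > threshold reads as causal and
    ratio ≤ threshold as familial confounding.  Otherwise inconclusive,
    ratio undefined (NaN).
    """
    if not np.isfinite(p_cotwin_change) or p_cotwin_change >= alpha:
        return "inconclusive", float("nan")
    denom = abs(self_change)
    ratio = abs(cotwin_change) / denom if denom > 0 else float("inf")
    if ratio > ratio_threshold:
        return "causal", ratio
    return "familial_confounding", ratio


def _three_models(table: pd.DataFrame, cov_cols: list[str], clusters: np.ndarray):
    y = table["y_self"].to_numpy(float)
    n = len(table)
    ones = np.ones(n)
    covs = [table[c].to_numpy(float) for c in cov_cols]
    xs = table["x_self"].to_numpy(float)
    xc = table["x_cotwin"].to_numpy(float)
    X1 = np.column_stack([ones, xs] + covs)
    X2 = np.column_stack([ones, xc] + covs)
    X3 = np.column_stack([ones, xs, xc] + covs)
    b_self = fit_paired_gee(y, X1, clusters).params[1]
    b_cotwin = fit_paired_gee(y, X2, clusters).params[1]
    full = fit_paired_gee(y, X3, clusters).params
    return b_self, b_cotwin, full[1], full[2]


def ice_falcon_fit(
    table: pd.DataFrame,
    direction: str = "meth_to_bp",
    covariate_cols: list[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    ratio_threshold: float = 1.5,
    alpha: float = 0.05,
    min_pairs: int = 20,
) -> IceFalconFit:
    """Fit the three GEE models and bootstrap the coefficient changes."""
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    cov_cols = list(covariate_cols or [])
    pair_ids = table["pair_id"].to_numpy()
    uniq_pairs, pair_codes = np.unique(pair_ids, return_inverse=True)
    n_pairs = len(uniq_pairs)
    if n_pairs < min_pairs:
        raise ValueError(f"ICE FALCON needs >= {min_pairs} complete pairs, got {n_pairs}")

    b_self, b_cotwin, b_self_full, b_cotwin_full = _three_models(table, cov_cols, pair_codes)
    self_change = b_self - b_self_full
    cotwin_change = b_cotwin - b_cotwin_full

    # pair-level bootstrap: each draw resamples pairs with replacement and
    # the two rows of a sampled pair keep a fresh cluster id
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    row_of_pair = [np.nonzero(pair_codes == k)[0] for k in range(n_pairs)]
    boot_self = np.empty(n_boot)
    boot_cotwin = np.empty(n_boot)
    tbl = table.reset_index(drop=True)
    for b in range(n_boot):
        draw = rng.integers(0, n_pairs, n_pairs)
        rows_idx = np.concatenate([row_of_pair[k] for k in draw])
        clusters = np.repeat(np.arange(n_pairs), [len(row_of_pair[k]) for k in draw])
        sub = tbl.iloc[rows_idx]
        try:
            s1, s2, f1, f2 = _three_models(sub, cov_cols, clusters)
            boot_self[b] = s1 - f1
            boot_cotwin[b] = s2 - f2
        except np.linalg.LinAlgError:
            boot_self[b] = np.nan
            boot_cotwin[b] = np.nan

    def boot_p(observed: float, draws: np.ndarray) -> tuple[float, str]:
        draws = draws[np.isfinite(draws)]
        sd = draws.std(ddof=1) if len(draws) > 1 else 0.0
        if sd == 0:
            return float("nan"), "degenerate bootstrap (zero variance)"
        return float(2.0 * stats.norm.sf(abs(observed) / sd)), ""

    p_self, d1 = boot_p(self_change, boot_self)
    p_cotwin, d2 = boot_p(cotwin_change, boot_cotwin)
    diagnostics = "; ".join(x for x in (d1, d2) if x)
    verdict, ratio = classify_causality(
        cotwin_change, self_change, p_cotwin,
        ratio_threshold=ratio_threshold, alpha=alpha)
    return IceFalconFit(
        direction=direction,
        beta_self=float(b_self),
        beta_cotwin=float(b_cotwin),
        beta_self_full=float(b_self_full),
        beta_cotwin_full=float(b_cotwin_full),
        self_change=float(self_change),
        cotwin_change=float(cotwin_change),
        p_self_change=p_self,
        p_cotwin_change=p_cotwin,
        ratio=ratio,
        verdict=verdict,
        n_pairs=n_pairs,
        diagnostics=diagnostics,
    )


def run_ice_falcon(
    matrix: CpgMatrix,
    cohort: TwinCohort,
    trait: str,
    top_rows: pd.DataFrame,
    components: CellComponents | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    ratio_threshold: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Both causal directions for every top CpG, one row per fit.

    meth_to_bp regresses blood pressure on self/co-twin methylation with
    age and sex; bp_to_meth regresses methylation on self/co-twin blood
    pressure, adding the cell-composition components when supplied (they
    confound methylation, the outcome of that direction).
    """
    M = matrix.require_m_values()
    bp = cohort.table[derived_column(trait)]
    base_cov = pd.DataFrame({
        "age": cohort.table["age_years"].astype(float),
        "sex_male": (cohort.table["sex"].astype(str).str.upper() == "M").astype(float),
    }, index=cohort.table.index)
    comp_cov = base_cov
    if components is not None:
        comp_cov = base_cov.join(components.components)

    records = []
    for i, (_, row) in enumerate(top_rows.iterrows()):
        locus = (row["chrom"], row["pos"])
        m = M.loc[locus]
        m = m if isinstance(m, pd.Series) else m.iloc[0]
        for j, direction in enumerate(DIRECTIONS):
            if direction == "meth_to_bp":
                table = reshape_pairs(cohort, x=m, y=bp, covariates=base_cov)
                covs = list(base_cov.columns)
            else:
                table = reshape_pairs(cohort, x=bp, y=m, covariates=comp_cov)
                covs = list(comp_cov.columns)
            fit = ice_falcon_fit(
                table, direction=direction, covariate_cols=covs,
                n_boot=n_boot, seed=int((seed + 1) * 100003 + i * 2 + j) % (2**31),
                ratio_threshold=ratio_threshold, alpha=alpha)
            records.append({
                "cpg": f"{row['chrom']}:{row['pos']}",
                "chrom": row["chrom"],
                "pos": row["pos"],
                "gene": row.get("gene_symbols", "NA"),
                "direction": direction,
                "beta_self": fit.beta_self,
                "beta_cotwin": fit.beta_cotwin,
                "self_change": fit.self_change,
                "p_self_change": fit.p_self_change,
                "cotwin_change": fit.cotwin_change,
                "p_cotwin_change": fit.p_cotwin_change,
                "ratio": fit.ratio,
                "verdict": fit.verdict,
            })
    return pd.DataFrame(records, columns=ICEFALCON_COLUMNS)


def write_icefalcon_tsv(fits: pd.DataFrame, path) -> None:
    out = fits.copy()
    out["ratio"] = out["ratio"].map(lambda r: "" if not np.isfinite(r) else f"{r:.3f}")
    out.to_csv(path, sep="\t", index=False, float_format="%.4g")
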