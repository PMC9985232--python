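"""Phenotype derivation, discordant-pair selection, and CpG matrix QC.

The preprocessing chain mirrors the standard discordant-twin EWAS recipe:

1. average the three repeated blood-pressure readings per individual and
   blank cohort-level outliers (beyond mean ± 3 SD of the derived values);
2. keep only pairs whose absolute intra-pair difference reaches the
   discordance threshold (2 mmHg for SBP, 1 mmHg for DBP, inclusive);
3. cap per-sample read coverage at the sample's 90th percentile;
4. drop CpGs with mean β < 0.01 or more than 10 missing observations;
5. transform β to M = log2(β / (1 − β)), the analysis scale.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import TwinCohort, derived_column, reading_columns
from .methylation import CpgMatrix

logger = logging.getLogger(__name__)

#: inclusive intra-pair |difference| thresholds (mmHg) by trait
DEFAULT_MIN_DIFF = {"SBP": 2.0, "DBP": 1.0}


def derive_bp(cohort: TwinCohort, trait: str = "SBP", sd_limit: float = 3.0) -> TwinCohort:
    """Average the three repeated readings; blank cohort-level outliers.

    The derived value is the arithmetic mean of the three readings.  Any
    derived value farther than ``sd_limit`` standard deviations from the
    cohort mean of derived values is set missing.  Records with missing
    readings are rejected with a diagnostic.
    """
    cols = reading_columns(trait)
    readings = cohort.table[cols]
    incomplete = readings.isna().any(axis=1)
    if incomplete.any():
        bad = list(cohort.table.index[incomplete][:5])
        raise ValueError(
            f"{int(incomplete.sum())} individuals lack complete {trait} readings "
            f"(e.g. {bad}); three readings per individual are required"
        )
    derived = readings.mean(axis=1)
    center, spread = derived.mean(), derived.std(ddof=1)
    if spread > 0:
        outlier = (derived - center).abs() > sd_limit * spread
        if outlier.any():
            logger.info(
                "%s: %d derived values beyond %.1f SD set missing",
                trait, int(outlier.sum()), sd_limit,
            )
        derived = derived.mask(outlier)
    return cohort.with_columns(**{derived_column(trait): derived})


@dataclass
class DiscordanceReport:
    trait: str
    min_diff: float
    n_pairs_in: int
    n_pairs_kept: int
    n_dropped_missing: int
    n_dropped_below_threshold: int
    median_abs_diff: float
    abs_diff_95_range: tuple[float, float]


def select_discordant_pairs(
    cohort: TwinCohort,
    trait: str = "SBP",
    min_diff: float | None = None,
) -> tuple[TwinCohort, DiscordanceReport]:
    """Keep pairs with |BP_1 − BP_2| ≥ min_diff (boundary inclusive).

    Pairs with a missing derived value in either co-twin are dropped: the
    pairwise design needs both members.  Returns the filtered cohort and a
    report with the median and 95% range of the kept |Δ|.
    """
    trait = trait.upper()
    if min_diff is None:
        min_diff = DEFAULT_MIN_DIFF[trait]
    col = derived_column(trait)
    if col not in cohort.table.columns:
        raise ValueError(f"derived {trait} missing; run derive_bp first")
    t1, t2 = cohort.pair_rows()
    diff = (t1[col] - t2[col]).abs()
    missing = diff.isna()
    kept_mask = (~missing) & (diff >= min_diff)
    kept = diff[kept_mask]
    report = DiscordanceReport(
        trait=trait,
        min_diff=float(min_diff),
        n_pairs_in=len(diff),
        n_pairs_kept=int(kept_mask.sum()),
        n_dropped_missing=int(missing.sum()),
        n_dropped_below_threshold=int((~missing).sum() - kept_mask.sum()),
        median_abs_diff=float(kept.median()) if len(kept) else float("nan"),
        abs_diff_95_range=(
            (float(np.percentile(kept, 2.5)), float(np.percentile(kept, 97.5)))
            if len(kept)
            else (float("nan"), float("nan"))
        ),
    )
    logger.info(
        "%s discordance >= %g mmHg: kept %d/%d pairs (median |d|=%.1f)",
        trait, min_diff, report.n_pairs_kept, report.n_pairs_in, report.median_abs_diff,
    )
    return cohort.subset_pairs(kept.index), report


def cap_coverage(matrix: CpgMatrix, quantile: float = 0.9) -> CpgMatrix:
    """Cap each sample's coverage at that sample's ``quantile`` percentile.

    Values above the per-sample percentile are replaced by the percentile
    value; β-values are untouched.  The percentile is computed per sample
    over its non-missing coverage entries.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    if matrix.coverage is None:
        raise ValueError("matrix has no coverage to cap")
    cov = matrix.coverage
    caps = cov.quantile(quantile, axis=0)
    capped = cov.clip(upper=caps, axis=1)
    return matrix.replace(coverage=capped)


@dataclass
class QcReport:
    n_cpgs_in: int
    n_dropped_low_beta: int
    n_dropped_missing: int
    n_cpgs_kept: int
    params: dict = field(default_factory=dict)


def qc_filter_cpgs(
    matrix: CpgMatrix,
    min_mean_beta: float = 0.01,
    max_missing: int = 10,
) -> tuple[CpgMatrix, QcReport]:
    """Drop CpGs with mean β < ``min_mean_beta`` or > ``max_missing`` missing.

    Both rules match the usual RRBS QC convention: the mean is taken over
    non-missing entries, and the missing-count rule is strict ("more than"),
    so a CpG with exactly ``max_missing`` missing observations is kept.
    """
    beta = matrix.beta
    mean_beta = beta.mean(axis=1, skipna=True)
    n_missing = beta.isna().sum(axis=1)
    low = (mean_beta < min_mean_beta) | mean_beta.isna()
    gappy = n_missing > max_missing
    keep = ~(low | gappy)
    report = QcReport(
        n_cpgs_in=len(beta),
        n_dropped_low_beta=int(low.sum()),
        n_dropped_missing=int(gappy.sum()),
        n_cpgs_kept=int(keep.sum()),
        params={"min_mean_beta": min_mean_beta, "max_missing": max_missing},
    )
    if report.n_cpgs_kept == 0:
        logger.warning("QC removed every CpG (min_mean_beta=%g, max_missing=%d)",
                       min_mean_beta, max_missing)
    filtered = matrix.replace(
        beta=beta[keep],
        coverage=matrix.coverage[keep] if matrix.coverage is not None else None,
        m_values=None,
    )
    return filtered, report


def beta_to_m(matrix: CpgMatrix, clip: tuple[float, float] = (0.001, 0.999)) -> CpgMatrix:
    """Attach M-values: M = log2(β / (1 − β)), missing propagates.

    β is clipped to ``clip`` before the transform so boundary values keep a
    finite M; the bounds are configurable.  The transform is strictly
    increasing and antisymmetric about β = 0.5 (M(β) = −M(1 − β)).
    """
    lo, hi = clip
    if not 0 < lo < hi < 1:
        raise ValueError("clip bounds must satisfy 0 < lo < hi < 1")
    b = matrix.beta.clip(lower=lo, upper=hi)
    m = np.log2(b / (1.0 - b))
    return matrix.replace(m_values=m)
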