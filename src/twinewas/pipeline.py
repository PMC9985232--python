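"""End-to-end pipeline orchestration and the run manifest.

Stages: preprocess → cell components → EWAS → DMR calling → ICE FALCON →
(optional) annotation and case–control validation.  Every stage writes its
table into the run directory; identical config + inputs + seed give
byte-identical numeric outputs.  Logging goes to stderr; results never do.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .cellmix import refactor_components, write_components_csv
from .cohort import TwinCohort
from .config import PipelineConfig
from .dmr import call_dmrs, write_dmr_outputs
from .ewas import run_ewas, write_ewas_tsv
from .genes import annotate_ewas, read_gene_models
from .icefalcon import run_ice_falcon, write_icefalcon_tsv
from .methylation import read_methylation_tsv
from .preprocess import (beta_to_m, cap_coverage, derive_bp, qc_filter_cpgs,
                         select_discordant_pairs)
from .validation import validate_cpgs

logger = logging.getLogger(__name__)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _StageTimer:
    def __init__(self, name):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            logger.info("stage %s: done in %.1fs", self.name, dt)
        else:
            logger.error("stage %s: FAILED after %.1fs (%s)", self.name, dt, exc)
        return False


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory."""
    outdir = Path(config.paths.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trait = config.trait.upper()

    with _StageTimer("load"):
        matrix = read_methylation_tsv(config.paths.methylation,
                                      coverage_path=config.paths.coverage)
        cohort = TwinCohort.from_csv(config.paths.phenotypes)

    with _StageTimer("preprocess"):
        cohort = derive_bp(cohort, trait, sd_limit=config.qc.bp_sd_limit)
        cohort, disc_report = select_discordant_pairs(
            cohort, trait, min_diff=config.discordance_min_diff)
        matrix = matrix.subset_individuals(cohort.individual_ids)
        if matrix.coverage is not None:
            matrix = cap_coverage(matrix, quantile=config.qc.coverage_quantile)
        matrix, qc_report = qc_filter_cpgs(
            matrix, min_mean_beta=config.qc.min_mean_beta,
            max_missing=config.qc.max_missing)
        matrix = beta_to_m(matrix)
        (outdir / "qc_report.txt").write_text(
            f"trait\t{trait}\n"
            f"pairs_in\t{disc_report.n_pairs_in}\n"
            f"pairs_kept\t{disc_report.n_pairs_kept}\n"
            f"median_abs_diff\t{disc_report.median_abs_diff:.2f}\n"
            f"abs_diff_95_range\t{disc_report.abs_diff_95_range[0]:.2f},"
            f"{disc_report.abs_diff_95_range[1]:.2f}\n"
            f"cpgs_in\t{qc_report.n_cpgs_in}\n"
            f"cpgs_dropped_low_beta\t{qc_report.n_dropped_low_beta}\n"
            f"cpgs_dropped_missing\t{qc_report.n_dropped_missing}\n"
            f"cpgs_kept\t{qc_report.n_cpgs_kept}\n")

    with _StageTimer("cellmix"):
        t_sites = min(config.cellmix.t, max(matrix.n_cpgs // 2, config.cellmix.k + 1))
        components = refactor_components(
            matrix, k=config.cellmix.k, t=t_sites, d=config.cellmix.d)
        write_components_csv(components, outdir / "cell_components.csv")

    with _StageTimer("ewas"):
        rows = run_ewas(matrix, cohort, trait, components,
                        orientation=config.ewas.orientation,
                        working=config.ewas.working,
                        min_pairs=config.ewas.min_pairs)
        if config.paths.genes:
            genes = read_gene_models(config.paths.genes)
            rows = annotate_ewas(rows, genes)
        write_ewas_tsv(rows, outdir / "ewas.tsv")

    with _StageTimer("dmr"):
        dmrs = call_dmrs(rows, seed_p=config.dmr.seed_p, window=config.dmr.window,
                         max_gap=config.dmr.max_gap, bin_size=config.dmr.bin_size,
                         max_dist=config.dmr.max_dist, alpha=config.dmr.alpha)
        write_dmr_outputs(dmrs, outdir / "dmrs.tsv", outdir / "dmrs.bed")

    with _StageTimer("icefalcon"):
        top = rows[rows["p_value"] < config.icefalcon.top_p]
        if len(top):
            fits = run_ice_falcon(
                matrix, cohort, trait, top, components,
                n_boot=config.icefalcon.n_boot, seed=config.seed,
                ratio_threshold=config.icefalcon.ratio_threshold,
                alpha=config.icefalcon.alpha)
        else:
            from .icefalcon import ICEFALCON_COLUMNS
            fits = pd.DataFrame(columns=ICEFALCON_COLUMNS)
            logger.info("no top CpGs below p < %g; ICE FALCON skipped",
                        config.icefalcon.top_p)
        write_icefalcon_tsv(fits, outdir / "icefalcon.tsv")

    with _StageTimer("validate"):
        tbl = cohort.table
        if "case_status" in tbl.columns and tbl["case_status"].nunique() == 2 and len(top):
            validation = validate_cpgs(
                matrix, cohort,
                loci=list(zip(top["chrom"], top["pos"])))
            validation.to_csv(outdir / "validation.tsv", sep="\t", index=False,
                              float_format="%.4g")
        else:
            logger.info("validation skipped (needs case/control classes and top CpGs)")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "trait": trait,
        "parameters": config.model_dump(),
        "inputs": {
            name: {"path": p, "sha256": _sha256(p)}
            for name, p in (("methylation", config.paths.methylation),
                            ("phenotypes", config.paths.phenotypes),
                            ("coverage", config.paths.coverage),
                            ("genes", config.paths.genes))
            if p
        },
        "n_pairs_analyzed": cohort.n_pairs,
        "n_cpgs_analyzed": matrix.n_cpgs,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
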