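"""CpG methylation matrix container and plain-text I/O.

``CpgMatrix`` holds a β-value matrix (CpGs × individuals) indexed by a
(chrom, pos) MultiIndex in genomic order, with optional read-coverage and
M-value matrices of the same shape.  β-values live in [0, 1] with missing
entries allowed; M-values exist only after the logit2 transform in
:func:`twinewas.preprocess.beta_to_m`.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from ._genome import sort_loci_frame


def _as_locus_frame(df: pd.DataFrame, what: str) -> pd.DataFrame:
    if not isinstance(df.index, pd.MultiIndex) or list(df.index.names) != ["chrom", "pos"]:
        raise ValueError(f"{what} must be indexed by a (chrom, pos) MultiIndex")
    df = df.copy()
    df.index = pd.MultiIndex.from_arrays(
        [
            df.index.get_level_values("chrom").astype(str),
            df.index.get_level_values("pos").astype(np.int64),
        ],
        names=["chrom", "pos"],
    )
    return sort_loci_frame(df)


class CpgMatrix:
    """β-values (and optional coverage / M-values) over CpGs × individuals."""

    def __init__(
        self,
        beta: pd.DataFrame,
        coverage: pd.DataFrame | None = None,
        m_values: pd.DataFrame | None = None,
        implanted_regions: list[tuple[str, int, int]] | None = None,
    ):
        beta = _as_locus_frame(beta.astype(float), "beta")
        vals = beta.to_numpy()
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=1.0) > 1:
                raise ValueError("beta values must lie in [0, 1] where present")
        if beta.index.has_duplicates:
            dups = beta.index[beta.index.duplicated()][:3].tolist()
            raise ValueError(f"duplicate CpG loci: {dups}")
        self.beta = beta
        self.coverage = None
        if coverage is not None:
            coverage = _as_locus_frame(coverage, "coverage")
            if not coverage.index.equals(beta.index) or list(coverage.columns) != list(beta.columns):
                raise ValueError("coverage must share loci and columns with beta")
            self.coverage = coverage
        self.m_values = None
        if m_values is not None:
            m_values = _as_locus_frame(m_values.astype(float), "m_values")
            if not m_values.index.equals(beta.index):
                raise ValueError("m_values must share loci with beta")
            self.m_values = m_values
        self.implanted_regions = list(implanted_regions or [])

    # -- accessors ---------------------------------------------------------
    @property
    def loci(self) -> pd.MultiIndex:
        return self.beta.index

    @property
    def individual_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_cpgs(self) -> int:
        return len(self.beta)

    def require_m_values(self) -> pd.DataFrame:
        if self.m_values is None:
            raise ValueError("M-values not computed; run preprocess.beta_to_m first")
        return self.m_values

    def subset_individuals(self, ids) -> "CpgMatrix":
        ids = [i for i in ids if i in self.beta.columns]
        return CpgMatrix(
            self.beta[ids],
            self.coverage[ids] if self.coverage is not None else None,
            self.m_values[ids] if self.m_values is not None else None,
            self.implanted_regions,
        )

    def replace(self, **kwargs) -> "CpgMatrix":
        args = dict(
            beta=self.beta,
            coverage=self.coverage,
            m_values=self.m_values,
            implanted_regions=self.implanted_regions,
        )
        args.update(kwargs)
        return CpgMatrix(**args)

    def __repr__(self) -> str:  # pragma: no cover
        extras = []
        if self.coverage is not None:
            extras.append("coverage")
        if self.m_values is not None:
            extras.append("M-values")
        tag = f" +{'+'.join(extras)}" if extras else ""
        return f"CpgMatrix({self.n_cpgs} CpGs x {len(self.individual_ids)} individuals{tag})"


# -- plain-text I/O (TSV with chrom, pos, one column per individual) -------

def read_methylation_tsv(path, coverage_path=None) -> CpgMatrix:
    beta = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    beta = beta.set_index(["chrom", "pos"])
    coverage = None
    if coverage_path is not None:
        coverage = pd.read_csv(coverage_path, sep="\t", dtype={"chrom": str})
        coverage = coverage.set_index(["chrom", "pos"])
    return CpgMatrix(beta, coverage=coverage)


def write_methylation_tsv(matrix: CpgMatrix, path, coverage_path=None, float_format="%.6g") -> None:
    matrix.beta.reset_index().to_csv(path, sep="\t", index=False, float_format=float_format)
    if coverage_path is not None and matrix.coverage is not None:
        matrix.coverage.reset_index().to_csv(coverage_path, sep="\t", index=False)
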