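"""Reference-free cell-type composition components (ReFACTor-style).

Bulk-blood methylation mixes cell-type-specific methylomes, and cell
composition varying with the trait is a classic EWAS confounder.  Without
reference profiles, composition can be recovered from the data itself: the
CpGs best explained by a low-rank structure are the cell-type-informative
ones, and principal components over those CpGs track the mixing fractions.

Procedure (for assumed ``k`` cell types, ``t`` retained sites, ``d``
returned components):

1. standardize each site across individuals (mean 0, SD 1);
2. rank-``k`` truncated SVD of the standardized matrix;
3. score each site by the Euclidean distance between its standardized row
   and its rank-``k`` reconstruction;
4. keep the ``t`` lowest-distance sites (ties broken by genomic order);
5. PCA of the retained sub-matrix; return the first ``d`` sample-score
   columns, ordered by decreasing explained variance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .methylation import CpgMatrix


@dataclass
class CellComponents:
    components: pd.DataFrame            # individuals × PC1..PCd
    selected_sites: pd.MultiIndex       # loci of the t retained sites
    params: dict
    explained_variance: np.ndarray = None

    @property
    def d(self) -> int:
        return self.components.shape[1]


def _svd_flip(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign convention: largest-|loading| row positive."""
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    return U * signs, Vt * signs[:, None]


def refactor_components(
    matrix: CpgMatrix,
    k: int = 5,
    t: int = 500,
    d: int = 5,
) -> CellComponents:
    """Estimate ``d`` composition components assuming ``k`` cell types."""
    n_ind = len(matrix.individual_ids)
    if not d <= k <= n_ind - 1:
        raise ValueError(f"need d <= k <= individuals-1 (d={d}, k={k}, n={n_ind})")

    beta = matrix.beta.to_numpy(dtype=float)          # (sites, n)
    # ReFACTor needs a complete matrix; mean-impute per site (internal only)
    if np.isnan(beta).any():
        site_means = np.nanmean(beta, axis=1)
        nan_r, nan_c = np.nonzero(np.isnan(beta))
        beta[nan_r, nan_c] = site_means[nan_r]

    sd = beta.std(axis=1, ddof=0)
    usable = sd > 0
    if int(usable.sum()) < t:
        raise ValueError(f"t={t} exceeds the {int(usable.sum())} variable sites")
    Z = (beta[usable] - beta[usable].mean(axis=1, keepdims=True)) / sd[usable, None]
    loci = matrix.loci[usable]

    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    recon = (U[:, :k] * S[:k]) @ Vt[:k]
    dist = np.linalg.norm(Z - recon, axis=1)

    # ties on equal distance resolve to the lowest genomic coordinate; loci
    # are in genomic order, so a stable sort suffices once numerically
    # indistinguishable distances (e.g. the exact-rank-k case) are quantized
    order = np.argsort(np.round(dist, 9), kind="stable")[:t]
    order.sort()                                       # keep genomic order
    Zt = Z[order]                                      # (t, n)
    selected = loci[order]

    # PCA over individuals: rows of Zt are mean-0 across individuals already
    Us, Ss, Vts = np.linalg.svd(Zt.T, full_matrices=False)   # (n, t) input
    Us, Vts = _svd_flip(Us, Vts)
    scores = Us[:, :d] * Ss[:d]
    comp = pd.DataFrame(
        scores,
        index=pd.Index(matrix.individual_ids, name="individual_id"),
        columns=[f"PC{i+1}" for i in range(d)],
    )
    expl = (Ss**2) / np.sum(Ss**2)
    return CellComponents(
        components=comp,
        selected_sites=selected,
        params={"k": k, "t": t, "d": d},
        explained_variance=expl[:d],
    )


def write_components_csv(components: CellComponents, path) -> None:
    components.components.reset_index().to_csv(path, index=False)
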