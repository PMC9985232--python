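"""DMR detection from EWAS p-values, comb-p style.

Nearby CpGs share regulatory state, so their association p-values are
spatially autocorrelated; a run of modest p-values can be jointly strong
evidence.  The procedure:

1. estimate a distance-binned autocorrelation function (ACF) of
   probit-transformed p-values, z = Φ⁻¹(1 − p), over same-chromosome
   probe pairs (negative estimates floored at 0 for weighting);
2. smooth each probe by a Stouffer–Liptak combination of all p-values
   within ±window, z_c = Σz_i / √(1ᵀΣ1), with Σ built from the ACF at the
   pairwise distances (diagonal 1);
3. seed candidate regions where the adjusted p falls below ``seed_p`` and
   extend them over gaps up to ``max_gap``; singletons are discarded;
4. score each region with the Stouffer–Liptak–Kechris combination of the
   member probes' ORIGINAL p-values (slk_p), plus a Šidák correction for
   the effective number of regions of that size
   (sidak_p = 1 − (1 − slk_p)^(covered_bases / region_bases)).

The ``significant`` flag uses sidak_p < 0.05: on a uniform null the raw
SLK p of seed-selected regions is not calibrated (the seeding step already
conditioned on small p-values), while the Šidák-corrected value holds the
genome-wide false-region count near zero.  Both values are reported.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_PMIN, _PMAX = 1e-300, 1.0 - 1e-16


@dataclass
class AcfEstimate:
    bin_edges: np.ndarray       # contiguous edges: (0, bin, 2*bin, ..., max_dist]
    correlations: np.ndarray    # Pearson correlation per bin; 0 for empty bins
    n_pairs: np.ndarray         # probe pairs per bin

    def corr_at(self, dist: np.ndarray) -> np.ndarray:
        """Floored correlation looked up by binned distance (0 beyond range)."""
        dist = np.asarray(dist, dtype=float)
        idx = np.searchsorted(self.bin_edges, dist, side="left") - 1
        out = np.zeros_like(dist, dtype=float)
        inside = (dist > 0) & (idx >= 0) & (idx < len(self.correlations))
        out[inside] = np.maximum(self.correlations[idx[inside]], 0.0)
        return out


def _z_from_p(p: np.ndarray) -> np.ndarray:
    return stats.norm.isf(np.clip(p, _PMIN, _PMAX))


def _chrom_arrays(rows: pd.DataFrame):
    """Yield (chrom, positions, z, original index) per chromosome in order."""
    z_all = _z_from_p(rows["p_value"].to_numpy(float))
    for chrom, sub in rows.groupby("chrom", sort=False, observed=True):
        pos = sub["pos"].to_numpy(np.int64)
        order = np.argsort(pos, kind="stable")
        idx = sub.index.to_numpy()[order]
        yield chrom, pos[order], z_all[rows.index.get_indexer(idx)], idx


def estimate_acf(rows: pd.DataFrame, max_dist: int = 500, bin_size: int = 50) -> AcfEstimate:
    """Distance-binned Pearson correlation of probit-transformed p-values.

    Bins partition (0, max_dist] into contiguous ``bin_size`` intervals;
    each same-chromosome probe pair is counted in exactly the bin holding
    its separation.
    """
    if max_dist < bin_size:
        raise ValueError("max_dist must be at least bin_size")
    edges = np.arange(0, max_dist + bin_size, bin_size, dtype=float)
    edges[-1] = max_dist            # last bin may be short
    nbins = len(edges) - 1
    pair_z1 = [[] for _ in range(nbins)]
    pair_z2 = [[] for _ in range(nbins)]
    rows = rows.dropna(subset=["p_value"])
    for _, pos, z, _ in _chrom_arrays(rows):
        hi = np.searchsorted(pos, pos + max_dist, side="right")
        for i in range(len(pos)):
            js = np.arange(i + 1, hi[i])
            if len(js) == 0:
                continue
            dist = pos[js] - pos[i]
            b = np.minimum(np.searchsorted(edges, dist, side="left") - 1, nbins - 1)
            for bi in np.unique(b):
                sel = js[b == bi]
                pair_z1[bi].append(np.full(len(sel), z[i]))
                pair_z2[bi].append(z[sel])
    corrs = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=int)
    for bi in range(nbins):
        if pair_z1[bi]:
            a = np.concatenate(pair_z1[bi])
            b = np.concatenate(pair_z2[bi])
            counts[bi] = len(a)
            if len(a) >= 2 and a.std() > 0 and b.std() > 0:
                corrs[bi] = float(np.corrcoef(a, b)[0, 1])
    return AcfEstimate(bin_edges=edges, correlations=corrs, n_pairs=counts)


def _sigma_from_acf(positions: np.ndarray, acf: AcfEstimate) -> np.ndarray:
    """Correlation matrix for a set of probe positions (same chromosome)."""
    dist = np.abs(positions[:, None] - positions[None, :]).astype(float)
    sigma = acf.corr_at(dist)
    np.fill_diagonal(sigma, 1.0)
    return sigma


def _repair_psd(sigma: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(sigma)
    if vals.min() >= -1e-10:
        return sigma
    logger.info("ACF correlation matrix not PSD (min eig %.2e); repairing", vals.min())
    vals = np.clip(vals, 0.0, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.clip(np.diag(fixed), 1e-12, None))
    return fixed / np.outer(d, d)


def _stouffer_liptak(z: np.ndarray, sigma: np.ndarray) -> float:
    sigma = _repair_psd(sigma)
    denom = float(np.sqrt(sigma.sum()))
    z_c = float(z.sum()) / max(denom, np.finfo(float).tiny)
    return float(np.clip(stats.norm.sf(z_c), np.finfo(float).tiny, 1.0))


def slk_adjust(rows: pd.DataFrame, acf: AcfEstimate, window: int = 200) -> pd.Series:
    """Per-probe Stouffer–Liptak combination over ±window neighbours."""
    adjusted = pd.Series(np.nan, index=rows.index, name="adjusted_p")
    valid = rows.dropna(subset=["p_value"])
    for _, pos, z, idx in _chrom_arrays(valid):
        lo = np.searchsorted(pos, pos - window, side="left")
        hi = np.searchsorted(pos, pos + window, side="right")
        out = np.empty(len(pos))
        for i in range(len(pos)):
            sel = slice(lo[i], hi[i])
            if hi[i] - lo[i] == 1:
                out[i] = float(np.clip(stats.norm.sf(z[i]), np.finfo(float).tiny, 1.0))
            else:
                sigma = _sigma_from_acf(pos[sel], acf)
                out[i] = _stouffer_liptak(z[sel], sigma)
        adjusted.loc[idx] = out
    return adjusted


def find_regions(
    rows: pd.DataFrame,
    adjusted: pd.Series,
    seed_p: float = 1e-4,
    max_gap: int = 200,
) -> pd.DataFrame:
    """Maximal runs of sub-``seed_p`` probes with gaps ≤ ``max_gap``.

    Singleton runs are discarded.  Returns one row per candidate region:
    chrom, start, end (1-based inclusive), n_probes, probe_positions.
    """
    if not 0 < seed_p < 1:
        raise ValueError("seed_p must lie in (0, 1)")
    regions = []
    valid = rows.assign(_adj=adjusted).dropna(subset=["_adj"])
    for chrom, sub in valid.groupby("chrom", sort=False, observed=True):
        sub = sub.sort_values("pos", kind="stable")
        pos = sub["pos"].to_numpy(np.int64)
        below = sub["_adj"].to_numpy(float) < seed_p
        run: list[int] = []
        for i in range(len(pos) + 1):
            extend = (
                i < len(pos) and below[i]
                and (not run or pos[i] - run[-1] <= max_gap)
            )
            if extend:
                run.append(int(pos[i]))
            else:
                if len(run) >= 2:
                    regions.append({
                        "chrom": chrom, "start": run[0], "end": run[-1],
                        "n_probes": len(run), "probe_positions": tuple(run),
                    })
                run = [int(pos[i])] if (i < len(pos) and below[i]) else []
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "n_probes",
                                          "probe_positions"])


def score_regions(
    regions: pd.DataFrame,
    rows: pd.DataFrame,
    acf: AcfEstimate,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Attach slk_p / sidak_p and the significance flag to candidate regions.

    slk_p combines the member probes' original p-values under the ACF
    correlation; sidak_p corrects it for the number of same-sized regions
    the covered genome could host (each probe covers one base, so
    covered_bases is the genome-wide probe count).
    """
    if len(regions) and (regions["n_probes"] < 2).any():
        raise ValueError("regions must contain at least two probes")
    covered_bases = int(rows["p_value"].notna().sum())
    lookup = rows.set_index(["chrom", "pos"])["p_value"]
    out = regions.copy()
    slk, sidak = [], []
    for _, reg in regions.iterrows():
        pos = np.asarray(reg["probe_positions"], dtype=np.int64)
        p = lookup.loc[[(reg["chrom"], q) for q in pos]].to_numpy(float)
        sigma = _sigma_from_acf(pos, acf)
        sp = _stouffer_liptak(_z_from_p(p), sigma)
        region_bases = int(reg["end"] - reg["start"] + 1)
        exponent = max(1.0, covered_bases / region_bases)
        sdk = float(-np.expm1(exponent * np.log1p(-min(sp, 1 - 1e-16))))
        slk.append(sp)
        sidak.append(min(max(sdk, sp), 1.0))
    out["slk_p"] = slk
    out["sidak_p"] = sidak
    out["significant"] = out["sidak_p"] < alpha if len(out) else pd.Series(dtype=bool)
    return out


def call_dmrs(
    rows: pd.DataFrame,
    seed_p: float = 1e-4,
    window: int = 200,
    max_gap: int = 200,
    bin_size: int = 50,
    max_dist: int = 500,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full pipeline: ACF → per-probe smoothing → seeding → region scores."""
    acf = estimate_acf(rows, max_dist=max_dist, bin_size=bin_size)
    adjusted = slk_adjust(rows, acf, window=window)
    candidates = find_regions(rows, adjusted, seed_p=seed_p, max_gap=max_gap)
    return score_regions(candidates, rows, acf, alpha=alpha)


def write_dmr_outputs(dmrs: pd.DataFrame, tsv_path, bed_path=None) -> None:
    """TSV mirror of the region table, plus BED6+ (0-based half-open)."""
    cols = ["chrom", "start", "end", "n_probes", "slk_p", "sidak_p", "significant"]
    dmrs[cols].to_csv(tsv_path, sep="\t", index=False, float_format="%.4g")
    if bed_path is not None:
        bed = pd.DataFrame({
            "chrom": dmrs["chrom"],
            "start": dmrs["start"] - 1,        # to 0-based half-open
            "end": dmrs["end"],
            "name": [f"dmr_{i+1}" for i in range(len(dmrs))],
            "n_probes": dmrs["n_probes"],
            "slk_p": dmrs["slk_p"],
            "sidak_p": dmrs["sidak_p"],
        })
        bed.to_csv(bed_path, sep="\t", index=False, header=False, float_format="%.4g")
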