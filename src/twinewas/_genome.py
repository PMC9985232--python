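"""Genome coordinate helpers shared across modules.

All coordinates are 1-based inclusive internally; BED export converts to
0-based half-open at the boundary.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

_SPECIAL = {"X": 23, "Y": 24, "M": 25, "MT": 25}


def chrom_rank(chrom: str) -> int:
    """Numeric rank for natural chromosome ordering (chr2 before chr10)."""
    name = str(chrom)
    if name.lower().startswith("chr"):
        name = name[3:]
    if name.upper() in _SPECIAL:
        return _SPECIAL[name.upper()]
    try:
        return int(name)
    except ValueError:
        # non-canonical contigs sort after everything, alphabetically
        return 1000 + sum(ord(c) for c in name) % 1000


def locus_order(chroms, positions) -> np.ndarray:
    """Indices that sort loci by (chromosome, position), natural chrom order."""
    chroms = np.asarray(chroms, dtype=object)
    positions = np.asarray(positions)
    ranks = np.array([chrom_rank(c) for c in chroms])
    # chrom string as secondary key keeps non-canonical contigs deterministic
    return np.lexsort((positions, chroms.astype(str), ranks))


def sort_loci_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Sort a DataFrame with a (chrom, pos) MultiIndex into genomic order."""
    idx = df.index
    order = locus_order(idx.get_level_values("chrom"), idx.get_level_values("pos"))
    if np.array_equal(order, np.arange(len(df))):
        return df
    return df.iloc[order]
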