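"""Gene-model loading and nearest-gene annotation.

Gene models come from user-supplied BED (0-based half-open, converted on
read) or GFF3 (1-based inclusive) files; coordinates are held 1-based
inclusive internally.  A CpG is annotated to the gene(s) minimizing the
distance to the gene body — distance 0 inside the gene, with exact ties
(including containment by overlapping genes) returning every such gene.
No search radius is imposed; the distance is reported.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

COLUMNS = ["chrom", "start", "end", "strand", "symbol", "ensembl_id"]


def _parse_gff_attributes(attr: str) -> dict:
    out = {}
    for field in str(attr).strip().split(";"):
        if "=" in field:
            k, v = field.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_models(path, fmt: str | None = None) -> pd.DataFrame:
    """Load gene models from BED or GFF3 into the internal 1-based table."""
    path = str(path)
    if fmt is None:
        low = path.lower()
        fmt = "gff3" if low.endswith((".gff", ".gff3")) else "bed"
    if fmt == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
        if df.shape[1] < 4:
            raise ValueError("BED gene models need at least chrom,start,end,name")
        genes = pd.DataFrame({
            "chrom": df[0].astype(str),
            "start": df[1].astype(np.int64) + 1,   # 0-based half-open -> 1-based
            "end": df[2].astype(np.int64),
            "strand": df[5].astype(str) if df.shape[1] > 5 else ".",
            "symbol": df[3].astype(str),
            "ensembl_id": df[3].astype(str),
        })
    elif fmt == "gff3":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "source", "type", "start", "end",
                                "score", "strand", "phase", "attributes"],
                         dtype={"chrom": str})
        df = df[df["type"] == "gene"]
        attrs = df["attributes"].map(_parse_gff_attributes)
        genes = pd.DataFrame({
            "chrom": df["chrom"].astype(str),
            "start": df["start"].astype(np.int64),
            "end": df["end"].astype(np.int64),
            "strand": df["strand"].astype(str),
            "symbol": attrs.map(lambda a: a.get("Name") or a.get("gene_name")
                                or a.get("ID", "NA")),
            "ensembl_id": attrs.map(lambda a: a.get("gene_id") or a.get("ID", "NA")),
        })
    else:
        raise ValueError(f"unknown gene-model format {fmt!r}")
    if (genes["start"] > genes["end"]).any():
        raise ValueError("gene models with start > end")
    return genes.reset_index(drop=True)


def nearest_gene(chrom: str, pos: int, genes: pd.DataFrame) -> tuple[list[str], float]:
    """Gene symbol(s) nearest to the CpG, with the distance in bp.

    Returns ([], inf) when the chromosome carries no gene model.  Result
    is invariant to the ordering of the gene table.
    """
    sub = genes[genes["chrom"] == str(chrom)]
    if len(sub) == 0:
        return [], float("inf")
    start = sub["start"].to_numpy(np.int64)
    end = sub["end"].to_numpy(np.int64)
    dist = np.where(
        (start <= pos) & (pos <= end), 0,
        np.minimum(np.abs(pos - start), np.abs(pos - end)),
    )
    dmin = dist.min()
    hits = sub.loc[dist == dmin, "symbol"]
    # deterministic order regardless of input table order
    return sorted(set(hits)), float(dmin)


def annotate_ewas(rows: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Fill the gene_symbols column (semicolon-joined; 'NA' when none)."""
    out = rows.copy()
    symbols = []
    for chrom, pos in zip(out["chrom"], out["pos"]):
        hits, _ = nearest_gene(chrom, int(pos), genes)
        symbols.append(";".join(hits) if hits else "NA")
    out["gene_symbols"] = symbols
    return out
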