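"""BED6 / bedGraph / TSV plumbing.

All coordinates are 0-based half-open (standard BED/bedGraph convention).
bedGraph files are written run-length encoded (one line per run of equal
counts, zero runs omitted) and expanded to dense per-base arrays on read.
Some PRO-seq dialects store minus-strand coverage as negative values; on
read, negative values are converted to their absolute value with a warning
so both dialects load.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "write_bedgraph",
    "read_bedgraph",
    "write_bed6",
    "read_bed6",
]


class FormatError(ValueError):
    """Malformed BED/bedGraph content; message names the file and line."""


def write_bedgraph(counts: np.ndarray, chrom: str, path: str | Path) -> None:
    """Write a dense per-base count vector as run-length-encoded bedGraph."""
    counts = np.asarray(counts)
    if counts.ndim != 1:
        raise ValueError("counts must be 1-D")
    # run boundaries where the value changes
    change = np.flatnonzero(np.diff(counts)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [counts.size]))
    vals = counts[starts]
    keep = vals != 0
    df = pd.DataFrame(
        {"chrom": chrom, "start": starts[keep], "end": ends[keep], "value": vals[keep]}
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path, genome_length: int | None = None) -> tuple[str, np.ndarray]:
    """Read a single-chromosome bedGraph into a dense per-base count vector.

    Returns (chrom, counts).  Negative values (minus-strand dialect) are
    absolute-valued with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "value"],
            comment="#",
            dtype={"chrom": str},
        )
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse as bedGraph ({exc})") from exc
    if df.empty:
        if genome_length is None:
            raise FormatError(f"{path}: empty bedGraph and no genome_length given")
        return "", np.zeros(genome_length)
    if df["chrom"].nunique() != 1:
        raise FormatError(f"{path}: expected a single chromosome, found {df['chrom'].nunique()}")
    bad = df.index[(df["end"] <= df["start"]) | (df["start"] < 0)]
    if len(bad):
        raise FormatError(f"{path}: line {bad[0] + 1}: invalid interval")
    if (df["value"] < 0).any():
        warnings.warn(
            f"{path}: negative bedGraph values found (minus-strand dialect); "
            "taking absolute values",
            stacklevel=2,
        )
        df["value"] = df["value"].abs()
    n = genome_length if genome_length is not None else int(df["end"].max())
    if int(df["end"].max()) > n:
        raise FormatError(f"{path}: intervals extend past genome length {n}")
    counts = np.zeros(n)
    for start, end, value in df[["start", "end", "value"]].itertuples(index=False):
        counts[start:end] = value
    if np.allclose(counts, np.round(counts)):
        counts = np.round(counts).astype(np.int64)
    return str(df["chrom"].iloc[0]), counts


def write_bed6(genes, path: str | Path) -> None:
    """Write gene annotations as BED6 (name=gene_id, score=1 for targets)."""
    rows = []
    for g in genes:
        start = min(g.pause_window[0], g.body_window[0])
        end = max(g.pause_window[1], g.body_window[1])
        rows.append((g.chrom, start, end, g.gene_id, int(g.is_target), g.strand))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path: str | Path) -> pd.DataFrame:
    """Read BED6 into a DataFrame; validates column count and coordinates."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "name": str, "strand": str},
        )
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse as BED6 ({exc})") from exc
    if df["strand"].isna().any() or not df["strand"].isin(["+", "-"]).all():
        raise FormatError(f"{path}: BED6 requires 6 columns with strand in {{+,-}}")
    bad = df.index[(df["end"] <= df["start"]) | (df["start"] < 0)]
    if len(bad):
        raise FormatError(f"{path}: line {bad[0] + 1}: invalid interval")
    return df
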