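"""Per-gene pause/body densities, pause indices, composite profiles, fold changes.

Densities are counts per bp per library-scale unit.  The default library
scale is counts-per-million (total counts on both strands / 1e6); pass
``scale="none"`` for raw counts per bp.  All windows are 0-based half-open,
so no base is counted in both the pause and the body window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import GeneAnnotation, SignalTrack

__all__ = [
    "window_density",
    "library_scale",
    "summarize",
    "composite_profile",
    "compare_conditions",
]

DEFAULT_PSEUDOCOUNT = 0.25  # counts per window, added before density conversion


def window_density(
    track: SignalTrack, window: tuple[int, int], scale: float = 1.0
) -> float:
    """Sum of counts in [start, end) divided by window length and scale."""
    start, end = window
    if not 0 <= start < end <= track.genome_length:
        raise ValueError(
            f"window [{start}, {end}) out of track bounds [0, {track.genome_length})"
        )
    return float(track.counts[start:end].sum()) / (end - start) / scale


def library_scale(tracks: dict[str, SignalTrack], mode: str = "cpm") -> float:
    """Library normalization factor: total counts/1e6 ('cpm') or 1 ('none')."""
    if mode == "none":
        return 1.0
    if mode == "cpm":
        total = sum(t.total for t in tracks.values())
        if total == 0:
            raise ValueError("cannot CPM-normalize an empty library")
        return total / 1e6
    raise ValueError(f"unknown scale mode {mode!r}")


def summarize(
    tracks: dict[str, SignalTrack],
    genes: list[GeneAnnotation],
    condition: str = "A",
    scale: str = "cpm",
) -> pd.DataFrame:
    """One row per gene: pause/body counts, densities, and pause index.

    The pause index is left NaN where the body density is zero (it is a
    ratio of densities and undefined there).
    """
    if not genes:
        raise ValueError("empty gene set")
    missing = {g.strand for g in genes} - set(tracks)
    if missing:
        raise ValueError(f"missing strand track(s): {sorted(missing)}")
    sf = library_scale(tracks, scale)
    rows = []
    for g in genes:
        track = tracks[g.strand]
        pc = float(track.counts[slice(*g.pause_window)].sum())
        bc = float(track.counts[slice(*g.body_window)].sum())
        pd_ = pc / g.l_p / sf
        bd = bc / g.l_b / sf
        rows.append(
            {
                "gene_id": g.gene_id,
                "condition": condition,
                "is_target": g.is_target,
                "pause_count": pc,
                "body_count": bc,
                "pause_density": pd_,
                "body_density": bd,
                "pause_index": pd_ / bd if bd > 0 else np.nan,
                "l_p": g.l_p,
                "l_b": g.l_b,
                "scale_factor": sf,
            }
        )
    return pd.DataFrame(rows)


def composite_profile(
    tracks: dict[str, SignalTrack],
    genes: list[GeneAnnotation],
    span: tuple[int, int] = (-500, 1500),
    scale: str = "cpm",
) -> pd.DataFrame:
    """Mean normalized density per position relative to the TSS.

    Minus-strand genes are flipped so positive positions point downstream.
    Returns a DataFrame with ``position`` (bp relative to TSS, half-open
    [span[0], span[1])), ``density`` (mean across genes), and ``n_genes``.
    """
    if not genes:
        raise ValueError("empty gene set")
    a, b = span
    if a >= b:
        raise ValueError(f"invalid span {span}")
    sf = library_scale(tracks, scale)
    acc = np.zeros(b - a)
    for g in genes:
        track = tracks[g.strand]
        if g.strand == "+":
            lo, hi = g.tss + a, g.tss + b
            if lo < 0 or hi > track.genome_length:
                raise ValueError(f"{g.gene_id}: span outside track bounds")
            seg = track.counts[lo:hi]
        else:
            # position +d downstream maps to coordinate tss-1-d
            lo, hi = g.tss - b, g.tss - a
            if lo < 0 or hi > track.genome_length:
                raise ValueError(f"{g.gene_id}: span outside track bounds")
            seg = track.counts[lo:hi][::-1]
        acc += seg / sf
    return pd.DataFrame(
        {
            "position": np.arange(a, b),
            "density": acc / len(genes),
            "n_genes": len(genes),
        }
    )


def compare_conditions(
    summary_a: pd.DataFrame,
    summary_b: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene log2 fold changes (B vs A) of pause and body density.

    The pseudocount (in counts per window) regularizes sparse windows
    before density conversion; ``delta_pause_index`` is the difference of
    the two log2 fold changes, so it is exactly antisymmetric under
    swapping A and B.  Raw (un-regularized) densities of both conditions
    are carried through for downstream effect-ratio checks.
    """
    if set(summary_a["gene_id"]) != set(summary_b["gene_id"]):
        raise ValueError("condition summaries cover different gene sets")
    a = summary_a.set_index("gene_id")
    b = summary_b.reindex(columns=summary_b.columns).set_index("gene_id").loc[a.index]

    def eps_density(df: pd.DataFrame, which: str) -> pd.Series:
        length = df["l_p"] if which == "pause" else df["l_b"]
        return (df[f"{which}_count"] + pseudocount) / length / df["scale_factor"]

    lfc_pause = np.log2(eps_density(b, "pause") / eps_density(a, "pause"))
    lfc_body = np.log2(eps_density(b, "body") / eps_density(a, "body"))
    out = pd.DataFrame(
        {
            "gene_id": a.index,
            "is_target": a["is_target"].values,
            "pause_density_a": a["pause_density"].values,
            "pause_density_b": b["pause_density"].values,
            "body_density_a": a["body_density"].values,
            "body_density_b": b["body_density"].values,
            "lfc_pause": lfc_pause.values,
            "lfc_body": lfc_body.values,
        }
    )
    out["delta_pause_index"] = out["lfc_pause"] - out["lfc_body"]
    return out.reset_index(drop=True)
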