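"""End-to-end synthetic pipeline: synth -> quantify -> compare -> infer.

Every run writes a ``provenance.json`` (config echo, seed, package
version) next to its outputs, and is byte-deterministic for a fixed
config.  If the synth-stage outputs already exist in the output directory
a rerun can resume from them instead of regenerating.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import pandas as pd

from . import __version__
from .inference import DEFAULT_TOL_LOG2, aggregate_call, classify_table
from .io import read_bed6, read_bedgraph, write_bed6, write_bedgraph
from .quantify import DEFAULT_PSEUDOCOUNT, compare_conditions, summarize
from .synthetic import (
    GeneAnnotation,
    SignalTrack,
    SyntheticConfig,
    SyntheticDataset,
    generate_dataset,
    generate_decay_timecourse,
    genome_length,
)

__all__ = ["write_dataset", "load_genes", "load_tracks", "run_pipeline"]

_STRAND_SUFFIX = {"+": "plus", "-": "minus"}


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write genes.bed, per-condition/strand bedGraphs, and truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bed6(ds.genes, outdir / "genes.bed")
    for cond, tracks in ds.tracks.items():
        for strand, track in tracks.items():
            name = f"cond{cond}_{_STRAND_SUFFIX[strand]}.bedgraph"
            write_bedgraph(track.counts, track.chrom, outdir / name)
    ds.truth_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)


def load_genes(path: str | Path, config: SyntheticConfig) -> list[GeneAnnotation]:
    """Rebuild gene annotations from a BED6 file plus the window config."""
    df = read_bed6(path)
    ref = config.reference
    l_p, l_b, gap = int(ref.l_p), int(ref.l_b), config.pause_body_gap
    genes = []
    for row in df.itertuples():
        if row.strand == "+":
            tss = int(row.start)
            pause = (tss, tss + l_p)
            body = (tss + l_p + gap, tss + l_p + gap + l_b)
        else:
            tss = int(row.end)
            pause = (tss - l_p, tss)
            body = (tss - l_p - gap - l_b, tss - l_p - gap)
        genes.append(
            GeneAnnotation(
                chrom=row.chrom,
                tss=tss,
                strand=row.strand,
                pause_window=pause,
                body_window=body,
                gene_id=row.name,
                is_target=bool(row.score),
            )
        )
    return genes


def load_tracks(
    outdir: str | Path, condition: str, n: int, chrom: str = "chrS"
) -> dict[str, SignalTrack]:
    """Read the two strand bedGraphs of one condition into SignalTracks."""
    outdir = Path(outdir)
    tracks = {}
    for strand, suffix in _STRAND_SUFFIX.items():
        path = outdir / f"cond{condition}_{suffix}.bedgraph"
        if not path.exists():
            raise FileNotFoundError(f"missing strand track: {path}")
        _, counts = read_bedgraph(path, genome_length=n)
        tracks[strand] = SignalTrack(chrom=chrom, counts=counts)
    return tracks


def run_pipeline(
    config: SyntheticConfig,
    outdir: str | Path,
    scale: str = "cpm",
    tol: float = DEFAULT_TOL_LOG2,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    resume: bool = False,
) -> dict:
    """Run synth -> quantify -> compare -> infer, writing TSVs to ``outdir``.

    With ``resume=True`` and existing genes.bed/bedGraph files, the synth
    stage is skipped and the downstream stages run from the files on disk.
    Returns a small result dict (aggregate call + output paths).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = genome_length(config)

    synth_outputs = [outdir / "genes.bed"] + [
        outdir / f"cond{c}_{s}.bedgraph" for c in "AB" for s in ("plus", "minus")
    ]
    if resume and all(p.exists() for p in synth_outputs):
        genes = load_genes(outdir / "genes.bed", config)
        tracks = {c: load_tracks(outdir, c, n, chrom=config.chrom) for c in "AB"}
    else:
        ds = generate_dataset(config)
        write_dataset(ds, outdir)
        tc = generate_decay_timecourse(1.0, 0.1, 0.02, noise_sd=0.02, seed=config.seed)
        tc.frame().to_csv(outdir / "timecourse.tsv", sep="\t", index=False)
        genes = ds.genes
        tracks = ds.tracks

    summaries = {
        cond: summarize(tracks[cond], genes, condition=cond, scale=scale) for cond in "AB"
    }
    pd.concat(summaries.values()).to_csv(outdir / "densities.tsv", sep="\t", index=False)

    fc = compare_conditions(summaries["A"], summaries["B"], pseudocount=pseudocount)
    fc.to_csv(outdir / "foldchange.tsv", sep="\t", index=False)

    calls = classify_table(fc, tol=tol)
    calls.to_csv(outdir / "mechanisms.tsv", sep="\t", index=False)
    agg = aggregate_call(fc, tol=tol)
    agg_targets = aggregate_call(fc[fc["is_target"]], tol=tol) if fc["is_target"].any() else None

    provenance = {
        "package": "pauseflux",
        "version": __version__,
        "seed": config.seed,
        "scale": scale,
        "tol_log2": tol,
        "pseudocount": pseudocount,
        "config": {
            **{k: v for k, v in config.__dict__.items() if k != "reference"},
            "reference": config.reference.to_dict(),
        },
        "aggregate_call": agg.call,
        "aggregate_call_targets": agg_targets.call if agg_targets else None,
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)

    return {
        "outdir": str(outdir),
        "aggregate": agg,
        "aggregate_targets": agg_targets,
        "fold_changes": fc,
        "calls": calls,
    }
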