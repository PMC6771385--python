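"""Synthetic PRO-seq-like data: gene models, count tracks, decay time courses.

This module is the statistical stand-in for a real nascent-transcription
experiment.  Each synthetic gene carries its own rate constants (log-normal
scatter around a reference parameter set), a short pause window at the TSS
and a long gene-body window downstream.  Per-base expected counts are the
kinetic model's steady-state densities scaled by a sequencing depth D
(expected counts per unit density per bp); observed counts are independent
Poisson draws per base, assigned to the strand of the gene.  Two conditions
are generated: a reference (A) and a perturbed condition (B) in which one
rate constant is scaled by a fold change in a designated fraction of
"target" genes.

Degradation time courses for the decay-fit stage follow a one-phase decay
y(t) = (y0 - plateau) e^{-k t} + plateau sampled every 15 min over 4 h
(17 points), with optional Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import RateParams, steady_state
from .waveform import make_waveform, waveform_density

__all__ = [
    "GeneAnnotation",
    "SignalTrack",
    "SyntheticConfig",
    "DecayTimecourse",
    "SyntheticDataset",
    "generate_genes",
    "expected_profile",
    "build_expected_tracks",
    "sample_counts",
    "generate_dataset",
    "generate_decay_timecourse",
]

DEFAULT_REFERENCE = RateParams(k_init=1.0, k_pre=0.5, k_rel=0.5, k_term=1.0)


@dataclass(frozen=True)
class GeneAnnotation:
    """One synthetic gene: TSS, strand, pause and body windows (0-based half-open)."""

    chrom: str
    tss: int
    strand: str
    pause_window: tuple[int, int]
    body_window: tuple[int, int]
    gene_id: str
    is_target: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        p0, p1 = self.pause_window
        b0, b1 = self.body_window
        if not (p0 < p1 and b0 < b1):
            raise ValueError("windows must be non-empty half-open intervals")
        if max(p0, b0) < min(p1, b1):
            raise ValueError("pause and body windows must not overlap")
        downstream_ok = b0 >= p1 if self.strand == "+" else b1 <= p0
        if not downstream_ok:
            raise ValueError("body window must lie downstream of the pause window")

    @property
    def l_p(self) -> int:
        return self.pause_window[1] - self.pause_window[0]

    @property
    def l_b(self) -> int:
        return self.body_window[1] - self.body_window[0]


@dataclass
class SignalTrack:
    """Per-base non-negative counts for one strand of one chromosome."""

    chrom: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def genome_length(self) -> int:
        return self.counts.size

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``rate_sigma`` is the log-scale SD of per-gene multiplicative scatter
    applied to each rate constant independently; ``perturb_parameter`` /
    ``perturb_fold`` define condition B at the target genes; ``depth`` is
    D, expected counts per unit model density per bp.
    """

    n_genes: int = 200
    fraction_targets: float = 0.3
    reference: RateParams = DEFAULT_REFERENCE
    rate_sigma: float = 0.25
    perturb_parameter: str = "k_pre"
    perturb_fold: float = 1.6
    depth: float = 100.0
    seed: int = 0
    chrom: str = "chrS"
    pause_body_gap: int = 500
    intergenic: int = 1000
    profile_mode: str = "flat"  # "flat" or "waveform"
    waveform_tau: float = 25.0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 <= self.fraction_targets <= 1:
            raise ValueError("fraction_targets must be in [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.profile_mode not in ("flat", "waveform"):
            raise ValueError(f"unknown profile_mode {self.profile_mode!r}")


def generate_genes(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneAnnotation], dict[str, RateParams]]:
    """Lay genes along one synthetic chromosome and draw per-gene rates.

    Genes alternate strands, each occupying l_p + gap + l_b bases with
    ``intergenic`` flanks.  Per-gene rate constants are the reference
    values times independent log-normal factors (median-preserving,
    sigma = ``rate_sigma``).  A ``fraction_targets`` subset is flagged as
    perturbation targets.  Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ref = config.reference
    l_p, l_b = int(ref.l_p), int(ref.l_b)
    span = l_p + config.pause_body_gap + l_b
    stride = span + config.intergenic
    genes: list[GeneAnnotation] = []
    params: dict[str, RateParams] = {}
    is_target = rng.random(config.n_genes) < config.fraction_targets
    for i in range(config.n_genes):
        s = config.intergenic + i * stride
        gene_id = f"gene_{i:04d}"
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            tss = s
            pause = (tss, tss + l_p)
            body = (tss + l_p + config.pause_body_gap, tss + span)
        else:
            tss = s + span
            pause = (tss - l_p, tss)
            body = (s, s + l_b)
        genes.append(
            GeneAnnotation(
                chrom=config.chrom,
                tss=tss,
                strand=strand,
                pause_window=pause,
                body_window=body,
                gene_id=gene_id,
                is_target=bool(is_target[i]),
            )
        )
        factors = np.exp(rng.normal(0.0, config.rate_sigma, size=4))
        params[gene_id] = RateParams(
            k_init=ref.k_init * factors[0],
            k_pre=ref.k_pre * factors[1],
            k_rel=ref.k_rel * factors[2],
            k_term=ref.k_term * factors[3],
            l_p=ref.l_p,
            l_b=ref.l_b,
        )
    return genes, params


def genome_length(config: SyntheticConfig) -> int:
    ref = config.reference
    span = int(ref.l_p) + config.pause_body_gap + int(ref.l_b)
    return config.intergenic + config.n_genes * (span + config.intergenic)


def expected_profile(
    gene: GeneAnnotation,
    params: RateParams,
    depth: float,
    mode: str = "flat",
    tau: float = 25.0,
) -> tuple[int, np.ndarray]:
    """Per-base expected counts over the gene's footprint.

    Returns (offset, values) where values cover
    [offset, offset + len(values)) on the gene's strand track.

    In ``flat`` mode the pause window gets D*p_ss per base and the body
    window D*b_ss, so windows integrate to D*p_ss*l_p and D*b_ss*l_b and
    their density ratio is the gene's pause index for any D.  In
    ``waveform`` mode the footprint is shaped by the calibrated
    peak/plateau curve (peak D*p_ss, plateau D*b_ss) as a function of
    distance from the TSS.
    """
    ss = steady_state(params)
    lo = min(gene.pause_window[0], gene.body_window[0])
    hi = max(gene.pause_window[1], gene.body_window[1])
    values = np.zeros(hi - lo)
    if mode == "flat":
        p0, p1 = gene.pause_window
        b0, b1 = gene.body_window
        values[p0 - lo : p1 - lo] = depth * ss.p_ss
        values[b0 - lo : b1 - lo] = depth * ss.b_ss
    elif mode == "waveform":
        if depth > 0 and ss.p_ss > ss.b_ss > 0:
            wf = make_waveform(ss.p_ss, ss.b_ss, tau=tau)
            # distance from TSS along the direction of transcription
            pos = np.arange(lo, hi)
            dist = (pos - gene.tss) if gene.strand == "+" else (gene.tss - 1 - pos)
            dist = np.clip(dist, 0, None).astype(float)
            values = depth * waveform_density(dist, wf)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return lo, values


def build_expected_tracks(
    genes: list[GeneAnnotation],
    params: dict[str, RateParams],
    config: SyntheticConfig,
) -> dict[str, np.ndarray]:
    """Dense expected-count vectors for both strands."""
    n = genome_length(config)
    tracks = {"+": np.zeros(n), "-": np.zeros(n)}
    for gene in genes:
        lo, values = expected_profile(
            gene,
            params[gene.gene_id],
            config.depth,
            mode=config.profile_mode,
            tau=config.waveform_tau,
        )
        tracks[gene.strand][lo : lo + values.size] += values
    return tracks


def sample_counts(
    expected: dict[str, np.ndarray],
    rng: np.random.Generator,
    chrom: str = "chrS",
) -> dict[str, SignalTrack]:
    """Independent Poisson draws per base; one SignalTrack per strand."""
    out = {}
    for strand, mu in expected.items():
        mu = np.asarray(mu, dtype=float)
        if not np.all(np.isfinite(mu)) or (mu < 0).any():
            raise ValueError("expected counts must be finite and non-negative")
        out[strand] = SignalTrack(chrom=chrom, counts=rng.poisson(mu))
    return out


@dataclass
class SyntheticDataset:
    """Everything one simulated two-condition experiment produced."""

    config: SyntheticConfig
    genes: list[GeneAnnotation]
    params_a: dict[str, RateParams]
    params_b: dict[str, RateParams]
    tracks: dict[str, dict[str, SignalTrack]] = field(default_factory=dict)

    def truth_frame(self) -> pd.DataFrame:
        """Per-gene true parameters and steady states for both conditions."""
        rows = []
        for g in self.genes:
            for cond, pmap in (("A", self.params_a), ("B", self.params_b)):
                pr = pmap[g.gene_id]
                ss = steady_state(pr)
                rows.append(
                    {
                        "gene_id": g.gene_id,
                        "condition": cond,
                        "is_target": g.is_target,
                        **pr.to_dict(),
                        "p_ss": ss.p_ss,
                        "b_ss": ss.b_ss,
                        "pause_index": ss.pause_index,
                    }
                )
        return pd.DataFrame(rows)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Full two-condition experiment: genes, truth, Poisson count tracks.

    Condition A uses each gene's own rates; condition B scales
    ``perturb_parameter`` by ``perturb_fold`` at target genes only.
    Byte-identical output for a fixed config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    genes, params_a = generate_genes(config, rng)
    params_b = {
        g.gene_id: (
            params_a[g.gene_id].perturb(config.perturb_parameter, config.perturb_fold)
            if g.is_target
            else params_a[g.gene_id]
        )
        for g in genes
    }
    ds = SyntheticDataset(config=config, genes=genes, params_a=params_a, params_b=params_b)
    for cond, pmap in (("A", params_a), ("B", params_b)):
        expected = build_expected_tracks(genes, pmap, config)
        ds.tracks[cond] = sample_counts(expected, rng, chrom=config.chrom)
    return ds


@dataclass(frozen=True)
class DecayTimecourse:
    """A degradation time course plus (when synthetic) its true parameters."""

    time: np.ndarray
    signal: np.ndarray
    y0: float | None = None
    plateau: float | None = None
    k: float | None = None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "signal": self.signal})


def generate_decay_timecourse(
    y0: float,
    plateau: float,
    k: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
    t_max: float = 240.0,
    dt: float = 15.0,
) -> DecayTimecourse:
    """One-phase decay sampled every ``dt`` min over ``t_max`` min.

    Defaults mimic a degradation assay sampled every 15 min for 4 h
    (17 points, 0-240 min inclusive).  Gaussian noise with SD ``noise_sd``
    is added when requested.
    """
    if not y0 > plateau >= 0:
        raise ValueError(f"need y0 > plateau >= 0, got y0={y0}, plateau={plateau}")
    if k < 0:
        raise ValueError(f"decay rate k must be >= 0, got {k}")
    t = np.arange(0.0, t_max + dt / 2, dt)
    y = (y0 - plateau) * np.exp(-k * t) + plateau
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=t.size)
    return DecayTimecourse(time=t, signal=y, y0=y0, plateau=plateau, k=k)
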