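"""Smooth pause-peak / gene-body-plateau profile for visualizing steady states.

The profile is a sum of exponentials in the genomic coordinate bp >= 0:

    density(bp) = (pk_pause / pk) * [ (bp/tau) e^{-(bp-tau)/tau}
                                      + pk_body (1 - e^{-bp/tau}) ]

The first term is a surge that rises from zero, peaks near bp = tau and
decays; the second rises monotonically to pk_body.  ``pk`` normalizes the
bracket by its own maximum so the curve's peak equals ``pk_pause``; the
asymptote is then pk_body * pk_pause / pk.  Setting the peak to a
condition's steady-state pause density and the plateau to its gene-body
density turns a (p_ss, b_ss) pair into a recognizable nascent-transcription
profile: a sharp promoter-proximal peak over a long low plateau.

The derivative root gives the peak position in closed form:

    bp* = tau * (pk_body + e) / e

and ``pk`` is the bracket evaluated at bp*.  Choosing pk_body for a desired
plateau is an implicit (fixed-point) problem because pk depends on pk_body;
``solve_pk_body`` solves it by bracketed root finding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import SteadyState

__all__ = [
    "WaveformParams",
    "waveform_density",
    "peak_location",
    "calibrate_pk",
    "solve_pk_body",
    "make_waveform",
    "render_condition_profiles",
]

DEFAULT_TAU = 25.0  # bp; keeps the peak well inside a <100-bp pause window


@dataclass(frozen=True)
class WaveformParams:
    """Calibrated waveform shape: peak ``pk_pause`` at bp*, plateau at plateau_target."""

    tau: float
    pk_pause: float
    pk_body: float
    pk: float
    plateau_target: float


def _bracket(bp: np.ndarray | float, tau: float, pk_body: float):
    """Unnormalized waveform bracket (surge term + plateau term)."""
    bp = np.asarray(bp, dtype=float)
    surge = (bp / tau) * np.exp(-(bp - tau) / tau)
    plateau = pk_body * (1.0 - np.exp(-bp / tau))
    return surge + plateau


def waveform_density(bp, wf: WaveformParams):
    """Evaluate the calibrated waveform at position(s) bp >= 0.

    density(0) = 0 and density -> pk_body*pk_pause/pk as bp -> infinity.
    """
    arr = np.asarray(bp, dtype=float)
    if np.any(arr < 0):
        raise ValueError("bp must be non-negative")
    out = (wf.pk_pause / wf.pk) * _bracket(arr, wf.tau, wf.pk_body)
    return float(out) if np.isscalar(bp) or arr.ndim == 0 else out


def peak_location(tau: float, pk_body: float) -> float:
    """Closed-form root of the waveform derivative: bp* = tau*(pk_body + e)/e."""
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    if pk_body < 0:
        raise ValueError(f"pk_body must be >= 0, got {pk_body}")
    return tau * (pk_body + math.e) / math.e


def calibrate_pk(tau: float, pk_body: float) -> float:
    """Normalization pk = bracket value at the peak, so max(density) = pk_pause."""
    return float(_bracket(peak_location(tau, pk_body), tau, pk_body))


def solve_pk_body(
    plateau_target: float, pk_pause: float, tau: float, tol: float = 1e-10
) -> float:
    """Find pk_body so the calibrated asymptote equals ``plateau_target``.

    The asymptote is pk_body*pk_pause/pk(pk_body), with pk itself depending
    on pk_body through the peak position, so this is an implicit root
    problem.  The asymptote/peak ratio grows monotonically from 0 (at
    pk_body = 0) toward 1, hence a solution exists iff
    0 < plateau_target < pk_pause.
    """
    if not 0 < plateau_target < pk_pause:
        raise ValueError(
            f"need 0 < plateau_target < pk_pause, got {plateau_target} vs {pk_pause}"
        )
    target_ratio = plateau_target / pk_pause

    def f(pk_body: float) -> float:
        return pk_body / calibrate_pk(tau, pk_body) - target_ratio

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - ratio < 1 always brackets
            raise RuntimeError("failed to bracket pk_body root")
    return float(brentq(f, 0.0, hi, xtol=tol, rtol=8.9e-16))


def make_waveform(
    pk_pause: float, plateau_target: float, tau: float = DEFAULT_TAU
) -> WaveformParams:
    """Calibrated waveform with peak ``pk_pause`` and asymptote ``plateau_target``."""
    pk_body = solve_pk_body(plateau_target, pk_pause, tau)
    return WaveformParams(
        tau=tau,
        pk_pause=pk_pause,
        pk_body=pk_body,
        pk=calibrate_pk(tau, pk_body),
        plateau_target=plateau_target,
    )


def render_condition_profiles(
    conditions: dict[str, SteadyState],
    tau: float = DEFAULT_TAU,
    length: int = 2000,
) -> pd.DataFrame:
    """One calibrated curve per condition, sampled at 1-bp steps.

    Each condition's curve peaks at its steady-state pause density and
    plateaus at its gene-body density, so the max/asymptote ratio of every
    curve equals that condition's pause index.  Requires p_ss > b_ss > 0
    (a peak below its plateau cannot be drawn with this shape).

    Returns a DataFrame with column ``bp`` plus one density column per
    condition label.
    """
    if not conditions:
        raise ValueError("need at least one condition")
    bp = np.arange(0, length + 1, dtype=float)
    out = {"bp": bp}
    for label, ss in conditions.items():
        if not ss.p_ss > ss.b_ss > 0:
            raise ValueError(
                f"condition {label!r}: need p_ss > b_ss > 0, "
                f"got p_ss={ss.p_ss}, b_ss={ss.b_ss}"
            )
        wf = make_waveform(ss.p_ss, ss.b_ss, tau=tau)
        out[label] = waveform_density(bp, wf)
    return pd.DataFrame(out)
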