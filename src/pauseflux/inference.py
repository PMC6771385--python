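"""Mechanism inference from density changes, and one-phase decay fitting.

The sensitivity sign table makes observed pause/body density changes
informative about which rate constant moved:

    pause ~0, body down  -> termination up
    pause ~0, body up    -> termination down
    pause down, body up  -> productive release up
    pause up, body down  -> productive release down
    both down            -> initiation down OR premature release up
    both up              -> initiation up OR premature release down

The last two classes are genuinely unresolvable from the two densities
alone: a change in k_init and an opposite change in k_pre produce identical
steady-state signatures (both scale p_ss and b_ss by a common factor, with
effect ratio Δp/Δb equal to the pause index).  The classifier therefore
reports the equivalence class, never a single rate, plus a consistency flag
recording whether the observed effect ratio matches the reference pause
index as the model predicts.

``fit_one_phase_decay`` fits y(t) = (y0 - plateau) e^{-kt} + plateau by
bounded nonlinear least squares (multi-start), the standard model for
quantifying degradation kinetics of a tagged protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .synthetic import DecayTimecourse

__all__ = [
    "MechanismCall",
    "DecayFit",
    "classify_mechanism",
    "classify_table",
    "aggregate_call",
    "estimate_rate_change",
    "fit_one_phase_decay",
]

DEFAULT_TOL_LOG2 = 0.2  # |log2 FC| below this counts as "unchanged"

_CALL_BY_SIGNS = {
    (0, 0): "none",
    (0, -1): "term_up",
    (0, 1): "term_down",
    (-1, 1): "rel_up",
    (1, -1): "rel_down",
    (-1, -1): "init_down_or_pre_up",
    (1, 1): "init_up_or_pre_down",
    # pause moved but body flat: no single-parameter mechanism fits
    (-1, 0): "none",
    (1, 0): "none",
}


@dataclass(frozen=True)
class MechanismCall:
    """Mechanism class implied by one gene's (or the aggregate) density changes."""

    gene_id: str
    sign_p: str
    sign_b: str
    call: str
    effect_ratio_observed: float
    pause_index_reference: float
    consistent: bool


def _thresholded_sign(x: float, tol: float) -> int:
    return 0 if abs(x) <= tol else (1 if x > 0 else -1)


def classify_mechanism(
    lfc_pause: float,
    lfc_body: float,
    p_i_ref: float,
    tol: float = DEFAULT_TOL_LOG2,
    gene_id: str = "aggregate",
    delta_p: float = math.nan,
    delta_b: float = math.nan,
    ratio_rtol: float = 0.2,
) -> MechanismCall:
    """Map a (pause, body) log2-fold-change pair to a mechanism class.

    ``tol`` is the log2 half-width of the "unchanged" band.  When absolute
    density changes ``delta_p``/``delta_b`` are supplied and the call is an
    initiation/premature class, the observed effect ratio Δp/Δb is compared
    with ``p_i_ref`` (relative tolerance ``ratio_rtol``) and reported in
    ``consistent``.
    """
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    if not (np.isfinite(lfc_pause) and np.isfinite(lfc_body)):
        raise ValueError("fold changes must be finite")
    if p_i_ref <= 0:
        raise ValueError(f"reference pause index must be > 0, got {p_i_ref}")
    sp = _thresholded_sign(lfc_pause, tol)
    sb = _thresholded_sign(lfc_body, tol)
    call = _CALL_BY_SIGNS[(sp, sb)]
    ratio = delta_p / delta_b if np.isfinite(delta_b) and delta_b != 0 else math.nan
    consistent = False
    if call in ("init_down_or_pre_up", "init_up_or_pre_down") and np.isfinite(ratio):
        consistent = abs(ratio - p_i_ref) <= ratio_rtol * p_i_ref
    sign_char = {1: "+", -1: "-", 0: "0"}
    return MechanismCall(
        gene_id=gene_id,
        sign_p=sign_char[sp],
        sign_b=sign_char[sb],
        call=call,
        effect_ratio_observed=ratio,
        pause_index_reference=p_i_ref,
        consistent=consistent,
    )


def _call_row(row, p_i_ref: float, tol: float, ratio_rtol: float) -> MechanismCall:
    return classify_mechanism(
        row.lfc_pause,
        row.lfc_body,
        p_i_ref,
        tol=tol,
        gene_id=row.gene_id,
        delta_p=row.pause_density_b - row.pause_density_a,
        delta_b=row.body_density_b - row.body_density_a,
        ratio_rtol=ratio_rtol,
    )


def classify_table(
    fold_changes: pd.DataFrame,
    p_i_ref: float | None = None,
    tol: float = DEFAULT_TOL_LOG2,
    ratio_rtol: float = 0.2,
) -> pd.DataFrame:
    """Per-gene mechanism calls for a ``compare_conditions`` table.

    ``p_i_ref`` defaults to the median reference-condition pause index of
    the analyzed genes (pause_density_a / body_density_a).
    """
    if p_i_ref is None:
        with np.errstate(divide="ignore", invalid="ignore"):
            pis = fold_changes["pause_density_a"] / fold_changes["body_density_a"]
        p_i_ref = float(np.nanmedian(pis.replace([np.inf, -np.inf], np.nan)))
    calls = [_call_row(row, p_i_ref, tol, ratio_rtol) for row in fold_changes.itertuples()]
    return pd.DataFrame([c.__dict__ for c in calls])


def aggregate_call(
    fold_changes: pd.DataFrame,
    p_i_ref: float | None = None,
    tol: float = DEFAULT_TOL_LOG2,
    ratio_rtol: float = 0.2,
) -> MechanismCall:
    """Mechanism call for the gene set as a whole (median fold changes,
    summed density changes)."""
    if p_i_ref is None:
        with np.errstate(divide="ignore", invalid="ignore"):
            pis = fold_changes["pause_density_a"] / fold_changes["body_density_a"]
        p_i_ref = float(np.nanmedian(pis.replace([np.inf, -np.inf], np.nan)))
    return classify_mechanism(
        float(fold_changes["lfc_pause"].median()),
        float(fold_changes["lfc_body"].median()),
        p_i_ref,
        tol=tol,
        gene_id="aggregate",
        delta_p=float((fold_changes["pause_density_b"] - fold_changes["pause_density_a"]).sum()),
        delta_b=float((fold_changes["body_density_b"] - fold_changes["body_density_a"]).sum()),
        ratio_rtol=ratio_rtol,
    )


def estimate_rate_change(
    pause_density_a: float,
    pause_density_b: float,
    assumed_mechanism: str,
) -> float:
    """Fold change of the assumed rate implied by the pause-density ratio.

    Under ``k_init``, p_ss is proportional to k_init, so the estimated fold
    change is the pause-density ratio B/A.  Under
    ``combined_k_pre_plus_k_rel``, p_ss is inversely proportional to the
    release pool (k_pre + k_rel), so the estimate is the inverse ratio A/B.
    The pool members cannot be separated from the two densities alone, so
    no per-rate estimate is offered.
    """
    if pause_density_a <= 0 or pause_density_b <= 0:
        raise ValueError("pause densities must be positive")
    if assumed_mechanism == "k_init":
        return pause_density_b / pause_density_a
    if assumed_mechanism == "combined_k_pre_plus_k_rel":
        return pause_density_a / pause_density_b
    raise ValueError(f"unsupported mechanism {assumed_mechanism!r}")


@dataclass(frozen=True)
class DecayFit:
    """One-phase decay fit: y(t) = (y0 - plateau) e^{-kt} + plateau."""

    y0: float
    plateau: float
    k: float
    half_life: float
    rss: float

    def to_dict(self) -> dict:
        return {
            "y0": self.y0,
            "plateau": self.plateau,
            "k_per_min": self.k,
            "half_life_min": self.half_life,
            "rss": self.rss,
        }


def _decay(t: np.ndarray, amp: float, plateau: float, k: float) -> np.ndarray:
    return amp * np.exp(-k * t) + plateau


def fit_one_phase_decay(
    tc: DecayTimecourse | pd.DataFrame,
    fix_plateau_zero: bool = False,
) -> DecayFit:
    """Bounded least-squares fit of the one-phase decay model.

    Parameterized as (amplitude, plateau, k) with amplitude = y0 - plateau,
    all constrained >= 0, which enforces y0 >= plateau >= 0 and k >= 0.
    Three data-driven starts are tried (initial amplitude/plateau from the
    first/last observations; k from a log-linear fit of the early decay,
    and x10 above/below it) and the lowest-RSS solution is kept.  With
    ``fix_plateau_zero`` the plateau is pinned at 0 (full-degradation
    variant).  The half-life ln2/k refers to decay toward the plateau.
    """
    if isinstance(tc, pd.DataFrame):
        t = tc["time"].to_numpy(dtype=float)
        y = tc["signal"].to_numpy(dtype=float)
    else:
        t, y = np.asarray(tc.time, dtype=float), np.asarray(tc.signal, dtype=float)
    if t.size < 4:
        raise ValueError(f"need at least 4 time points, got {t.size}")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("times and signals must be finite")

    plateau0 = max(float(y[-1]), 0.0) if not fix_plateau_zero else 0.0
    amp0 = max(float(y[0]) - plateau0, 1e-12)
    # crude k from a log-linear fit of the early, above-plateau part
    early = y[: max(t.size // 2, 2)] - plateau0
    mask = early > 0
    if mask.sum() >= 2:
        slope = np.polyfit(t[: early.size][mask], np.log(early[mask]), 1)[0]
        k0 = max(-slope, 1e-6)
    else:
        k0 = 1.0 / max(t[-1], 1.0)

    if fix_plateau_zero:
        model = lambda tt, amp, k: _decay(tt, amp, 0.0, k)  # noqa: E731
        bounds = ([0.0, 0.0], [np.inf, np.inf])
        starts = [(amp0, k) for k in (k0, k0 * 10, k0 / 10)]
    else:
        model = _decay
        bounds = ([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf])
        starts = [(amp0, plateau0, k) for k in (k0, k0 * 10, k0 / 10)]

    best: tuple[float, np.ndarray] | None = None
    errors = []
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                model, t, y, p0=p0, bounds=bounds, maxfev=20000, xtol=1e-14, ftol=1e-14
            )
        except Exception as exc:  # noqa: BLE001 - collect per-start diagnostics
            errors.append(f"start {p0}: {exc}")
            continue
        rss = float(np.sum((model(t, *popt) - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        raise RuntimeError(
            "one-phase decay fit failed from all starts:\n" + "\n".join(errors)
        )
    rss, popt = best
    if fix_plateau_zero:
        amp, k = popt
        plateau = 0.0
    else:
        amp, plateau, k = popt
    return DecayFit(
        y0=float(amp + plateau),
        plateau=float(plateau),
        k=float(k),
        half_life=float(math.log(2) / k) if k > 0 else math.inf,
        rss=rss,
    )
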