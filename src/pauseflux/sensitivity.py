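"""Closed-form parameter sensitivity of the pausing model's steady states.

For each rate constant k the finite change Δp(k) = p_ss[k_hi] − p_ss[k_lo]
(and likewise Δb) has an exact algebraic form because the steady states are
rational in the parameters; no linearization is involved.  The sign pattern
under an increase of each parameter is fixed for any positive parameter set:

    k_init -> (Δp > 0, Δb > 0)     more initiation raises both densities
    k_pre  -> (Δp < 0, Δb < 0)     premature release drains both
    k_rel  -> (Δp < 0, Δb > 0)     productive release moves Pol II downstream
                                    (Δb = 0 exactly when k_pre = 0: with no
                                    premature loss, throughput is set by
                                    k_init alone)
    k_term -> (Δp = 0, Δb < 0)     termination acts downstream of the pause

For perturbations of k_init or k_pre of *any* magnitude the effect ratio
Δp/Δb equals the pause index P_i = k_term/(r k_rel) exactly, and
|Δp| > |Δb| iff k_rel/k_term < l_b/l_p iff P_i > 1.  Because l_b/l_p is
~100 for typical genes, pause-region changes dominate: a coordinate drop in
pause and body densities with ratio P_i is the signature of reduced
initiation or increased premature release.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import RATE_NAMES, InvalidParameterError, RateParams, steady_state

__all__ = [
    "SensitivityResult",
    "EffectRatioReport",
    "delta_p",
    "delta_b",
    "partials",
    "sensitivity_table",
    "effect_ratio",
]


def _check(parameter: str, k_hi: float, k_lo: float) -> None:
    if parameter not in RATE_NAMES:
        raise InvalidParameterError(f"unknown rate parameter {parameter!r}")
    if not k_hi > k_lo:
        raise InvalidParameterError(f"require k_hi > k_lo, got {k_hi} <= {k_lo}")
    lower_ok = k_lo >= 0 if parameter in ("k_init", "k_pre") else k_lo > 0
    if not lower_ok:
        raise InvalidParameterError(f"k_lo={k_lo} out of domain for {parameter}")


def delta_p(params: RateParams, parameter: str, k_hi: float, k_lo: float) -> float:
    """Exact change in steady-state pause density when ``parameter`` goes lo -> hi."""
    _check(parameter, k_hi, k_lo)
    if parameter == "k_init":
        return (k_hi - k_lo) / (params.k_pre + params.k_rel)
    if parameter == "k_pre":
        return params.k_init * (k_lo - k_hi) / ((k_hi + params.k_rel) * (k_lo + params.k_rel))
    if parameter == "k_rel":
        return params.k_init * (k_lo - k_hi) / ((params.k_pre + k_hi) * (params.k_pre + k_lo))
    # k_term does not enter p_ss at all
    return 0.0


def delta_b(params: RateParams, parameter: str, k_hi: float, k_lo: float) -> float:
    """Exact change in steady-state gene-body density when ``parameter`` goes lo -> hi."""
    _check(parameter, k_hi, k_lo)
    r = params.r
    if parameter == "k_init":
        return r * params.k_rel * (k_hi - k_lo) / (params.k_term * (params.k_pre + params.k_rel))
    if parameter == "k_pre":
        return (
            r
            * params.k_rel
            * params.k_init
            * (k_lo - k_hi)
            / (params.k_term * (k_hi + params.k_rel) * (k_lo + params.k_rel))
        )
    if parameter == "k_rel":
        return (
            r
            * params.k_init
            * params.k_pre
            * (k_hi - k_lo)
            / (params.k_term * (params.k_pre + k_hi) * (params.k_pre + k_lo))
        )
    return (
        params.r
        * params.k_init
        * params.k_rel
        * (k_lo - k_hi)
        / (k_hi * k_lo * (params.k_pre + params.k_rel))
    )


def partials(params: RateParams, parameter: str) -> tuple[float, float]:
    """Analytic partial derivatives (d p_ss/dk, d b_ss/dk) at the reference point."""
    if parameter not in RATE_NAMES:
        raise InvalidParameterError(f"unknown rate parameter {parameter!r}")
    pool = params.k_pre + params.k_rel
    r = params.r
    if parameter == "k_init":
        return 1.0 / pool, r * params.k_rel / (params.k_term * pool)
    if parameter == "k_pre":
        dp = -params.k_init / pool**2
        return dp, r * params.k_rel * dp / params.k_term
    if parameter == "k_rel":
        dp = -params.k_init / pool**2
        db = r * params.k_init * params.k_pre / (params.k_term * pool**2)
        return dp, db
    db = -r * params.k_rel * params.k_init / (params.k_term**2 * pool)
    return 0.0, db


def _sign(x: float) -> str:
    return "+" if x > 0 else "-" if x < 0 else "0"


@dataclass(frozen=True)
class SensitivityResult:
    """Finite and infinitesimal sensitivity of (p_ss, b_ss) to one parameter."""

    parameter: str
    k_lo: float
    k_hi: float
    delta_p: float
    delta_b: float
    sign_p: str
    sign_b: str
    partial_p: float
    partial_b: float


def sensitivity(params: RateParams, parameter: str, k_hi: float, k_lo: float) -> SensitivityResult:
    """Full sensitivity record for one perturbed parameter."""
    dp = delta_p(params, parameter, k_hi, k_lo)
    db = delta_b(params, parameter, k_hi, k_lo)
    pp, pb = partials(params, parameter)
    return SensitivityResult(
        parameter=parameter,
        k_lo=k_lo,
        k_hi=k_hi,
        delta_p=dp,
        delta_b=db,
        sign_p=_sign(dp),
        sign_b=_sign(db),
        partial_p=pp,
        partial_b=pb,
    )


def sensitivity_table(params: RateParams, factor: float = 1.25) -> list[SensitivityResult]:
    """One sensitivity row per rate constant, each increased by ``factor``.

    For any positive parameters the sign pattern is
    k_init (+,+), k_pre (-,-), k_rel (-,+), k_term (0,-); the k_rel row
    degenerates to (-,0) when k_pre = 0.
    """
    if factor <= 1:
        raise InvalidParameterError(f"factor must be > 1, got {factor}")
    rows = []
    for name in RATE_NAMES:
        k_lo = getattr(params, name)
        if k_lo == 0:
            # a zero rate cannot be scaled up; perturb additively by the
            # mean of the other rates so the row is still informative
            others = [getattr(params, n) for n in RATE_NAMES if n != name]
            k_hi = (factor - 1) * sum(others) / len(others)
        else:
            k_hi = k_lo * factor
        rows.append(sensitivity(params, name, k_hi, k_lo))
    return rows


def table_frame(rows: list[SensitivityResult]) -> pd.DataFrame:
    """Sensitivity rows as a tidy DataFrame (for TSV export)."""
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass(frozen=True)
class EffectRatioReport:
    """Δp/Δb for a k_init or k_pre perturbation, against the pause index."""

    parameter: str
    ratio: float
    pause_index: float
    condition_met: bool


def effect_ratio(params: RateParams, parameter: str, k_hi: float, k_lo: float) -> EffectRatioReport:
    """Effect ratio Δp/Δb for an initiation or premature-release change.

    The ratio equals the pause index exactly, for perturbations of any
    magnitude; ``condition_met`` records whether k_rel/k_term < l_b/l_p,
    i.e. whether the pause-region effect exceeds the gene-body effect.
    Only k_init and k_pre are supported: for k_term the ratio is trivially
    zero, and for k_rel the two densities move in opposite directions so a
    single ratio is not the relevant summary.
    """
    if parameter not in ("k_init", "k_pre"):
        raise InvalidParameterError(
            f"effect ratio is defined for k_init and k_pre perturbations, got {parameter!r}"
        )
    dp = delta_p(params, parameter, k_hi, k_lo)
    db = delta_b(params, parameter, k_hi, k_lo)
    if db == 0:
        raise InvalidParameterError("delta_b is zero; effect ratio undefined")
    p_i = steady_state(params).pause_index
    condition = params.k_rel / params.k_term < params.l_b / params.l_p
    return EffectRatioReport(
        parameter=parameter, ratio=dp / db, pause_index=p_i, condition_met=condition
    )
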