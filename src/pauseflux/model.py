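"""Two-compartment kinetic model of promoter-proximal Pol II pausing.

The model tracks two densities (polymerases per bp of DNA): ``p``, the
density in the short promoter-proximal pause region, and ``b``, the density
in the long gene body.  Four first-order rate constants drive the dynamics:

    dp/dt = k_init - (k_pre + k_rel) * p
    db/dt = r * k_rel * p - k_term * b

where ``k_init`` is the initiation rate (it folds in free-Pol II
concentration), ``k_pre`` is premature (non-productive) pause release,
``k_rel`` is productive release into gene-body elongation, ``k_term`` is
termination, and ``r = l_p / l_b`` rescales the flux for the length
difference between the two compartments.  Units are dimensionless; the
model is used for ratios and relative changes, not absolute rates.

At steady state,

    p_ss = k_init / (k_pre + k_rel)
    b_ss = r * k_rel * p_ss / k_term

and the pause index P_i = p_ss / b_ss = k_term / (r * k_rel) depends only on
termination, productive release, and the length ratio.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "RateParams",
    "PolState",
    "SteadyState",
    "InvalidParameterError",
    "steady_state",
    "simulate_dynamics",
    "pause_index",
]

RATE_NAMES = ("k_init", "k_pre", "k_rel", "k_term")


class InvalidParameterError(ValueError):
    """Raised when rate constants or segment lengths are out of domain."""


@dataclass(frozen=True)
class RateParams:
    """Rate constants and segment lengths of the pausing model.

    ``k_init`` and ``k_pre`` may be zero (no initiation / no premature
    release are both analyzed limits); ``k_rel`` and ``k_term`` must be
    positive so that steady states and the pause index are defined.
    ``r`` is always derived from ``l_p``/``l_b`` and never set directly.
    """

    k_init: float
    k_pre: float
    k_rel: float
    k_term: float
    l_p: float = 100.0
    l_b: float = 10_000.0

    def __post_init__(self) -> None:
        if not (self.k_init >= 0 and math.isfinite(self.k_init)):
            raise InvalidParameterError(f"k_init must be >= 0, got {self.k_init}")
        if not (self.k_pre >= 0 and math.isfinite(self.k_pre)):
            raise InvalidParameterError(f"k_pre must be >= 0, got {self.k_pre}")
        if not (self.k_rel > 0 and math.isfinite(self.k_rel)):
            raise InvalidParameterError(f"k_rel must be > 0, got {self.k_rel}")
        if not (self.k_term > 0 and math.isfinite(self.k_term)):
            raise InvalidParameterError(f"k_term must be > 0, got {self.k_term}")
        if not (0 < self.l_p < self.l_b):
            raise InvalidParameterError(
                f"require 0 < l_p < l_b, got l_p={self.l_p}, l_b={self.l_b}"
            )

    @property
    def r(self) -> float:
        """Length ratio l_p / l_b (dimensionless)."""
        return self.l_p / self.l_b

    def perturb(self, parameter: str, factor: float) -> "RateParams":
        """Return a copy with one rate constant multiplied by ``factor``."""
        if parameter not in RATE_NAMES:
            raise InvalidParameterError(f"unknown rate parameter {parameter!r}")
        return replace(self, **{parameter: getattr(self, parameter) * factor})

    @classmethod
    def from_json(cls, path: str | Path) -> "RateParams":
        """Load from a flat JSON file with keys k_init, k_pre, k_rel, k_term, l_p, l_b."""
        with open(path) as fh:
            raw = json.load(fh)
        known = {"k_init", "k_pre", "k_rel", "k_term", "l_p", "l_b"}
        return cls(**{k: float(v) for k, v in raw.items() if k in known})

    def to_dict(self) -> dict:
        return {
            "k_init": self.k_init,
            "k_pre": self.k_pre,
            "k_rel": self.k_rel,
            "k_term": self.k_term,
            "l_p": self.l_p,
            "l_b": self.l_b,
        }


@dataclass(frozen=True)
class PolState:
    """Pol II densities at one time point."""

    t: float
    p: float
    b: float


@dataclass(frozen=True)
class SteadyState:
    """Closed-form steady state of the model."""

    p_ss: float
    b_ss: float
    pause_index: float


def steady_state(params: RateParams) -> SteadyState:
    """Closed-form steady state (p_ss, b_ss) and pause index.

    p_ss = k_init/(k_pre + k_rel); b_ss = r*k_rel*p_ss/k_term;
    P_i = k_term/(r*k_rel), which is independent of k_init and k_pre.
    """
    denom = params.k_pre + params.k_rel
    if denom <= 0:
        raise InvalidParameterError("k_pre + k_rel must be > 0")
    if params.k_term <= 0:
        raise InvalidParameterError("k_term must be > 0")
    p_ss = params.k_init / denom
    b_ss = params.r * params.k_rel * p_ss / params.k_term
    p_i = params.k_term / (params.r * params.k_rel)
    return SteadyState(p_ss=p_ss, b_ss=b_ss, pause_index=p_i)


def pause_index(p: float, b: float) -> float:
    """Ratio of pause-region to gene-body density, P_i = p/b.

    Raises if the gene-body density is not positive.
    """
    if b <= 0:
        raise ValueError(f"gene-body density must be > 0 to form a pause index, got {b}")
    return p / b


def simulate_dynamics(
    params: RateParams,
    init: PolState | tuple[float, float],
    t_grid: Sequence[float] | np.ndarray,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> pd.DataFrame:
    """Integrate the linear ODE system on a strictly increasing time grid.

    Parameters
    ----------
    init
        Initial (p, b) densities, both >= 0, as a ``PolState`` or tuple.
    t_grid
        Strictly increasing times; the first entry is the initial time.

    Returns
    -------
    DataFrame with columns ``t``, ``p``, ``b``, one row per grid point.
    The trajectory converges to ``steady_state(params)`` as t grows.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValueError("t_grid must be a non-empty 1-D sequence")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("t_grid must be strictly increasing")
    if isinstance(init, PolState):
        p0, b0 = init.p, init.b
    else:
        p0, b0 = init
    if p0 < 0 or b0 < 0:
        raise ValueError("initial densities must be non-negative")

    k_out = params.k_pre + params.k_rel
    flux = params.r * params.k_rel

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        p, b = y
        return [params.k_init - k_out * p, flux * p - params.k_term * b]

    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        [p0, b0],
        t_eval=t,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:  # pragma: no cover - linear system, LSODA is robust
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return pd.DataFrame({"t": sol.t, "p": sol.y[0], "b": sol.y[1]})


def states_from_trajectory(traj: pd.DataFrame) -> list[PolState]:
    """View a trajectory DataFrame as a list of PolState records."""
    return [PolState(t=row.t, p=row.p, b=row.b) for row in traj.itertuples()]
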