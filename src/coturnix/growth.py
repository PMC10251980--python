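"""Gompertz growth-curve fitting and inflection-point functionals.

The growth of each bird is modelled as

    y(t) = beta0 * exp(-beta1 * exp(-beta2 * t))

with asymptotic (mature) weight ``beta0`` (g), scaling constant
``beta1`` (dimensionless, the constant of integration) and instantaneous
growth rate ``beta2`` (per day).  The curve inflects at age
``IPT = ln(beta1)/beta2`` days, where the weight is ``IPW = beta0/e`` g.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "GompertzParams",
    "InflectionPoint",
    "GrowthFit",
    "gompertz_value",
    "fit_gompertz",
    "fit_gompertz_batch",
    "inflection_point",
    "r_squared",
]

# Lower bounds keep the optimizer away from degenerate flat/negative
# curves: 1 g asymptote, 1e-3 scaling, 1e-4 /day rate.
_LOWER_BOUNDS = (1.0, 1e-3, 1e-4)
_MAX_ITER = 500
_FTOL = 1e-10


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz parameters; all strictly positive."""

    beta0: float  # asymptotic weight, g
    beta1: float  # scaling constant
    beta2: float  # instantaneous growth rate, /day

    def __post_init__(self):
        for name in ("beta0", "beta1", "beta2"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2])


@dataclass(frozen=True)
class InflectionPoint:
    ipt: float  # age at inflection, days (negative if beta1 < 1)
    ipw: float  # weight at inflection, g


@dataclass(frozen=True)
class GrowthFit:
    params: GompertzParams
    r_squared: float
    converged: bool
    n_points: int
    message: str = ""


def gompertz_value(params: GompertzParams, t):
    """Gompertz curve weight at age ``t`` (days; scalar or array)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age must be non-negative")
    return params.beta0 * np.exp(-params.beta1 * np.exp(-params.beta2 * t))


def inflection_point(params: GompertzParams) -> InflectionPoint:
    """Inflection coordinates: ``ipw = beta0/e``, ``ipt = ln(beta1)/beta2``.

    ``ipt`` is reported as-is (negative when ``beta1 < 1``, i.e. the
    inflection precedes hatch), never clipped.
    """
    return InflectionPoint(
        ipt=math.log(params.beta1) / params.beta2,
        ipw=params.beta0 / math.e,
    )


def r_squared(observed, fitted) -> float:
    """Coefficient of determination, 1 - SSE/SST (SST about the mean)."""
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape or obs.size < 2:
        raise ValueError("need two equal-length vectors of >= 2 points")
    sst = np.sum((obs - obs.mean()) ** 2)
    if sst == 0:
        raise ValueError("observed values are constant; R^2 undefined")
    return 1.0 - np.sum((obs - fit) ** 2) / sst


def _self_start(ages: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Initial values: beta0 from the data ceiling, beta2 from the slope
    of the double-log linearization, beta1 from the hatch-weight ratio."""
    b0 = 1.2 * weights.max()
    ratio = np.clip(weights / b0, 1e-10, 1 - 1e-10)
    z = np.log(-np.log(ratio))  # = ln(beta1) - beta2 * t
    slope, intercept = np.polyfit(ages, z, 1)
    b2 = max(-slope, _LOWER_BOUNDS[2] * 10)
    b1 = max(np.exp(intercept), _LOWER_BOUNDS[1] * 10)
    return np.array([b0, b1, b2])


def fit_gompertz(ages, weights, init: GompertzParams | None = None) -> GrowthFit:
    """Least-squares Gompertz fit for a single bird.

    Uses a damped Gauss-Newton (trust-region-reflective) iteration with
    the self-start described in :func:`_self_start`.  Non-convergence is
    reported via the ``converged`` flag and ``message``, never silently.

    Parameters
    ----------
    ages, weights
        Matched vectors; at least 4 distinct ages, all weights > 0.
    init
        Optional starting parameters overriding the self-start.
    """
    ages = np.asarray(ages, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if ages.shape != weights.shape:
        raise ValueError("ages and weights must have equal length")
    if len(np.unique(ages)) < 4:
        raise ValueError("need at least 4 distinct ages to fit 3 parameters")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")

    if init is not None:
        x0 = init.as_array()
    else:
        x0 = _self_start(ages, weights)
    x0 = np.maximum(x0, np.asarray(_LOWER_BOUNDS) * (1 + 1e-9))

    def residual(x):
        return x[0] * np.exp(-x[1] * np.exp(-x[2] * ages)) - weights

    res = least_squares(
        residual,
        x0,
        bounds=(_LOWER_BOUNDS, np.inf),
        method="trf",
        ftol=_FTOL,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=_MAX_ITER * 4,
    )
    params = GompertzParams(*np.maximum(res.x, _LOWER_BOUNDS))
    at_bound = np.any(np.isclose(res.x, _LOWER_BOUNDS, rtol=1e-6))
    converged = bool(res.success) and not at_bound
    try:
        r2 = r_squared(weights, residual(res.x) + weights)
    except ValueError:
        r2 = 0.0
        converged = False
    msg = res.message if not converged else ""
    if at_bound:
        msg = (msg + "; " if msg else "") + "parameter at lower bound"
    return GrowthFit(
        params=params,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        converged=converged,
        n_points=len(ages),
        message=msg,
    )


def fit_gompertz_batch(weights_long: pd.DataFrame) -> pd.DataFrame:
    """Fit every bird in a long-format weekly-weights table.

    Parameters
    ----------
    weights_long
        Columns ``id, age_days, weight_g`` (the dialect written by the
        synthetic-flock generator).

    Returns
    -------
    DataFrame indexed by ``id`` with columns ``beta0 beta1 beta2 IPT IPW
    r_squared converged``.
    """
    rows = []
    for bird, grp in weights_long.groupby("id", sort=False):
        fit = fit_gompertz(grp["age_days"], grp["weight_g"])
        ip = inflection_point(fit.params)
        rows.append(
            {
                "id": bird,
                "beta0": fit.params.beta0,
                "beta1": fit.params.beta1,
                "beta2": fit.params.beta2,
                "IPT": ip.ipt,
                "IPW": ip.ipw,
                "r_squared": fit.r_squared,
                "converged": fit.converged,
            }
        )
    if not rows:
        raise ValueError("no birds in table")
    out = pd.DataFrame(rows).set_index("id")
    n_bad = int((~out["converged"]).sum())
    if n_bad:
        warnings.warn(f"{n_bad} bird(s) did not converge", stacklevel=2)
    return out
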