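"""First-order organic-matter degradation kinetics.

Model: OM loss(%) = A * (1 - exp(-k t)), with A the asymptotic maximum
degradation (% of total C) and k the rate constant (d⁻¹). Fitting is
nonlinear least squares (Levenberg–Marquardt family; trust-region
reflective when the physical bounds A ∈ [0, 100], k ∈ [0, 10] are active),
minimising the sum of squared differences between observed and predicted
losses.

Reported fit statistics:

* ``residual_mean_square`` = SS_res / (n - 2)
* ``see`` = sqrt(SS_res / (n - 2)) — standard error of the estimate
* ``f_value`` = ((SS_tot - SS_res) / 2) / (SS_res / (n - 2))
* ``r_squared`` = 1 - SS_res / SS_tot, SS_tot about the mean
* parameter standard errors from the Jacobian at the optimum

The F statistic is referred to an F(2, n-2) distribution by
:func:`fit_summary`.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "OMLossSeries",
    "KineticFit",
    "FitError",
    "predict_om_loss",
    "fit_first_order",
    "fit_summary",
    "read_series",
    "write_fit",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the last iterate if known."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass
class OMLossSeries:
    """OM-loss observations: composting day vs cumulative % OM lost."""

    times: np.ndarray
    losses: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.losses = np.asarray(self.losses, dtype=float)
        if self.times.shape != self.losses.shape or self.times.ndim != 1:
            raise ValueError("times and losses must be 1-D arrays of equal length")
        if self.times.size < 4:
            raise ValueError("at least 4 observations needed to fit 2 parameters")
        if self.times[0] < 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if np.any((self.losses < 0) | (self.losses > 100)):
            raise ValueError("losses must lie in [0, 100] %")


@dataclass
class KineticFit:
    a_max: float
    k_rate: float
    a_se: float
    k_se: float
    residual_mean_square: float
    f_value: float
    see: float
    r_squared: float
    n_obs: int

    def to_dict(self) -> dict:
        return asdict(self)


def predict_om_loss(a_max: float, k_rate: float, t) -> float | np.ndarray:
    """Evaluate A * (1 - exp(-k t)); monotone in t, bounded above by A."""
    if a_max < 0 or k_rate < 0:
        raise ValueError("a_max and k_rate must be non-negative")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = a_max * (-np.expm1(-k_rate * t))
    return float(out) if out.ndim == 0 else out


def _default_init(times: np.ndarray, losses: np.ndarray) -> tuple[float, float]:
    # a0 slightly above the observed max; k0 from the half-rise time.
    a0 = max(losses.max() * 1.1, 1e-3)
    half = losses.max() / 2.0
    above = times[losses >= half] if losses.max() > 0 else np.array([])
    t_half = above[0] if above.size and above[0] > 0 else max(times[-1] / 3.0, 1.0)
    return a0, math.log(2.0) / t_half


def fit_first_order(
    series: OMLossSeries,
    init: Optional[tuple[float, float]] = None,
    max_iter: int = 2000,
    tol: float = 1e-10,
) -> KineticFit:
    """Least-squares fit of the first-order degradation model.

    Bounds A ∈ [0, 100], k ∈ [0, 10] keep the optimum physical. A series
    with no signal (all losses ≈ 0) degenerates: the fit is returned with
    zero parameters, NaN statistics and a warning.
    """
    t, y = series.times, series.losses
    n = t.size
    if np.allclose(y, 0.0):
        warnings.warn("all-zero losses: degenerate fit, k_rate set to 0", stacklevel=2)
        return KineticFit(0.0, 0.0, math.nan, math.nan, 0.0, math.nan, 0.0, math.nan, n)
    p0 = init if init is not None else _default_init(t, y)

    def model(tt, a, k):
        return a * (-np.expm1(-k * tt))

    try:
        popt, pcov = optimize.curve_fit(
            model, t, y, p0=p0, bounds=([0.0, 0.0], [100.0, 10.0]),
            maxfev=max_iter, xtol=tol, ftol=tol, gtol=tol,
        )
    except RuntimeError as exc:
        raise FitError(f"first-order fit did not converge: {exc}", last_iterate=p0) from exc
    a_hat, k_hat = float(popt[0]), float(popt[1])
    resid = y - model(t, a_hat, k_hat)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    dof = n - 2
    rms = ss_res / dof
    see = math.sqrt(rms)
    f_value = ((ss_tot - ss_res) / 2.0) / rms if rms > 0 else math.inf
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
    perr = np.sqrt(np.diag(pcov))
    return KineticFit(a_hat, k_hat, float(perr[0]), float(perr[1]),
                      rms, f_value, see, r2, n)


def fit_summary(fit: KineticFit, alpha: float = 0.001) -> dict:
    """F-test of the fitted model against F(2, n-2).

    Returns the p-value and a verdict at the requested significance level.
    """
    dof = fit.n_obs - 2
    if math.isinf(fit.f_value):
        p = 0.0
    else:
        p = float(stats.f.sf(fit.f_value, 2, dof))
    return {
        "f_value": fit.f_value,
        "df": (2, dof),
        "p_value": p,
        "alpha": alpha,
        "significant": bool(p < alpha),
    }


def read_series(path) -> OMLossSeries:
    """Read an OM-loss series from CSV with columns day, om_loss_pct."""
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("day", "om_loss_pct"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    return OMLossSeries(df["day"].to_numpy(float), df["om_loss_pct"].to_numpy(float))


def write_fit(fit: KineticFit, path) -> None:
    """Write the full fit report as JSON."""
    with open(path, "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2)
        fh.write("\n")
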