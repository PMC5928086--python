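"""Growth kinetics: specific growth rates, logistic fits, weekly trajectory bins.

Rates are computed from paired cell counts on a natural-log scale, abundance
series are fitted with a three-parameter logistic curve, and replicate
trajectories are summarised per treatment into fixed-width time bins with
Tukey-style whiskers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "LogisticFit",
    "specific_growth_rate",
    "logistic",
    "fit_logistic",
    "bin_growth_trajectories",
]


@dataclass(frozen=True)
class LogisticFit:
    """Least-squares estimates of a logistic growth curve.

    Attributes
    ----------
    k : float
        Carrying capacity (cells mL^-1).
    r : float
        Maximum specific growth rate (day^-1).
    n0 : float
        Initial cell density (cells mL^-1).
    rss : float
        Residual sum of squares of log-density residuals.
    converged : bool
        Whether the optimizer reported success.
    k_identifiable : bool
        False when the series shows no plateau (max observed density well
        below the fitted capacity), in which case ``k`` carries large
        uncertainty.
    """

    k: float
    r: float
    n0: float
    rss: float
    converged: bool
    k_identifiable: bool = True


def specific_growth_rate(n_t0: float, n_t1: float, dt: float) -> float:
    """Specific growth rate mu = (ln N_t1 - ln N_t0) / dt in day^-1.

    Negative values indicate decline; the function is antisymmetric in the
    two densities.
    """
    n_t0 = float(n_t0)
    n_t1 = float(n_t1)
    dt = float(dt)
    if n_t0 <= 0 or n_t1 <= 0:
        raise ValueError("cell densities must be positive")
    if dt <= 0:
        raise ValueError("time interval must be positive")
    return (np.log(n_t1) - np.log(n_t0)) / dt


def logistic(
    t: np.ndarray | float,
    k: float,
    r: float,
    n0: float,
    *,
    printed_sign: bool = False,
) -> np.ndarray | float:
    """Logistic abundance N(t) = K / (1 + ((K - N0)/N0) * exp(-r t)).

    With ``printed_sign=True`` the exponent is ``+r t`` instead, a form that
    decays for r > 0; the default negative exponent is the growth convention
    (N(0) = N0, N(inf) = K for r > 0).
    """
    t = np.asarray(t, dtype=float)
    sign = 1.0 if printed_sign else -1.0
    return k / (1.0 + ((k - n0) / n0) * np.exp(sign * r * t))


def fit_logistic(
    times,
    counts,
    *,
    printed_sign: bool = False,
) -> LogisticFit:
    """Fit a logistic growth curve to an abundance time series.

    The objective is least squares on log counts (multiplicative error
    typical of cytometry counts). Requires at least 4 distinct time points.
    Non-convergence is flagged on the result rather than raised.
    """
    t = np.asarray(times, dtype=float)
    n = np.asarray(counts, dtype=float)
    if t.shape != n.shape or t.ndim != 1:
        raise ValueError("times and counts must be 1-d arrays of equal length")
    if np.unique(t).size < 4:
        raise ValueError("need at least 4 distinct time points")
    if np.any(n <= 0):
        raise ValueError("cell counts must be positive")
    if np.any(np.diff(t[np.argsort(t, kind="stable")]) < 0):  # pragma: no cover
        raise ValueError("times must be sortable")

    log_n = np.log(n)
    flat = np.ptp(log_n) < 1e-12
    if flat:
        warnings.warn("flat series: growth rate is ~0", stacklevel=2)

    def resid(theta):
        k, r, n0 = np.exp(theta)
        pred = logistic(t, k, r, n0, printed_sign=printed_sign)
        return np.log(np.maximum(pred, 1e-300)) - log_n

    n0_init = max(n[np.argmin(t)], 1e-12)
    k_init = max(n.max(), n0_init * 1.001)
    # early-phase log slope as an r guess
    order = np.argsort(t)
    half = max(2, len(t) // 2)
    slope = np.polyfit(t[order][:half], log_n[order][:half], 1)[0]
    r_init = abs(slope) if abs(slope) > 1e-6 else 0.1

    best = None
    for r0 in (r_init, r_init * 3.0, r_init / 3.0, 1.0):
        for k0 in (k_init, k_init * 5.0):
            theta0 = np.log([k0, r0, n0_init])
            try:
                res = least_squares(resid, theta0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
            except Exception:  # pragma: no cover - optimizer pathologies
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None:  # pragma: no cover
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, False, False)

    k, r, n0 = np.exp(best.x)
    rss = float(2.0 * best.cost)
    if flat:
        r = 0.0
    # series never reaches the inflection -> capacity poorly constrained
    k_identifiable = bool(n.max() >= 0.5 * k)
    converged = bool(best.success)
    return LogisticFit(float(k), float(r), float(n0), rss, converged, k_identifiable)


def bin_growth_trajectories(
    obs: pd.DataFrame,
    bin_width: float = 7.0,
    *,
    time_col: str = "time_days",
    rate_col: str = "growth_rate",
    treatment_col: str = "treatment",
) -> pd.DataFrame:
    """Summarise growth-rate observations per (treatment, time bin).

    Bins are half-open ``[i*w, (i+1)*w)`` and numbered from 1, so an
    observation at exactly day ``bin_width`` falls in bin 2. Each row
    reports median, quartiles and whiskers at the most extreme observation
    within 1.5x IQR of the corresponding quartile. Empty bins are omitted.
    """
    if treatment_col not in obs.columns:
        raise ValueError(f"observations must carry a {treatment_col!r} column")
    df = obs[[treatment_col, time_col, rate_col]].dropna()
    binned = df.assign(bin=(np.floor(df[time_col] / bin_width) + 1).astype(int))

    rows = []
    for (treatment, b), grp in binned.groupby([treatment_col, "bin"], sort=True):
        x = grp[rate_col].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        in_lo = x[x >= q1 - 1.5 * iqr]
        in_hi = x[x <= q3 + 1.5 * iqr]
        rows.append(
            {
                treatment_col: treatment,
                "bin": b,
                "n": len(x),
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_low": in_lo.min(),
                "whisker_high": in_hi.max(),
            }
        )
    return pd.DataFrame(rows)
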