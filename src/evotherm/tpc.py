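"""Thermal performance curves: a high-temperature-inactivation Boltzmann
model, its closed-form optimum, nonlinear least-squares fitting, and
AICc-based model comparison.

The model for the log rate at absolute temperature ``T`` is

    ln b(T) = Ea * (1/(k*Tc) - 1/(k*T)) + ln b(Tc)
              - ln(1 + exp(Eh * (1/(k*Th) - 1/(k*T))))

with Boltzmann's constant ``k`` in eV/K, activation energy ``Ea`` (eV),
inactivation energy ``Eh`` (eV), half-inactivation temperature ``Th`` (K)
and a reference temperature ``Tc`` (default 18 degC) at which the rate is
``exp(ln_b_tc)``. The rate peaks at

    T_opt = Eh * Th / (Eh + k * Th * ln(Eh/Ea - 1)).

Temperatures are Kelvin internally and Celsius at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

BOLTZMANN_EV = 8.62e-5  # eV K^-1
TC_DEFAULT_K = 291.15  # 18 degC

__all__ = [
    "BOLTZMANN_EV",
    "TC_DEFAULT_K",
    "SharpeSchoolfieldParams",
    "TPCFit",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
    "ss_log_rate",
    "compute_topt",
    "fit_tpc",
    "fit_tpc_table",
    "aicc",
    "compare_models_aicc",
]


def celsius_to_kelvin(t_c):
    return np.asarray(t_c, dtype=float) + 273.15


def kelvin_to_celsius(t_k):
    return np.asarray(t_k, dtype=float) - 273.15


@dataclass(frozen=True)
class SharpeSchoolfieldParams:
    """Parameters of the thermal performance model.

    ``ln_b_tc`` is the log rate at the reference temperature ``tc`` (K);
    ``ea`` and ``eh`` are the activation and inactivation energies in eV
    (``eh > ea > 0``); ``th`` is the half-inactivation temperature in K.
    """

    ln_b_tc: float
    ea: float
    eh: float
    th: float
    tc: float = TC_DEFAULT_K

    def __post_init__(self):
        if not (self.eh > self.ea > 0):
            raise ValueError("require eh > ea > 0")
        if self.th <= 0 or self.tc <= 0:
            raise ValueError("temperatures must be positive Kelvin")

    @property
    def topt(self) -> float:
        return compute_topt(self.ea, self.eh, self.th)


@dataclass(frozen=True)
class TPCFit:
    params: SharpeSchoolfieldParams
    topt: float
    covariance: np.ndarray | None
    rss: float
    aicc: float
    n_obs: int
    converged: bool
    unidentifiable: bool = False
    flux: str | None = None
    treatment: str | None = None
    replicate: str | None = None
    labels: dict = field(default_factory=dict)


def ss_log_rate(t_k, params: SharpeSchoolfieldParams):
    """Evaluate ln b(T) at absolute temperature(s) ``t_k``.

    The inactivation term uses log1p(exp(x)) evaluated overflow-safely
    (for x > 0 it is computed as x + log1p(exp(-x))).
    """
    t = np.asarray(t_k, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive Kelvin")
    k = BOLTZMANN_EV
    rise = params.ea * (1.0 / (k * params.tc) - 1.0 / (k * t))
    x = params.eh * (1.0 / (k * params.th) - 1.0 / (k * t))
    inact = np.logaddexp(0.0, x)  # ln(1 + e^x), overflow-safe
    out = rise + params.ln_b_tc - inact
    return out if out.ndim else float(out)


def compute_topt(ea: float, eh: float, th: float) -> float:
    """Closed-form optimum temperature (K) of the thermal performance curve."""
    if not (eh > ea > 0):
        raise ValueError("require eh > ea > 0")
    return eh * th / (eh + BOLTZMANN_EV * th * math.log(eh / ea - 1.0))


def _fit_theta(t_k, log_rate, tc, theta0, bounds):
    def resid(theta):
        ln_b, ea, d_eh, th = theta
        p = SharpeSchoolfieldParams(ln_b, ea, ea + d_eh, th, tc)
        return ss_log_rate(t_k, p) - log_rate

    return least_squares(
        resid, theta0, bounds=bounds, xtol=1e-15, ftol=1e-15, gtol=1e-15
    )


def fit_tpc(
    temps_c,
    rates,
    *,
    tc_c: float = 18.0,
    flux: str | None = None,
    treatment: str | None = None,
    replicate: str | None = None,
) -> TPCFit:
    """Fit the thermal performance model to (temperature degC, rate) data.

    Rates must be positive (fitting is on the log scale). ``eh > ea`` is
    enforced by parametrising ``eh = ea + d`` with ``d`` bounded away from
    zero; initial values come from a small multi-start grid. Data that do
    not span both sides of the apparent optimum, or fewer than 5 distinct
    temperatures, leave the fit flagged ``unidentifiable``.
    """
    t_c = np.asarray(temps_c, dtype=float)
    b = np.asarray(rates, dtype=float)
    if t_c.shape != b.shape or t_c.ndim != 1:
        raise ValueError("temps and rates must be 1-d arrays of equal length")
    if len(t_c) < 5:
        raise ValueError("need at least 5 observations")
    if np.any(b <= 0):
        raise ValueError("rates must be positive for log-scale fitting")

    t_k = celsius_to_kelvin(t_c)
    tc = float(celsius_to_kelvin(tc_c))
    y = np.log(b)

    distinct = np.unique(t_k)
    i_max = int(np.argmax([y[t_k == u].mean() for u in distinct]))
    one_sided = i_max in (0, len(distinct) - 1)
    unidentifiable = bool(one_sided or distinct.size < 5)

    t_lo, t_hi = float(t_k.min()), float(t_k.max())
    bounds = (
        [-50.0, 1e-3, 1e-3, t_lo],
        [50.0, 10.0, 30.0, t_hi + 20.0],
    )
    ln_b0 = float(np.interp(tc, t_k[np.argsort(t_k)], y[np.argsort(t_k)]))
    th0 = float(distinct[i_max])
    starts = [
        (ln_b0, ea0, d0, th)
        for ea0 in (0.5, 1.5)
        for d0 in (1.0, 4.0)
        for th in (th0, min(th0 + 5.0, t_hi + 19.0))
    ]

    best = None
    for theta0 in starts:
        theta0 = np.clip(theta0, bounds[0], bounds[1])
        try:
            res = _fit_theta(t_k, y, tc, theta0, bounds)
        except Exception:  # pragma: no cover
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:  # pragma: no cover
        raise RuntimeError("all optimizer starts failed")

    ln_b, ea, d_eh, th = best.x
    params = SharpeSchoolfieldParams(float(ln_b), float(ea), float(ea + d_eh), float(th), tc)
    rss = float(2.0 * best.cost)
    n = len(b)
    # rss == 0 (exact interpolation) degenerates to -inf
    score = aicc(rss, n, 4) if rss > 0 else float("-inf")

    cov = None
    try:
        jac = best.jac
        dof = max(n - 4, 1)
        s2 = rss / dof
        cov = s2 * np.linalg.pinv(jac.T @ jac)
    except Exception:  # pragma: no cover
        pass

    return TPCFit(
        params=params,
        topt=params.topt,
        covariance=cov,
        rss=rss,
        aicc=score,
        n_obs=n,
        converged=bool(best.success),
        unidentifiable=unidentifiable,
        flux=flux,
        treatment=treatment,
        replicate=replicate,
    )


def fit_tpc_table(
    df: pd.DataFrame,
    *,
    tc_c: float = 18.0,
    temp_col: str = "temp_c",
    rate_col: str = "rate",
    group_cols: tuple[str, ...] = ("treatment", "replicate", "flux"),
) -> pd.DataFrame:
    """Fit one curve per group of a long-format rate table; return tidy fits."""
    present = [c for c in group_cols if c in df.columns]
    rows = []
    for keys, grp in df.groupby(list(present), sort=True) if present else [((), df)]:
        if not isinstance(keys, tuple):
            keys = (keys,)
        fit = fit_tpc(grp[temp_col], grp[rate_col], tc_c=tc_c)
        row = dict(zip(present, keys))
        row.update(
            ln_b_tc=fit.params.ln_b_tc,
            ea=fit.params.ea,
            eh=fit.params.eh,
            th_k=fit.params.th,
            topt_c=float(kelvin_to_celsius(fit.topt)),
            rss=fit.rss,
            aicc=fit.aicc,
            n_obs=fit.n_obs,
            converged=fit.converged,
            unidentifiable=fit.unidentifiable,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def compare_treatment_models(
    df: pd.DataFrame,
    *,
    tc_c: float = 18.0,
    temp_col: str = "temp_c",
    rate_col: str = "rate",
    treatment_col: str = "treatment",
) -> pd.DataFrame:
    """AICc comparison of a pooled curve versus treatment-specific curves.

    The "pooled" candidate fits one curve to all observations (4
    parameters); the "by_treatment" candidate fits one curve per treatment
    level (4 x levels parameters, RSS summed). Both are scored on the same
    n, so Akaike weights quantify support for a treatment effect on the
    curve parameters.
    """
    treatments = df[treatment_col].unique()
    pooled = fit_tpc(df[temp_col], df[rate_col], tc_c=tc_c)
    n = len(df)
    candidates = {
        "pooled": {
            "rss": pooled.rss, "n": n, "p": 4,
            "params": {"ea": pooled.params.ea, "eh": pooled.params.eh,
                       "th": pooled.params.th},
        }
    }
    if len(treatments) > 1:
        rss = 0.0
        for t in treatments:
            sub = df[df[treatment_col] == t]
            rss += fit_tpc(sub[temp_col], sub[rate_col], tc_c=tc_c).rss
        candidates["by_treatment"] = {"rss": rss, "n": n, "p": 4 * len(treatments)}
    return compare_models_aicc(candidates)


def aicc(rss: float, n: int, p: int) -> float:
    """Small-sample corrected AIC: n ln(RSS/n) + 2p + 2p(p+1)/(n-p-1)."""
    if n <= p + 1:
        raise ValueError("AICc undefined for n <= p + 1")
    if rss <= 0:
        raise ValueError("RSS must be positive")
    return n * math.log(rss / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


def compare_models_aicc(candidates) -> pd.DataFrame:
    """Rank candidate models by AICc and compute Akaike weights.

    ``candidates`` maps label -> dict with keys ``rss``, ``n``, ``p`` and
    optionally ``params`` (a mapping of parameter name -> value). All
    candidates must be fitted to the same data (equal ``n``). Returns a
    DataFrame sorted by AICc with columns aicc, delta_aicc, weight and, if
    parameters were supplied, weight-averaged parameters over the
    delta < 2 candidate set in ``DataFrame.attrs['averaged_params']``.
    """
    if not candidates:
        raise ValueError("no candidate models")
    ns = {c["n"] for c in candidates.values()}
    if len(ns) != 1:
        raise ValueError("all candidates must be fitted to identical data (equal n)")
    rows = []
    for label, c in candidates.items():
        rows.append({"model": label, "rss": c["rss"], "n": c["n"], "p": c["p"],
                     "aicc": aicc(c["rss"], c["n"], c["p"])})
    tab = pd.DataFrame(rows).sort_values("aicc", kind="stable").reset_index(drop=True)
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].min()
    rel = np.exp(-0.5 * tab["delta_aicc"].to_numpy())
    tab["weight"] = rel / rel.sum()

    in_set = tab["delta_aicc"] < 2.0
    averaged: dict[str, float] = {}
    sel = tab.loc[in_set, ["model", "weight"]]
    w = sel["weight"].to_numpy()
    w = w / w.sum()
    for name in sorted({k for lab in sel["model"] for k in candidates[lab].get("params", {})}):
        vals, ws = [], []
        for lab, wi in zip(sel["model"], w):
            p = candidates[lab].get("params", {})
            if name in p:
                vals.append(p[name])
                ws.append(wi)
        if vals:
            ws = np.asarray(ws) / np.sum(ws)
            averaged[name] = float(np.dot(ws, vals))
    tab.attrs["averaged_params"] = averaged
    return tab
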