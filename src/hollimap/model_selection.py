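"""Classical growth-curve fits and information-criterion model comparison.

Fits Gompertz, logistic and Richards curves to mean abundance
trajectories by nonlinear least squares, and the coupled Holling-LV
system to a pair of mean trajectories, then compares models with AIC,
BIC and Hannan-Quinn criteria computed from the Gaussian profile
likelihood.  Mirrors the common workflow of benchmarking an
interaction-aware model against single-species growth equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .dynamics import (
    ClassicalGrowthParams,
    HollingLVParams,
    classical_growth_curve,
    _rk4_sample,
)

__all__ = [
    "FitReport",
    "information_criteria",
    "fit_growth_model",
    "fit_holling_lv_curves",
]


@dataclass(frozen=True)
class FitReport:
    """Summary of one least-squares growth-model fit.

    Criteria are reported raw (AIC = 2k - 2l); per-observation variants
    (value / n) are stored alongside since both conventions circulate.
    """

    model: str
    params: dict
    stderr: dict
    r2: float
    adj_r2: float
    aic: float
    bic: float
    hq: float
    n_obs: int
    k_params: int
    loglik: float
    rss: float
    converged: bool = True

    @property
    def per_observation(self) -> dict:
        return {
            "aic": self.aic / self.n_obs,
            "bic": self.bic / self.n_obs,
            "hq": self.hq / self.n_obs,
        }

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params,
            "stderr": self.stderr,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "aic": self.aic,
            "bic": self.bic,
            "hq": self.hq,
            "n_obs": self.n_obs,
            "k_params": self.k_params,
            "loglik": self.loglik,
            "rss": self.rss,
            "converged": self.converged,
        }


def information_criteria(loglik: float, k: int, n: int) -> tuple:
    """(AIC, BIC, HQ) from a maximised log-likelihood.

    AIC = 2k - 2l;  BIC = k ln(n) - 2l;  HQ = 2k ln(ln n) - 2l.
    HQ requires n >= 3 (ln ln n must be defined and positive).
    """
    if n < 1 or k < 0:
        raise ValueError("need n >= 1 and k >= 0")
    if k > 0 and n < 3:
        raise ValueError("HQ criterion requires n >= 3")
    aic = 2 * k - 2 * loglik
    bic = k * math.log(n) - 2 * loglik
    hq = (2 * k * math.log(math.log(n)) if k > 0 else 0.0) - 2 * loglik
    return aic, bic, hq


def _gaussian_profile_loglik(rss: float, n: int) -> float:
    """Profile log-likelihood of a Gaussian residual model at sigma^2 = RSS/n."""
    s2 = max(rss / n, 1e-300)
    return -0.5 * n * (math.log(2 * math.pi * s2) + 1.0)


def _report(model, names, est, stderr, fitted, values, converged) -> FitReport:
    values = np.asarray(values, dtype=float)
    n = len(values)
    resid = values - fitted
    rss = float(resid @ resid)
    tss = float(np.sum((values - values.mean()) ** 2))
    # constant data carries no explainable variation: define R^2 = 0 there
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    k_mean = len(names)
    k = k_mean + 1  # + residual variance
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k_mean - 1) if n > k_mean + 1 else float("nan")
    ll = _gaussian_profile_loglik(rss, n)
    aic, bic, hq = information_criteria(ll, k, n)
    return FitReport(
        model=model,
        params=dict(zip(names, map(float, est))),
        stderr=dict(zip(names, map(float, stderr))),
        r2=r2,
        adj_r2=adj,
        aic=aic,
        bic=bic,
        hq=hq,
        n_obs=n,
        k_params=k,
        loglik=ll,
        rss=rss,
        converged=converged,
    )


def _stderr_from_jac(sol, n) -> np.ndarray:
    """Gauss-Newton standard errors from the least-squares Jacobian."""
    try:
        J = sol.jac
        rss = 2.0 * sol.cost
        dof = max(n - J.shape[1], 1)
        s2 = rss / dof
        cov = s2 * np.linalg.pinv(J.T @ J)
        return np.sqrt(np.maximum(np.diag(cov), 0.0))
    except Exception:
        return np.full(len(sol.x), float("nan"))


def fit_growth_model(model: str, times, values) -> FitReport:
    """Least-squares fit of one classical growth curve to one trajectory.

    model in {"gompertz", "logistic", "richards"}.  Starting values are
    derived from the data (K near the max, inflection near mid-curve).
    Non-convergence is flagged on the report rather than raised.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if model not in ("gompertz", "logistic", "richards"):
        raise ValueError(f"unknown model {model!r}")
    names = ["K", "a", "b"] + (["m"] if model == "richards" else [])
    if len(y) < len(names) + 2:
        raise ValueError("too few observations for the requested model")

    K0 = max(float(y.max()), 1e-3)
    b0 = 2.0 / max(float(t.max() - t.min()), 1e-3)
    y0 = max(float(y[0]), K0 * 1e-3)
    if model == "logistic":
        a0 = max(K0 / y0 - 1.0, 0.1)
        x0 = [K0, a0, b0]
    elif model == "gompertz":
        a0 = max(math.log(K0 / y0), 0.1)
        x0 = [K0, a0, b0]
    else:
        x0 = [K0, max(K0 / y0 - 1.0, 0.1), b0, 1.0]

    def curve(p):
        cg = ClassicalGrowthParams(
            model=model,
            K=abs(p[0]) + 1e-12,
            a=p[1],
            b=p[2],
            m=(p[3] if model == "richards" else None),
        )
        return classical_growth_curve(cg, t)

    def resid(p):
        if model == "richards" and abs(p[3]) < 1e-6:
            return np.full_like(y, 1e6)
        with np.errstate(over="ignore", invalid="ignore"):
            c = curve(p)
        return np.where(np.isfinite(c), c - y, 1e6)

    sol = least_squares(resid, x0, method="lm", max_nfev=2000)
    fitted = curve(sol.x)
    est = list(sol.x)
    est[0] = abs(est[0])
    return _report(model, names, est, _stderr_from_jac(sol, len(y)), fitted, y, sol.success)


def fit_holling_lv_curves(
    times, E_values, S_values, step: float = 0.05
) -> tuple:
    """Least-squares fit of the coupled Holling-LV system to both species'
    mean trajectories jointly; returns (FitReport for E, FitReport for S,
    HollingLVParams).

    Initial abundances are fixed at the first observations; the six ODE
    parameters are fitted to the stacked residuals of both curves.  The
    per-species reports attribute three mean parameters to each species
    (its r, K, and interaction scalar) so criteria are comparable with the
    three-parameter classical fits.
    """
    t = np.asarray(times, dtype=float)
    E = np.asarray(E_values, dtype=float)
    S = np.asarray(S_values, dtype=float)
    E0, S0 = max(float(E[0]), 1e-3), max(float(S[0]), 1e-3)
    span = max(float(t.max() - t.min()), 1e-3)

    def solve(p):
        r_e, K_e, a_es, r_s, K_s, a_se = p
        Ev, Sv, diverged, _ = _rk4_sample(
            abs(r_e), abs(K_e) + 1e-9, a_es, abs(r_s), abs(K_s) + 1e-9, a_se,
            E0, S0, float(t[0]), t, step,
        )
        if diverged:
            return None, None
        return Ev, Sv

    def resid(p):
        Ev, Sv = solve(p)
        if Ev is None:
            return np.full(2 * len(t), 1e6)
        return np.concatenate([Ev - E, Sv - S])

    x0 = np.array([2.0 / span, max(E.max(), 1e-2), 0.0, 2.0 / span, max(S.max(), 1e-2), 0.0])
    sol = least_squares(resid, x0, method="lm", max_nfev=4000)
    params = HollingLVParams(
        abs(sol.x[0]), abs(sol.x[1]) + 1e-9, float(sol.x[2]),
        abs(sol.x[3]), abs(sol.x[4]) + 1e-9, float(sol.x[5]),
    )
    Ev, Sv = solve(sol.x)
    se = _stderr_from_jac(sol, 2 * len(t))
    rep_E = _report(
        "holling_lv", ["r_e", "K_e", "alpha_es"], [params.r_e, params.K_e, params.alpha_es],
        se[:3], Ev, E, sol.success,
    )
    rep_S = _report(
        "holling_lv", ["r_s", "K_s", "alpha_se"], [params.r_s, params.K_s, params.alpha_se],
        se[3:], Sv, S, sol.success,
    )
    return rep_E, rep_S, params
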