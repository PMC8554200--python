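"""Genotype-specific longitudinal likelihood and maximum-likelihood fitting.

The observation model: each individual (an interspecific pair in
co-culture, or a single strain in monoculture) contributes a stacked
longitudinal vector y_i -- (E_i(1..T); S_i(1..T)) in co-culture, a single
species' T-vector in monoculture -- distributed as multivariate normal
with a genotype-combination-specific mean vector and a covariance shared
across combinations.  Means are trajectories of the Holling type II
Lotka-Volterra system (co-culture) or its interaction-free logistic
reduction (monoculture); the covariance is the bivariate SAD(1) structure
of :mod:`hollimap.covariance`.

The joint likelihood over combinations j with members i factorises as

    L = prod_j prod_{i in j} f(y_i; mu_j(theta_j), Sigma(sad))

and is maximised by a hybrid of Nelder-Mead simplex search (on
transformed parameters) with fourth-order Runge-Kutta evaluation of the
mean trajectories.  Because, given Sigma, the likelihood separates over
combinations, the fitter cycles block-coordinate updates: one simplex
search per combination's six ODE parameters, then one over the SAD
parameters, until the joint log-likelihood stabilises.  Sufficient
statistics (per-combination means and the pooled within scatter) make
each likelihood evaluation independent of sample size.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import least_squares, minimize

from .covariance import SADParams, build_sad1_covariance, _antedependence_matrix
from .dynamics import (
    HollingLVParams,
    logistic_closed_form,
    _rk4_sample,
)

__all__ = [
    "GenotypeModel",
    "FitConfig",
    "FitError",
    "genotype_mean_curves",
    "model_covariance",
    "joint_log_likelihood",
    "fit_parameters",
    "fit_constrained",
]

_LOG2PI = math.log(2.0 * math.pi)
_BAD = 1e12  # objective value returned on invalid parameter proposals


class FitError(ValueError):
    """Raised for degenerate fitting inputs (empty cells, all-zero data)."""


@dataclass(frozen=True)
class GenotypeModel:
    """A fitted (or true) genotype-specific model.

    thetas  : mapping combination label -> HollingLVParams
    inits   : mapping combination label -> (E0, S0) at the first observation time
    sad     : shared SAD(1) covariance parameters
    culture : "coculture" (bivariate) or "monoculture" (univariate)
    species : for monoculture, which species the data describe ("E" or "S")
    """

    thetas: Mapping[str, HollingLVParams]
    sad: SADParams
    inits: Mapping[str, tuple]
    culture: str = "coculture"
    species: str | None = None
    loglik: float | None = None
    converged: bool = True

    def to_json(self) -> str:
        obj = {
            "combinations": {
                lab: dict(zip(HollingLVParams.FIELD_ORDER, th.as_array().tolist()))
                for lab, th in self.thetas.items()
            },
            "inits": {lab: list(map(float, v)) for lab, v in self.inits.items()},
            "sad": {
                "phi_e": self.sad.phi_e,
                "phi_s": self.sad.phi_s,
                "nu_e": self.sad.nu_e,
                "nu_s": self.sad.nu_s,
                "rho": self.sad.rho,
            },
            "culture": self.culture,
            "species": self.species,
            "loglik": self.loglik,
            "converged": self.converged,
        }
        return json.dumps(obj, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GenotypeModel":
        obj = json.loads(text)
        thetas = {
            lab: HollingLVParams(**vals) for lab, vals in obj["combinations"].items()
        }
        sad = SADParams(**obj["sad"])
        inits = {lab: tuple(v) for lab, v in obj["inits"].items()}
        return cls(
            thetas=thetas,
            sad=sad,
            inits=inits,
            culture=obj.get("culture", "coculture"),
            species=obj.get("species"),
            loglik=obj.get("loglik"),
            converged=obj.get("converged", True),
        )


def _mean_vector(
    theta: HollingLVParams,
    init: tuple,
    times: np.ndarray,
    culture: str,
    species: str | None,
    step: float,
) -> np.ndarray:
    """Mean vector for one combination: 2T stacked (E; S) in co-culture,
    T for one species in monoculture (interaction-free logistic)."""
    t0 = float(times[0])
    if culture == "coculture":
        E, S, diverged, _ = _rk4_sample(
            theta.r_e,
            theta.K_e,
            theta.alpha_es,
            theta.r_s,
            theta.K_s,
            theta.alpha_se,
            float(init[0]),
            float(init[1]),
            t0,
            times,
            step,
        )
        if diverged:
            raise OverflowError("mean trajectory diverged")
        return np.concatenate([E, S])
    if species == "E":
        return logistic_closed_form(theta.r_e, theta.K_e, float(init[0]), times - t0)
    if species == "S":
        return logistic_closed_form(theta.r_s, theta.K_s, float(init[1]), times - t0)
    raise ValueError("monoculture mode requires species 'E' or 'S'")


def genotype_mean_curves(
    model: GenotypeModel, times: Sequence[float], step: float = 0.05
) -> dict:
    """Per-combination mean vectors mu_j on the given time grid."""
    t = np.asarray(times, dtype=float)
    return {
        lab: _mean_vector(th, model.inits[lab], t, model.culture, model.species, step)
        for lab, th in model.thetas.items()
    }


def model_covariance(
    sad: SADParams, T: int, culture: str = "coculture", species: str | None = None
) -> np.ndarray:
    """Covariance of the stacked observation vector under the SAD(1) model."""
    if culture == "coculture":
        return build_sad1_covariance(sad, T)
    phi, nu = (sad.phi_e, sad.nu_e) if species == "E" else (sad.phi_s, sad.nu_s)
    L = _antedependence_matrix(phi, T)
    return nu**2 * (L @ L.T)


def joint_log_likelihood(
    Y: np.ndarray,
    labels: Sequence,
    model: GenotypeModel,
    times: Sequence[float],
    step: float = 0.05,
) -> float:
    """Joint Gaussian log-likelihood of observations under a genotype model.

    Y has one row per individual; columns are the stacked time grid
    (E block then S block in co-culture).  Every label must have a
    corresponding theta in the model.
    """
    Y = np.asarray(Y, dtype=float)
    labels = np.asarray(labels)
    t = np.asarray(times, dtype=float)
    T = len(t)
    D = Y.shape[1]
    expected = 2 * T if model.culture == "coculture" else T
    if D != expected:
        raise ValueError(f"Y has {D} columns, expected {expected}")
    unknown = set(np.unique(labels)) - set(model.thetas)
    if unknown:
        raise ValueError(f"observations assigned to undeclared combinations: {unknown}")
    mus = genotype_mean_curves(model, t, step=step)
    sigma = model_covariance(model.sad, T, model.culture, model.species)
    try:
        cf = cho_factor(sigma, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular covariance matrix: {exc}") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    dev = Y - np.stack([mus[lab] for lab in labels])
    quad = float(np.sum(dev * cho_solve(cf, dev.T).T))
    n = Y.shape[0]
    return -0.5 * (n * D * _LOG2PI + n * logdet + quad)


# ---------------------------------------------------------------------------
# Fitting


@dataclass(frozen=True)
class FitConfig:
    """Optimizer configuration for :func:`fit_parameters`.

    step         : RK4 integration step (hours) used during fitting
    n_restarts   : independent Nelder-Mead starts (jittered after the first)
    jitter       : relative log-scale jitter applied to restart starting values
    max_cycles   : block-coordinate cycles (theta blocks + SAD block)
    block_maxfev : max function evaluations per theta simplex search
    sad_maxfev   : max function evaluations per SAD simplex search
    tol          : stop cycling when the joint log-likelihood gains less
    seed         : seed for restart jitter
    init_mode    : how initial abundances enter the mean model --
                   "shared": fixed at the global mean first-time abundance
                   (one inoculum for all combinations; the default),
                   "per_group": fixed at each combination's own mean
                   first-time abundance, "free": fitted per combination
    """

    step: float = 0.05
    n_restarts: int = 3
    jitter: float = 0.08
    max_cycles: int = 6
    block_maxfev: int = 300
    sad_maxfev: int = 250
    tol: float = 1e-3
    xatol: float = 1e-5
    fatol: float = 1e-7
    seed: int = 0
    init_mode: str = "shared"

    def __post_init__(self):
        if self.init_mode not in ("shared", "per_group", "free"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")

    @property
    def free_init(self) -> bool:
        return self.init_mode == "free"


# parameter transforms: simplex search runs unconstrained
def _enc_pos(x):
    return math.log(x)


def _dec_pos(z):
    return math.exp(min(max(z, -500.0), 60.0))


def _enc_phi(x):
    return math.atanh(min(max(x / 3.0, -0.999999), 0.999999))


def _dec_phi(z):
    return 3.0 * math.tanh(z)


def _enc_rho(x):
    return math.atanh(min(max(x, -0.999999), 0.999999))


def _dec_rho(z):
    return math.tanh(z)


def _theta_to_x(theta: HollingLVParams, culture: str, species: str | None):
    if culture == "coculture":
        return np.array(
            [
                _enc_pos(theta.r_e),
                _enc_pos(theta.K_e),
                theta.alpha_es,
                _enc_pos(theta.r_s),
                _enc_pos(theta.K_s),
                theta.alpha_se,
            ]
        )
    if species == "E":
        return np.array([_enc_pos(theta.r_e), _enc_pos(theta.K_e)])
    return np.array([_enc_pos(theta.r_s), _enc_pos(theta.K_s)])


def _x_to_theta(x, culture: str, species: str | None, base: HollingLVParams):
    if culture == "coculture":
        return HollingLVParams(
            _dec_pos(x[0]), _dec_pos(x[1]), x[2], _dec_pos(x[3]), _dec_pos(x[4]), x[5]
        )
    if species == "E":
        return replace(base, r_e=_dec_pos(x[0]), K_e=_dec_pos(x[1]))
    return replace(base, r_s=_dec_pos(x[0]), K_s=_dec_pos(x[1]))


def _sad_to_x(sad: SADParams, culture: str, species: str | None):
    if culture == "coculture":
        return np.array(
            [
                _enc_phi(sad.phi_e),
                _enc_phi(sad.phi_s),
                _enc_pos(sad.nu_e),
                _enc_pos(sad.nu_s),
                _enc_rho(sad.rho),
            ]
        )
    if species == "E":
        return np.array([_enc_phi(sad.phi_e), _enc_pos(sad.nu_e)])
    return np.array([_enc_phi(sad.phi_s), _enc_pos(sad.nu_s)])


def _x_to_sad(x, culture: str, species: str | None, base: SADParams):
    if culture == "coculture":
        return SADParams(
            _dec_phi(x[0]), _dec_phi(x[1]), _dec_pos(x[2]), _dec_pos(x[3]), _dec_rho(x[4])
        )
    if species == "E":
        return replace(base, phi_e=_dec_phi(x[0]), nu_e=_dec_pos(x[1]))
    return replace(base, phi_s=_dec_phi(x[0]), nu_s=_dec_pos(x[1]))


def _suff_stats(Y: np.ndarray, labels: np.ndarray, groups: Sequence):
    """Counts, group means and pooled within-group scatter."""
    counts, means = {}, {}
    Sw = np.zeros((Y.shape[1], Y.shape[1]))
    for g in groups:
        rows = Y[labels == g]
        counts[g] = len(rows)
        if len(rows) < 2:
            raise FitError(
                f"combination {g!r} has {len(rows)} individual(s); at least 2 required"
            )
        means[g] = rows.mean(axis=0)
        dev = rows - means[g]
        Sw += dev.T @ dev
    return counts, means, Sw


def _logistic_start(times: np.ndarray, ybar: np.ndarray, x0: float):
    """Least-squares logistic (r, K) start for one species' mean curve."""
    t = times - times[0]
    x0 = max(x0, 1e-3)
    ymax = max(float(ybar.max()), x0 * 1.5, 1e-2)

    def resid(p):
        return logistic_closed_form(math.exp(p[0]), math.exp(p[1]), x0, t) - ybar

    try:
        sol = least_squares(
            resid,
            np.array([math.log(0.3), math.log(ymax)]),
            method="lm",
            max_nfev=200,
        )
        r, K = math.exp(sol.x[0]), math.exp(sol.x[1])
        if not (0 < r < 1e3 and 0 < K < 1e9):
            raise ValueError
        return r, K
    except Exception:
        return 0.3, ymax


def _sad_moment_start(
    resid: np.ndarray, T: int, culture: str, species: str | None
) -> SADParams:
    """Moment-based starting values for the SAD parameters from residuals."""

    def per_species(block):
        prev, cur = block[:, :-1], block[:, 1:]
        denom = float(np.sum(prev * prev))
        phi = float(np.sum(prev * cur) / denom) if denom > 1e-12 else 0.5
        phi = min(max(phi, -2.5), 2.5)
        innov = np.concatenate([block[:, :1], cur - phi * prev], axis=1)
        nu = float(np.sqrt(max(np.mean(innov**2), 1e-8)))
        return phi, nu, innov

    if culture == "coculture":
        phi_e, nu_e, inn_e = per_species(resid[:, :T])
        phi_s, nu_s, inn_s = per_species(resid[:, T:])
        num = float(np.mean(inn_e * inn_s))
        rho = min(max(num / (nu_e * nu_s), -0.95), 0.95)
        return SADParams(phi_e, phi_s, nu_e, nu_s, rho)
    phi, nu, _ = per_species(resid)
    if species == "E":
        return SADParams(phi, 0.5, nu, 1.0, 0.0)
    return SADParams(0.5, phi, 1.0, nu, 0.0)


class _Objective:
    """Shared state for the block-coordinate likelihood maximisation."""

    def __init__(self, times, counts, means, Sw, culture, species, step, free_init):
        self.times = times
        self.T = len(times)
        self.counts = counts
        self.means = means
        self.Sw = Sw
        self.culture = culture
        self.species = species
        self.step = step
        self.free_init = free_init
        self.N = sum(counts.values())
        self.D = 2 * self.T if culture == "coculture" else self.T
        self.scale = max(max(abs(float(m.max())) for m in means.values()), 1.0)
        self.cf = None
        self.logdet = None

    def default_init(self, g):
        """Initial abundances fixed at the group's mean first-time values."""
        ybar = self.means[g]
        if self.culture == "coculture":
            return (max(float(ybar[0]), 1e-3), max(float(ybar[self.T]), 1e-3))
        v = max(float(ybar[0]), 1e-3)
        return (v, v)

    def shared_init(self):
        """Global mean first-time abundances (one inoculum for everyone)."""
        tot = sum(self.counts[g] * self.means[g] for g in self.counts) / self.N
        if self.culture == "coculture":
            return (max(float(tot[0]), 1e-3), max(float(tot[self.T]), 1e-3))
        v = max(float(tot[0]), 1e-3)
        return (v, v)

    def init_for(self, g, init_mode: str):
        return self.shared_init() if init_mode == "shared" else self.default_init(g)

    def set_sigma(self, sad: SADParams):
        sigma = model_covariance(sad, self.T, self.culture, self.species)
        self.cf = cho_factor(sigma, lower=True, check_finite=False)
        self.logdet = 2.0 * float(np.sum(np.log(np.diag(self.cf[0]))))
        self.sinv = cho_solve(self.cf, np.eye(self.D), check_finite=False)

    def quad(self, v):
        return float(v @ self.sinv @ v)

    def plausible(self, theta: HollingLVParams) -> bool:
        """Reject parameter proposals outside the scientifically meaningful
        box: rates below 20/h, carrying capacities within ~20x the observed
        abundance scale, |alpha| <= 5 (beyond which the Holling term dwarfs
        the logistic term).  Keeps the simplex off likelihood ridges where
        (K, alpha) trade off into absurd joint values."""
        s = self.scale
        return (
            1e-4 <= theta.r_e <= 20.0
            and 1e-4 <= theta.r_s <= 20.0
            and 1e-3 <= theta.K_e <= 20.0 * s
            and 1e-3 <= theta.K_s <= 20.0 * s
            and abs(theta.alpha_es) <= 5.0
            and abs(theta.alpha_se) <= 5.0
        )

    def group_quad(self, g, theta, init):
        """n_g (ybar_g - mu_g)' Sigma^-1 (ybar_g - mu_g); +inf on divergence."""
        if not self.plausible(theta):
            return _BAD
        try:
            mu = _mean_vector(theta, init, self.times, self.culture, self.species, self.step)
        except (OverflowError, ValueError):
            return _BAD
        if not np.all(np.isfinite(mu)):
            return _BAD
        return self.counts[g] * self.quad(self.means[g] - mu)

    def loglik(self, thetas, inits, sad):
        """Full joint log-likelihood at the current parameters."""
        self.set_sigma(sad)
        tr = float(np.trace(cho_solve(self.cf, self.Sw)))
        total = tr
        for g in thetas:
            total += self.group_quad(g, thetas[g], inits[g])
        return -0.5 * (self.N * self.D * _LOG2PI + self.N * self.logdet + total)


def _simplex(fun, x0, maxfev, xatol=1e-5, fatol=1e-7):
    res = minimize(
        fun,
        x0,
        method="Nelder-Mead",
        options={
            "maxfev": maxfev,
            "xatol": xatol,
            "fatol": fatol,
            "adaptive": False,
        },
    )
    # Nelder-Mead is monotone: the returned point is never worse than x0
    return res.x, res.fun


def fit_parameters(
    Y: np.ndarray,
    labels: Sequence,
    times: Sequence[float],
    mode: str = "by_combination",
    config: FitConfig = FitConfig(),
    culture: str = "coculture",
    species: str | None = None,
    warm_start: GenotypeModel | None = None,
) -> GenotypeModel:
    """Maximum-likelihood fit of the genotype-specific longitudinal model.

    mode="null" fits one shared theta for all individuals (the
    genotype-invariant hypothesis); mode="by_combination" fits one theta
    per distinct label.  SAD covariance parameters are fitted jointly in
    both modes.  A ``warm_start`` model (typically the null fit, when
    fitting the alternative) seeds every block, which both accelerates
    convergence and keeps nested likelihood-ratio statistics non-negative.

    Returns a :class:`GenotypeModel` carrying the maximised log-likelihood
    and a convergence flag (False if the final cycle was still improving
    by more than the tolerance after all restarts).
    """
    Y = np.asarray(Y, dtype=float)
    labels = np.asarray(labels)
    t = np.asarray(times, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != len(labels):
        raise ValueError("Y must be (n, D) with one label per row")
    if not np.all(np.isfinite(Y)):
        raise FitError("non-finite abundance values in input")
    if np.all(Y == 0):
        raise FitError("all abundances are zero; nothing to fit")
    if mode not in ("null", "by_combination"):
        raise ValueError(f"unknown mode {mode!r}")

    if mode == "null":
        groups = ["__all__"]
        glabels = np.full(len(labels), "__all__")
    else:
        groups = sorted(np.unique(labels).tolist())
        glabels = labels
    counts, means, Sw = _suff_stats(Y, glabels, groups)
    obj = _Objective(t, counts, means, Sw, culture, species, config.step, config.free_init)

    # ---- starting values -------------------------------------------------
    def fresh_start(g):
        ybar = means[g]
        init = obj.init_for(g, config.init_mode)
        if culture == "coculture":
            r_e, K_e = _logistic_start(t, ybar[: obj.T], init[0])
            r_s, K_s = _logistic_start(t, ybar[obj.T :], init[1])
            theta = HollingLVParams(r_e, K_e, 0.0, r_s, K_s, 0.0)
        else:
            r, K = _logistic_start(t, ybar, init[0])
            theta = HollingLVParams(
                r if species == "E" else 0.3,
                K if species == "E" else 10.0,
                0.0,
                r if species == "S" else 0.3,
                K if species == "S" else 10.0,
                0.0,
            )
        return theta, init

    start_thetas, start_inits = {}, {}
    for g in groups:
        if warm_start is not None:
            src = warm_start.thetas
            theta = src[g] if g in src else next(iter(src.values()))
            start_thetas[g] = theta
            start_inits[g] = (
                warm_start.inits[g]
                if g in warm_start.inits and config.init_mode != "shared"
                else obj.init_for(g, config.init_mode)
            )
        else:
            start_thetas[g], start_inits[g] = fresh_start(g)
    if warm_start is not None:
        start_sad = warm_start.sad
    else:
        mu0 = {
            g: _mean_vector(start_thetas[g], start_inits[g], t, culture, species, config.step)
            for g in groups
        }
        resid = Y - np.stack([mu0[g] for g in glabels])
        start_sad = _sad_moment_start(resid, obj.T, culture, species)

    rng = np.random.default_rng(config.seed)
    best = None
    for restart in range(max(config.n_restarts, 1)):
        thetas = dict(start_thetas)
        inits = dict(start_inits)
        sad = start_sad
        if restart > 0:  # jitter on the transformed scale
            jit = {}
            for g in groups:
                x = _theta_to_x(thetas[g], culture, species)
                x = x + config.jitter * rng.standard_normal(len(x))
                jit[g] = _x_to_theta(x, culture, species, thetas[g])
            thetas = jit
            xs = _sad_to_x(sad, culture, species)
            xs = xs + config.jitter * rng.standard_normal(len(xs))
            sad = _x_to_sad(xs, culture, species, sad)

        current = obj.loglik(thetas, inits, sad)
        converged = False
        for _cycle in range(config.max_cycles):
            obj.set_sigma(sad)
            for g in groups:
                base = thetas[g]
                if config.free_init:
                    x0 = np.concatenate(
                        [
                            _theta_to_x(base, culture, species),
                            [math.log(max(inits[g][0], 1e-4)), math.log(max(inits[g][1], 1e-4))],
                        ]
                    )

                    def f(x, g=g, base=base):
                        th = _x_to_theta(x[:-2], culture, species, base)
                        init = (_dec_pos(x[-2]), _dec_pos(x[-1]))
                        return obj.group_quad(g, th, init)

                    x, _ = _simplex(f, x0, config.block_maxfev, config.xatol, config.fatol)
                    thetas[g] = _x_to_theta(x[:-2], culture, species, base)
                    inits[g] = (_dec_pos(x[-2]), _dec_pos(x[-1]))
                else:
                    x0 = _theta_to_x(base, culture, species)

                    def f(x, g=g, base=base):
                        return obj.group_quad(
                            g, _x_to_theta(x, culture, species, base), inits[g]
                        )

                    x, _ = _simplex(f, x0, config.block_maxfev, config.xatol, config.fatol)
                    thetas[g] = _x_to_theta(x, culture, species, base)

            # SAD block: theta fixed, M = Sw + sum_g n_g d_g d_g'
            M = Sw.copy()
            for g in groups:
                mu = _mean_vector(thetas[g], inits[g], t, culture, species, config.step)
                d = means[g] - mu
                M += counts[g] * np.outer(d, d)

            def f_sad(x, sad=sad):
                cand = _x_to_sad(x, culture, species, sad)
                try:
                    sigma = model_covariance(cand, obj.T, culture, species)
                    cf = cho_factor(sigma, lower=True, check_finite=False)
                except (np.linalg.LinAlgError, ValueError):
                    return _BAD
                logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
                return obj.N * logdet + float(
                    np.trace(cho_solve(cf, M, check_finite=False))
                )

            xs, _ = _simplex(f_sad, _sad_to_x(sad, culture, species), config.sad_maxfev, config.xatol, config.fatol)
            sad = _x_to_sad(xs, culture, species, sad)

            new = obj.loglik(thetas, inits, sad)
            if new - current < config.tol:
                converged = True
                current = max(new, current)
                break
            current = new

        if best is None or current > best[0]:
            best = (current, thetas, inits, sad, converged)

    loglik, thetas, inits, sad, converged = best
    if not converged:
        warnings.warn(
            "fit did not stabilise within the cycle budget; result flagged",
            RuntimeWarning,
        )
    return GenotypeModel(
        thetas=thetas,
        sad=sad,
        inits=inits,
        culture=culture,
        species=species,
        loglik=float(loglik),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Constrained fits for parameter-subset hypothesis tests

_INDEP_FIELDS = ("r_e", "K_e", "r_s", "K_s")
_INTER_FIELDS = ("r_e", "alpha_es", "r_s", "alpha_se")
_ENCODERS = {
    "r_e": (_enc_pos, _dec_pos),
    "K_e": (_enc_pos, _dec_pos),
    "r_s": (_enc_pos, _dec_pos),
    "K_s": (_enc_pos, _dec_pos),
    "alpha_es": (lambda v: v, lambda v: v),
    "alpha_se": (lambda v: v, lambda v: v),
}


def fit_constrained(
    Y: np.ndarray,
    labels: Sequence,
    times: Sequence[float],
    which: str,
    config: FitConfig = FitConfig(),
    warm_start: GenotypeModel | None = None,
) -> GenotypeModel:
    """Fit with a parameter subset constrained equal across combinations.

    which="independent" shares (r_e, K_e, r_s, K_s) across combinations
    while the interaction scalars stay combination-specific -- the null of
    "no genotype effect on independent growth".  which="interaction"
    shares (r_e, alpha_es, r_s, alpha_se), leaving carrying capacities
    free -- the null of "no genotype effect on interaction growth".
    Co-culture only.
    """
    if which not in ("independent", "interaction"):
        raise ValueError(f"unknown subset {which!r}")
    shared_fields = _INDEP_FIELDS if which == "independent" else _INTER_FIELDS
    free_fields = tuple(f for f in HollingLVParams.FIELD_ORDER if f not in shared_fields)

    Y = np.asarray(Y, dtype=float)
    labels = np.asarray(labels)
    t = np.asarray(times, dtype=float)
    groups = sorted(np.unique(labels).tolist())
    counts, means, Sw = _suff_stats(Y, labels, groups)
    obj = _Objective(t, counts, means, Sw, "coculture", None, config.step, False)

    if warm_start is not None:
        base_thetas = {
            g: (warm_start.thetas[g] if g in warm_start.thetas else next(iter(warm_start.thetas.values())))
            for g in groups
        }
        sad = warm_start.sad
    else:
        null = fit_parameters(Y, labels, t, mode="null", config=config)
        base_thetas = {g: next(iter(null.thetas.values())) for g in groups}
        sad = null.sad
    inits = {g: obj.init_for(g, config.init_mode) for g in groups}
    shared0 = np.array(
        [
            np.mean([getattr(base_thetas[g], f) for g in groups])
            for f in shared_fields
        ]
    )

    def pack():
        x = [
            _ENCODERS[f][0](v if v != 0 or f.startswith("alpha") else 1e-6)
            for f, v in zip(shared_fields, shared0)
        ]
        for g in groups:
            for f in free_fields:
                x.append(_ENCODERS[f][0](getattr(base_thetas[g], f)))
        return np.array(x)

    n_shared = len(shared_fields)
    n_free = len(free_fields)

    def unpack(x):
        shared = {
            f: _ENCODERS[f][1](x[i]) for i, f in enumerate(shared_fields)
        }
        thetas = {}
        for gi, g in enumerate(groups):
            vals = dict(shared)
            for fi, f in enumerate(free_fields):
                vals[f] = _ENCODERS[f][1](x[n_shared + gi * n_free + fi])
            thetas[g] = HollingLVParams(**{k: vals[k] for k in HollingLVParams.FIELD_ORDER})
        return thetas

    # start from the constrained projection of the warm-start model (shared
    # entries averaged across combinations), never from the unconstrained
    # point itself: the running likelihood must belong to the null family
    thetas = unpack(pack())
    for g in groups:
        base_thetas[g] = thetas[g]
    current = obj.loglik(thetas, inits, sad)
    for _cycle in range(config.max_cycles):
        obj.set_sigma(sad)

        def f(x):
            try:
                cand = unpack(x)
            except ValueError:
                return _BAD
            return sum(obj.group_quad(g, cand[g], inits[g]) for g in groups)

        x0 = pack()
        x, _ = _simplex(f, x0, config.block_maxfev * len(groups), config.xatol, config.fatol)
        thetas = unpack(x)
        for g in groups:
            base_thetas[g] = thetas[g]
        shared0 = np.array([getattr(thetas[groups[0]], f) for f in shared_fields])

        M = Sw.copy()
        for g in groups:
            mu = _mean_vector(thetas[g], inits[g], t, "coculture", None, config.step)
            d = means[g] - mu
            M += counts[g] * np.outer(d, d)

        def f_sad(xs, sad=sad):
            cand = _x_to_sad(xs, "coculture", None, sad)
            try:
                sigma = model_covariance(cand, obj.T)
                cf = cho_factor(sigma, lower=True, check_finite=False)
            except (np.linalg.LinAlgError, ValueError):
                return _BAD
            logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            return obj.N * logdet + float(
                np.trace(cho_solve(cf, M, check_finite=False))
            )

        xs, _ = _simplex(f_sad, _sad_to_x(sad, "coculture", None), config.sad_maxfev, config.xatol, config.fatol)
        sad = _x_to_sad(xs, "coculture", None, sad)
        new = obj.loglik(thetas, inits, sad)
        if new - current < config.tol:
            current = max(new, current)
            break
        current = new

    return GenotypeModel(
        thetas=thetas,
        sad=sad,
        inits=inits,
        culture="coculture",
        species=None,
        loglik=float(current),
        converged=True,
    )
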