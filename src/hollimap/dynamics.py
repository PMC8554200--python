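"""Coupled two-species growth dynamics with a Holling type II interaction term.

The core model couples logistic self-limited growth of two co-cultured
species with a saturating (Holling type II) cross-species term:

    dE/dt = r_e E (1 - E/K_e) + r_e E (alpha_es / (1 + E)) S
    dS/dt = r_s S (1 - S/K_s) + r_s S (alpha_se / (1 + S)) E

where E and S are the abundances of species A and B, r_* are Malthusian
growth rates, K_* carrying capacities, and alpha_es / alpha_se signed
interaction scalars (positive: benefit from the partner, negative: harm,
zero: neutrality).  The first summand is the *independent* component --
the growth the species would show in monoculture -- and the second the
*dependent* component contributed by the partner species.

Solutions are computed with a fixed-step fourth-order Runge-Kutta scheme;
partial steps land exactly on requested observation times so the sampled
trajectory retains full RK4 accuracy on arbitrary (non-integer) grids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

__all__ = [
    "HollingLVParams",
    "StatePair",
    "Trajectory",
    "TrajectoryDecomposition",
    "ClassicalGrowthParams",
    "TrajectoryDivergenceError",
    "holling_lv_rhs",
    "solve_holling_lv",
    "solve_logistic_pair",
    "logistic_closed_form",
    "decompose_trajectory",
    "classical_growth_curve",
]

#: Abundances beyond this magnitude abort integration with a divergence error.
OVERFLOW_GUARD = 1e12

#: Default RK4 integration step in hours.
DEFAULT_STEP = 0.01


class TrajectoryDivergenceError(RuntimeError):
    """Raised when the ODE state exceeds the overflow guard during integration."""

    def __init__(self, time: float):
        self.time = time
        super().__init__(
            f"trajectory diverged (state exceeded {OVERFLOW_GUARD:g}) near t={time:.4g} h"
        )


@dataclass(frozen=True)
class HollingLVParams:
    """Six parameters of the coupled Holling-LV system for one genotype class.

    r_e, r_s : Malthusian growth rates (per hour, > 0)
    K_e, K_s : carrying capacities (abundance units, > 0)
    alpha_es : effect of species B on species A (signed, dimensionless)
    alpha_se : effect of species A on species B (signed, dimensionless)
    """

    r_e: float
    K_e: float
    alpha_es: float
    r_s: float
    K_s: float
    alpha_se: float

    def __post_init__(self):
        for name in ("r_e", "r_s"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        for name in ("K_e", "K_s"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        for name in ("alpha_es", "alpha_se"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def without_interaction(self) -> "HollingLVParams":
        """Same growth parameters with both interaction scalars set to zero."""
        return HollingLVParams(self.r_e, self.K_e, 0.0, self.r_s, self.K_s, 0.0)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.r_e, self.K_e, self.alpha_es, self.r_s, self.K_s, self.alpha_se]
        )

    FIELD_ORDER = ("r_e", "K_e", "alpha_es", "r_s", "K_s", "alpha_se")

    @classmethod
    def from_array(cls, arr) -> "HollingLVParams":
        r_e, K_e, a_es, r_s, K_s, a_se = (float(x) for x in arr)
        return cls(r_e, K_e, a_es, r_s, K_s, a_se)


@dataclass(frozen=True)
class StatePair:
    """Abundance state (E, S); both components non-negative."""

    E: float
    S: float

    def __post_init__(self):
        if not (math.isfinite(self.E) and math.isfinite(self.S)):
            raise ValueError("state must be finite")
        if self.E < 0 or self.S < 0:
            raise ValueError("abundances must be non-negative")


@dataclass(frozen=True)
class Trajectory:
    """Sampled abundances of both species on a strictly increasing time grid."""

    times: np.ndarray
    E_values: np.ndarray
    S_values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.E_values, dtype=float)
        s = np.asarray(self.S_values, dtype=float)
        if not (len(t) == len(e) == len(s)):
            raise ValueError("times, E_values, S_values must have equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(e)) and np.all(np.isfinite(s))):
            raise ValueError("trajectory values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "E_values", e)
        object.__setattr__(self, "S_values", s)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("time\tE\tS\n")
            for t, e, s in zip(self.times, self.E_values, self.S_values):
                fh.write(f"{t:.10g}\t{e:.10g}\t{s:.10g}\n")


@dataclass(frozen=True)
class TrajectoryDecomposition:
    """Net trajectories split into independent (monoculture-like) and
    dependent (partner-driven) components; net = independent + dependent
    holds exactly by construction."""

    times: np.ndarray
    net_E: np.ndarray
    net_S: np.ndarray
    independent_E: np.ndarray
    independent_S: np.ndarray
    dependent_E: np.ndarray
    dependent_S: np.ndarray


def holling_lv_rhs(state: StatePair | tuple, params: HollingLVParams):
    """Right-hand side (dE/dt, dS/dt) of the Holling-LV system."""
    E, S = (state.E, state.S) if isinstance(state, StatePair) else state
    if not (math.isfinite(E) and math.isfinite(S)):
        raise ValueError("state must be finite")
    dE = params.r_e * E * (1.0 - E / params.K_e) + params.r_e * E * (
        params.alpha_es / (1.0 + E)
    ) * S
    dS = params.r_s * S * (1.0 - S / params.K_s) + params.r_s * S * (
        params.alpha_se / (1.0 + S)
    ) * E
    return dE, dS


@njit(cache=True)
def _rk4_sample(r_e, K_e, a_es, r_s, K_s, a_se, E0, S0, t0, times, step):
    """Fixed-step RK4 sampler; compiled hot path shared by all fitting code.

    Takes full steps of ``step`` between sample times plus one shortened
    step landing exactly on each sample time.  Returns (E_out, S_out,
    diverged_flag, divergence_time); on divergence outputs are invalid.
    """
    n = times.shape[0]
    E_out = np.empty(n)
    S_out = np.empty(n)
    E = E0
    S = S0
    t = t0
    guard = 1e12
    for i in range(n):
        target = times[i]
        remaining = target - t
        n_full = int(remaining / step)
        for j in range(n_full + 1):
            if j < n_full:
                h = step
            else:
                h = target - (t + n_full * step)
                if h <= 1e-12 * max(1.0, abs(target)):
                    continue
            # classical RK4 on the coupled system
            k1E = r_e * E * (1.0 - E / K_e) + r_e * E * (a_es / (1.0 + E)) * S
            k1S = r_s * S * (1.0 - S / K_s) + r_s * S * (a_se / (1.0 + S)) * E
            E2 = E + 0.5 * h * k1E
            S2 = S + 0.5 * h * k1S
            k2E = r_e * E2 * (1.0 - E2 / K_e) + r_e * E2 * (a_es / (1.0 + E2)) * S2
            k2S = r_s * S2 * (1.0 - S2 / K_s) + r_s * S2 * (a_se / (1.0 + S2)) * E2
            E3 = E + 0.5 * h * k2E
            S3 = S + 0.5 * h * k2S
            k3E = r_e * E3 * (1.0 - E3 / K_e) + r_e * E3 * (a_es / (1.0 + E3)) * S3
            k3S = r_s * S3 * (1.0 - S3 / K_s) + r_s * S3 * (a_se / (1.0 + S3)) * E3
            E4 = E + h * k3E
            S4 = S + h * k3S
            k4E = r_e * E4 * (1.0 - E4 / K_e) + r_e * E4 * (a_es / (1.0 + E4)) * S4
            k4S = r_s * S4 * (1.0 - S4 / K_s) + r_s * S4 * (a_se / (1.0 + S4)) * E4
            E = E + h / 6.0 * (k1E + 2.0 * k2E + 2.0 * k3E + k4E)
            S = S + h / 6.0 * (k1S + 2.0 * k2S + 2.0 * k3S + k4S)
            if not (abs(E) < guard and abs(S) < guard):
                return E_out, S_out, True, t
        t = target
        if not (math.isfinite(E) and math.isfinite(S)):
            return E_out, S_out, True, t
        E_out[i] = E
        S_out[i] = S
    return E_out, S_out, False, t


def solve_holling_lv(
    params: HollingLVParams,
    init: StatePair | tuple,
    times: Sequence[float],
    step: float = DEFAULT_STEP,
    t0: float | None = None,
) -> Trajectory:
    """Integrate the coupled system with fixed-step RK4, sampling at ``times``.

    Integration starts at ``t0`` (default: the first requested time) from
    ``init``.  Between sample points the solver takes full steps of size
    ``step`` plus one shortened final step landing exactly on the sample
    time, so no post-hoc interpolation is needed.

    Raises
    ------
    TrajectoryDivergenceError
        if the state magnitude exceeds the overflow guard (1e12).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    t_arr = np.asarray(times, dtype=float)
    if t_arr.ndim != 1 or len(t_arr) == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if len(t_arr) > 1 and not np.all(np.diff(t_arr) > 0):
        raise ValueError("times must be strictly increasing")
    E, S = (init.E, init.S) if isinstance(init, StatePair) else map(float, init)
    if E < 0 or S < 0:
        raise ValueError("initial state must be non-negative")
    t = float(t_arr[0]) if t0 is None else float(t0)
    if t_arr[0] < t:
        raise ValueError("first requested time precedes integration start")

    E_out, S_out, diverged, t_div = _rk4_sample(
        params.r_e,
        params.K_e,
        params.alpha_es,
        params.r_s,
        params.K_s,
        params.alpha_se,
        float(E),
        float(S),
        t,
        t_arr,
        float(step),
    )
    if diverged:
        raise TrajectoryDivergenceError(t_div)
    return Trajectory(t_arr.copy(), E_out, S_out)


def logistic_closed_form(r: float, K: float, x0: float, t) -> np.ndarray:
    """Closed-form logistic solution K x0 e^{rt} / (K + x0 (e^{rt} - 1))."""
    t = np.asarray(t, dtype=float)
    if x0 == 0:
        return np.zeros_like(t)
    ert = np.exp(r * t)
    return K * x0 * ert / (K + x0 * (ert - 1.0))


def solve_logistic_pair(
    params: HollingLVParams,
    init: StatePair | tuple,
    times: Sequence[float],
    t0: float | None = None,
) -> Trajectory:
    """Uncoupled (interaction-free) solution of both species.

    With both interaction scalars zero the system decouples into two
    logistic equations with exact closed forms, used for monoculture mean
    curves and as the independent component of the decomposition.
    """
    t_arr = np.asarray(times, dtype=float)
    E0, S0 = (init.E, init.S) if isinstance(init, StatePair) else map(float, init)
    start = float(t_arr[0]) if t0 is None else float(t0)
    rel = t_arr - start
    return Trajectory(
        t_arr.copy(),
        logistic_closed_form(params.r_e, params.K_e, E0, rel),
        logistic_closed_form(params.r_s, params.K_s, S0, rel),
    )


def decompose_trajectory(
    params: HollingLVParams,
    init: StatePair | tuple,
    times: Sequence[float],
    step: float = DEFAULT_STEP,
    t0: float | None = None,
) -> TrajectoryDecomposition:
    """Split the net trajectory into independent and dependent components.

    The independent component is the standalone logistic solution (same r,
    K, and initial state, interaction scalars zero) -- the growth the
    species would show in monoculture.  The dependent component is the
    remainder net - independent, so the identity net = independent +
    dependent is exact at every sampled time.
    """
    net = solve_holling_lv(params, init, times, step=step, t0=t0)
    indep = solve_logistic_pair(params, init, times, t0=t0)
    return TrajectoryDecomposition(
        times=net.times,
        net_E=net.E_values,
        net_S=net.S_values,
        independent_E=indep.E_values,
        independent_S=indep.S_values,
        dependent_E=net.E_values - indep.E_values,
        dependent_S=net.S_values - indep.S_values,
    )


@dataclass(frozen=True)
class ClassicalGrowthParams:
    """Parameters of a classical single-species growth curve.

    model : one of {"gompertz", "logistic", "richards"}
    K     : asymptote (> 0)
    a     : shape parameter
    b     : rate parameter
    m     : Richards exponent (richards only; must be nonzero)
    """

    model: str
    K: float
    a: float
    b: float
    m: float | None = None

    def __post_init__(self):
        if self.model not in ("gompertz", "logistic", "richards"):
            raise ValueError(f"unknown model {self.model!r}")
        if not (math.isfinite(self.K) and self.K > 0):
            raise ValueError("K must be finite and > 0")
        if self.model == "richards":
            if self.m is None or self.m == 0:
                raise ValueError("richards requires a nonzero exponent m")
        elif self.m is not None:
            raise ValueError("m is only meaningful for the richards model")


def classical_growth_curve(params: ClassicalGrowthParams, times) -> np.ndarray:
    """Evaluate a classical growth curve.

    logistic:  K / (1 + a e^{-bt})
    gompertz:  K exp(-a e^{-bt})
    richards:  K / (1 + a e^{-bt})^{1/m}
    """
    t = np.asarray(times, dtype=float)
    decay = np.exp(-params.b * t)
    if params.model == "logistic":
        return params.K / (1.0 + params.a * decay)
    if params.model == "gompertz":
        return params.K * np.exp(-params.a * decay)
    return params.K / (1.0 + params.a * decay) ** (1.0 / params.m)
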