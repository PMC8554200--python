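"""Bivariate first-order structured antedependence (SAD(1)) covariance.

Residuals of each species follow the nonstationary recursion

    e_k(0) = eps_k(0),   e_k(t) = phi_k e_k(t-1) + eps_k(t),   k in {E, S}

with innovation standard deviations nu_k and a contemporaneous
cross-species innovation correlation rho (innovations at different times
are independent).  Writing L_k for the lower-triangular matrix with
(L_k)_{ts} = phi_k^{t-s} (t >= s), the implied 2T x 2T covariance of the
stacked residual vector (e_E; e_S) has blocks

    Sigma_EE = nu_e^2 L_e L_e',   Sigma_SS = nu_s^2 L_s L_s',
    Sigma_ES = rho nu_e nu_s L_e L_s'.

This five-parameter structure is the minimal bivariate SAD(1) producing
within-species serial covariance plus a cross-species covariance band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["SADParams", "build_sad1_covariance", "sad1_innovation_weights"]


@dataclass(frozen=True)
class SADParams:
    """SAD(1) covariance parameters.

    phi_e, phi_s : antedependence (carry-over) coefficients per species
    nu_e, nu_s   : innovation standard deviations (> 0)
    rho          : cross-species innovation correlation, |rho| <= 1
    """

    phi_e: float
    phi_s: float
    nu_e: float
    nu_s: float
    rho: float

    def __post_init__(self):
        for name in ("phi_e", "phi_s", "nu_e", "nu_s", "rho"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.nu_e <= 0 or self.nu_s <= 0:
            raise ValueError("innovation SDs nu_e, nu_s must be > 0")
        if abs(self.rho) > 1:
            raise ValueError("|rho| must be <= 1")


def _antedependence_matrix(phi: float, T: int) -> np.ndarray:
    """Lower-triangular L with L[t, s] = phi^(t-s) for t >= s."""
    powers = np.empty(T)
    powers[0] = 1.0
    for k in range(1, T):
        powers[k] = powers[k - 1] * phi
    idx = np.arange(T)
    lag = idx[:, None] - idx[None, :]
    return np.where(lag >= 0, powers[np.maximum(lag, 0)], 0.0)


def build_sad1_covariance(sad: SADParams, T: int) -> np.ndarray:
    """Covariance matrix of the stacked residuals, ordered (E block, S block).

    Marginal variances grow along the diagonal as
    nu_k^2 (1 + phi_k^2 + ... + phi_k^{2t}) -- the nonstationary
    accumulation characteristic of antedependence models.
    """
    if not isinstance(T, (int, np.integer)) or T < 1:
        raise ValueError("T must be an integer >= 1")
    L_e = _antedependence_matrix(sad.phi_e, T)
    L_s = _antedependence_matrix(sad.phi_s, T)
    ee = sad.nu_e**2 * (L_e @ L_e.T)
    ss = sad.nu_s**2 * (L_s @ L_s.T)
    es = sad.rho * sad.nu_e * sad.nu_s * (L_e @ L_s.T)
    top = np.hstack([ee, es])
    bottom = np.hstack([es.T, ss])
    return np.vstack([top, bottom])


def sad1_innovation_weights(phi: float, t_index: int) -> float:
    """Sum of squared innovation weights 1 + phi^2 + ... + phi^(2 t) at time
    index ``t_index`` (0-based); the marginal residual variance there is
    nu^2 times this factor."""
    if t_index < 0:
        raise ValueError("t_index must be >= 0")
    if phi == 1.0:
        return float(t_index + 1)
    return float((1.0 - phi ** (2 * (t_index + 1))) / (1.0 - phi**2))
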