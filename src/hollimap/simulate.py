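"""Synthetic two-species community mapping datasets and the power study.

The generator emulates the structure of a bacterial co-culture mapping
experiment: n interspecific strain pairs, biallelic haploid marker
panels for both genomes, 16 observation times over 36 hours, mean
trajectories from the Holling type II Lotka-Volterra system with
genotype-combination-specific parameters at one causal marker pair, and
SAD(1)-correlated residuals whose innovation variance is calibrated so
that the genetic fraction of phenotypic variance at a reference time
equals a requested heritability H^2.

Genotype effects are multiplicative offsets: the focal allele of each
genome scales its own species' growth rate and carrying capacity, and
the allele pair jointly scales the interaction scalars (a cross-genome
epistatic component).  Because the innovation variance is recalibrated
from the realised genetic variance, detection power is governed by H^2,
the sample size and the effect/covariance shapes -- not by the absolute
effect magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.stats import binomtest

from .covariance import SADParams, build_sad1_covariance, sad1_innovation_weights
from .dataset import CommunityDataset
from .dynamics import HollingLVParams, logistic_closed_form, solve_holling_lv
from .likelihood import FitConfig, fit_parameters
from .scan import ThresholdSpec, bonferroni_chisq_threshold, lr_statistic

__all__ = [
    "SimulationConfig",
    "default_config",
    "calibrate_noise_from_h2",
    "combination_thetas",
    "simulate_dataset",
    "implied_noncentrality",
    "power_fpr_study",
]

_COMBOS = ("AB", "Ab", "aB", "ab")


@dataclass(frozen=True)
class SimulationConfig:
    """Generating model of one synthetic community mapping dataset.

    Defaults live in ``data/default_simulation.yaml`` (via
    :func:`default_config`), not here: this class only validates.
    """

    n_pairs: int
    n_markers: int
    causal_a: int
    causal_b: int
    times: np.ndarray
    h2: float
    allele_freq: float
    base_theta: HollingLVParams
    init: tuple
    effect_r: float
    effect_K: float
    effect_alpha: float
    sad: SADParams  # nu entries are the template, replaced by calibration when h2 > 0
    seed: int = 0
    solver_step: float = 0.02
    ensure_filled_cells: bool = True

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError("heritability must be in [0, 1)")
        if not 0.0 < self.allele_freq < 1.0:
            raise ValueError("allele frequency must be in (0, 1)")
        if self.causal_a >= self.n_markers or self.causal_b >= self.n_markers:
            raise ValueError("causal marker index must be < n_markers")
        if self.n_pairs < 8:
            raise ValueError("need at least 8 pairs to fill four combination cells")


def default_config(**overrides) -> SimulationConfig:
    """The documented default generating model (see data/default_simulation.yaml)."""
    text = resources.files("hollimap.data").joinpath("default_simulation.yaml").read_text()
    raw = yaml.safe_load(text)
    grid = raw.pop("time_grid")
    times = np.linspace(grid["start"], grid["end"], grid["points"])
    theta = HollingLVParams(**raw.pop("base_theta"))
    sad = SADParams(**raw.pop("sad"))
    init = tuple(raw.pop("init"))
    cfg = dict(raw, times=times, base_theta=theta, sad=sad, init=init)
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def combination_thetas(config: SimulationConfig) -> dict:
    """Per-combination Holling-LV parameters from the multiplicative offsets.

    The uppercase allele of genome A scales (r_e, K_e) up and the
    lowercase down; genome B likewise for (r_s, K_s); the product of the
    two allele signs scales both interaction scalars (epistatic
    component).  With h2 = 0 all four combinations share the base
    parameters (no genotype effect).
    """
    b = config.base_theta
    if config.h2 == 0.0:
        return {c: b for c in _COMBOS}
    out = {}
    for c in _COMBOS:
        s1 = 1.0 if c[0] == "A" else -1.0
        s2 = 1.0 if c[1] == "B" else -1.0
        out[c] = HollingLVParams(
            r_e=b.r_e * (1.0 + s1 * config.effect_r),
            K_e=b.K_e * (1.0 + s1 * config.effect_K),
            alpha_es=b.alpha_es * (1.0 + s1 * s2 * config.effect_alpha),
            r_s=b.r_s * (1.0 + s2 * config.effect_r),
            K_s=b.K_s * (1.0 + s2 * config.effect_K),
            alpha_se=b.alpha_se * (1.0 + s1 * s2 * config.effect_alpha),
        )
    return out


def _combination_frequencies(p: float) -> dict:
    return {
        "AB": p * p,
        "Ab": p * (1 - p),
        "aB": (1 - p) * p,
        "ab": (1 - p) * (1 - p),
    }


def _mean_curves(config: SimulationConfig) -> dict:
    """Per-combination (mu_E, mu_S) on the observation grid, solved from t=0."""
    out = {}
    for c, th in combination_thetas(config).items():
        tr = solve_holling_lv(th, config.init, config.times, step=config.solver_step, t0=0.0)
        out[c] = (tr.E_values, tr.S_values)
    return out


def calibrate_noise_from_h2(
    mean_curves: dict,
    combination_frequencies: dict,
    h2: float,
    sad: SADParams,
    reference_index: int | None = None,
) -> tuple:
    """Innovation SDs (nu_e, nu_s) so the genetic variance fraction at the
    reference time equals h2 per species.

    Genetic variance at each time is the frequency-weighted variance of
    the combination mean curves; the SAD(1) marginal residual variance at
    time index t is nu^2 (1 + phi^2 + ... + phi^(2t)).  The reference
    index defaults to the time of maximum genetic variance per species.
    With h2 = 0 there is nothing to calibrate and the template SDs are
    returned unchanged.
    """
    if not 0.0 <= h2 < 1.0:
        raise ValueError("h2 must be in [0, 1)")
    if h2 == 0.0:
        return sad.nu_e, sad.nu_s
    f = np.array([combination_frequencies[c] for c in _COMBOS])
    f = f / f.sum()
    out = []
    for k, phi in ((0, sad.phi_e), (1, sad.phi_s)):
        curves = np.stack([mean_curves[c][k] for c in _COMBOS])
        mbar = f @ curves
        gvar = f @ (curves - mbar) ** 2
        ref = int(np.argmax(gvar)) if reference_index is None else reference_index
        g = float(gvar[ref])
        if g <= 0:
            raise ValueError("h2 > 0 requires nonzero genetic variance")
        resid = g * (1.0 - h2) / h2
        nu = math.sqrt(resid / sad1_innovation_weights(phi, ref))
        out.append(nu)
    return out[0], out[1]


def _calibrated_sad(config: SimulationConfig, mean_curves: dict) -> SADParams:
    freqs = _combination_frequencies(config.allele_freq)
    nu_e, nu_s = calibrate_noise_from_h2(mean_curves, freqs, config.h2, config.sad)
    return dc_replace(config.sad, nu_e=nu_e, nu_s=nu_s)


def _sad_residuals(rng, sad: SADParams, n: int, T: int) -> tuple:
    """Draw n bivariate SAD(1) residual series of length T."""
    z1 = rng.standard_normal((n, T))
    z2 = rng.standard_normal((n, T))
    eps_e = sad.nu_e * z1
    eps_s = sad.nu_s * (sad.rho * z1 + math.sqrt(1.0 - sad.rho**2) * z2)
    e = np.empty((n, T))
    s = np.empty((n, T))
    e[:, 0] = eps_e[:, 0]
    s[:, 0] = eps_s[:, 0]
    for t in range(1, T):
        e[:, t] = sad.phi_e * e[:, t - 1] + eps_e[:, t]
        s[:, t] = sad.phi_s * s[:, t - 1] + eps_s[:, t]
    return e, s


def _draw_genotypes(rng, config: SimulationConfig) -> tuple:
    n, m, p = config.n_pairs, config.n_markers, config.allele_freq
    ga = (rng.random((n, m)) < p).astype(np.int8)
    gb = (rng.random((n, m)) < p).astype(np.int8)
    if config.ensure_filled_cells:
        # resample the causal columns until all four combination cells have
        # >= 2 members, so the four-genotype fit is always defined
        for _ in range(1000):
            a = ga[:, config.causal_a]
            b = gb[:, config.causal_b]
            cells = np.array(
                [np.sum((a == i) & (b == j)) for i in (1, 0) for j in (1, 0)]
            )
            if cells.min() >= 2:
                break
            ga[:, config.causal_a] = rng.random(n) < p
            gb[:, config.causal_b] = rng.random(n) < p
        else:
            raise RuntimeError("could not fill all four combination cells")
    return ga, gb


def simulate_dataset(config: SimulationConfig) -> CommunityDataset:
    """Generate one complete community mapping dataset.

    Marker alleles are drawn independently at the configured frequency;
    only the causal marker pair carries an effect.  Co-culture
    trajectories are combination means plus bivariate SAD(1) residuals;
    monoculture trajectories are the interaction-free logistic means of
    each strain's own-genome genotype plus univariate SAD(1) residuals.
    The truth record stores the generating parameters for scoring.
    """
    rng = np.random.default_rng(config.seed)
    ga, gb = _draw_genotypes(rng, config)
    n, T = config.n_pairs, len(config.times)

    strains_a = [f"A{i:04d}" for i in range(n)]
    strains_b = [f"B{i:04d}" for i in range(n)]
    marker_ids = [f"M{j:04d}" for j in range(config.n_markers)]
    genotypes_a = pd.DataFrame(ga, index=strains_a, columns=marker_ids)
    genotypes_b = pd.DataFrame(gb, index=strains_b, columns=marker_ids)
    pairing = pd.DataFrame(
        {
            "pair_id": [f"P{i:04d}" for i in range(n)],
            "strain_a": strains_a,
            "strain_b": strains_b,
        }
    )

    curves = _mean_curves(config)
    sad = _calibrated_sad(config, curves)
    a = ga[:, config.causal_a]
    b = gb[:, config.causal_b]
    labels = np.char.add(np.where(a == 1, "A", "a"), np.where(b == 1, "B", "b"))

    mu_E = np.stack([curves[lab][0] for lab in labels])
    mu_S = np.stack([curves[lab][1] for lab in labels])
    res_E, res_S = _sad_residuals(rng, sad, n, T)
    co_E = mu_E + res_E
    co_S = mu_S + res_S

    # monoculture: own-genome effect only, interaction-free logistic means
    thetas = combination_thetas(config)
    t = config.times
    mono_mu_E = np.stack(
        [
            logistic_closed_form(
                thetas["AB" if ai == 1 else "ab"].r_e,
                thetas["AB" if ai == 1 else "ab"].K_e,
                config.init[0],
                t,
            )
            for ai in a
        ]
    )
    mono_mu_S = np.stack(
        [
            logistic_closed_form(
                thetas["AB" if bi == 1 else "ab"].r_s,
                thetas["AB" if bi == 1 else "ab"].K_s,
                config.init[1],
                t,
            )
            for bi in b
        ]
    )
    me, _ = _sad_residuals(rng, sad, n, T)
    _, ms = _sad_residuals(rng, sad, n, T)
    mono_E = mono_mu_E + me
    mono_S = mono_mu_S + ms

    truth = {
        "causal_a": marker_ids[config.causal_a],
        "causal_b": marker_ids[config.causal_b],
        "h2": config.h2,
        "seed": config.seed,
        "sad": {
            "phi_e": sad.phi_e,
            "phi_s": sad.phi_s,
            "nu_e": sad.nu_e,
            "nu_s": sad.nu_s,
            "rho": sad.rho,
        },
        "thetas": {
            c: dict(zip(HollingLVParams.FIELD_ORDER, th.as_array().tolist()))
            for c, th in thetas.items()
        },
        "init": list(config.init),
    }
    return CommunityDataset(
        genotypes_a=genotypes_a,
        genotypes_b=genotypes_b,
        pairing=pairing,
        times=t,
        co_E=co_E,
        co_S=co_S,
        mono_E=mono_E,
        mono_S=mono_S,
        truth=truth,
    )


def implied_noncentrality(config: SimulationConfig, n_pairs: int | None = None) -> float:
    """Design-calculation noncentrality of the four-combination LR test.

    Computes sum_j n f_j delta_j' Sigma^-1 delta_j with delta_j the
    combination mean deviation (stacked E; S) and Sigma the calibrated
    SAD(1) covariance: the asymptotic noncentral-chi-square parameter of
    the causal-pair scan under this generating model.  Used for power
    analysis, not by the estimator.
    """
    n = config.n_pairs if n_pairs is None else n_pairs
    curves = _mean_curves(config)
    sad = _calibrated_sad(config, curves)
    freqs = _combination_frequencies(config.allele_freq)
    sigma = build_sad1_covariance(sad, len(config.times))
    mus = {c: np.concatenate(curves[c]) for c in _COMBOS}
    f = np.array([freqs[c] for c in _COMBOS])
    f = f / f.sum()
    stacked = np.stack([mus[c] for c in _COMBOS])
    mbar = f @ stacked
    lam = 0.0
    for fc, c in zip(f, _COMBOS):
        d = mus[c] - mbar
        lam += n * fc * float(d @ np.linalg.solve(sigma, d))
    return lam


def _study_threshold(spec: ThresholdSpec) -> float:
    if spec.method != "bonferroni_chisq":
        raise ValueError("the power study uses a chi-square threshold spec")
    return bonferroni_chisq_threshold(1, spec.alpha, spec.df or 18)


def power_fpr_study(
    settings,
    replicates: int = 200,
    threshold_spec: ThresholdSpec = ThresholdSpec(method="bonferroni_chisq", alpha=0.05, df=18),
    seed: int = 0,
    base_config: SimulationConfig | None = None,
    fit_config: FitConfig | None = None,
) -> pd.DataFrame:
    """Empirical power / false-positive-rate study at the causal marker pair.

    For each (n_pairs, h2) setting, simulates ``replicates`` datasets,
    tests the causal marker pair (four-combination fit against the shared
    null, both solved by the simplex/Runge-Kutta hybrid) against the
    chi-square threshold, and reports the rejection fraction: power when
    h2 > 0, false positive rate when h2 = 0.  A Wilson 95% binomial
    interval accompanies each cell.

    Each replicate simulates only the causal marker pair (non-causal
    markers carry no effect and are irrelevant to this per-locus test).
    """
    if replicates < 20:
        raise ValueError("need at least 20 replicates for a meaningful rate")
    base = default_config() if base_config is None else base_config
    fit = fit_config if fit_config is not None else FitConfig(
        step=0.1, n_restarts=1, max_cycles=4, block_maxfev=250, sad_maxfev=200,
        tol=1e-3,
    )
    crit = _study_threshold(threshold_spec)
    root = np.random.default_rng(seed)
    rows = []
    import warnings as _warnings

    for n_pairs, h2 in settings:
        hits = 0
        for _rep in range(replicates):
            rep_seed = int(root.integers(0, 2**31 - 1))
            cfg = dc_replace(
                base, n_pairs=n_pairs, h2=h2, n_markers=1, causal_a=0, causal_b=0,
                seed=rep_seed,
            )
            ds = simulate_dataset(cfg)
            Y = ds.Y_coculture()
            labels = np.char.add(
                np.where(ds.genome_alleles("A", "M0000") == 1, "A", "a"),
                np.where(ds.genome_alleles("B", "M0000") == 1, "B", "b"),
            )
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)
                h0 = fit_parameters(Y, np.zeros(len(Y)), ds.times, mode="null", config=fit)
                h1 = fit_parameters(
                    Y, labels, ds.times, mode="by_combination", config=fit, warm_start=h0
                )
                lr = lr_statistic(h0.loglik, h1.loglik)
            if lr >= crit:
                hits += 1
        rate = hits / replicates
        ci = binomtest(hits, replicates).proportion_ci(0.95, method="wilson")
        rows.append(
            {
                "n_pairs": n_pairs,
                "h2": h2,
                "measure": "power" if h2 > 0 else "fpr",
                "value": rate,
                "ci_low": ci.low,
                "ci_high": ci.high,
                "replicates": replicates,
                "threshold": crit,
            }
        )
    return pd.DataFrame(rows)
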