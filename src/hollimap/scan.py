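"""Likelihood-ratio genome scans for interaction QTLs.

Each marker test compares the genotype-invariant null (one shared set of
growth parameters for all individuals) against genotype-specific
alternatives, with the statistic LR = 2 (log L1 - log L0).  One-genome
scans split individuals into the two haploid genotype classes of a
marker; the two-genome scan crosses one marker from each species'
genome, forming the four interspecific combinations AB, Ab, aB, ab.
Critical thresholds come either from permutation of whole phenotype
trajectories (preserving the longitudinal covariance) or from a
chi-square quantile with Bonferroni correction.

Because the null fit does not depend on the marker, each scan fits it
once and warm-starts every per-marker alternative fit from it; simplex
refinement from that start keeps nested statistics non-negative.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .dataset import CommunityDataset
from .likelihood import FitConfig, GenotypeModel, fit_constrained, fit_parameters

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdSpec",
    "ScanResult",
    "ScanOutput",
    "lr_statistic",
    "scan_one_genome",
    "scan_two_genomes",
    "subset_test",
    "permutation_threshold",
    "bonferroni_chisq_threshold",
]

#: free ODE parameters per genotype class, by analysis type
DF_PER_CLASS = {"coculture_1d": 6, "coculture_2d": 6, "monoculture": 2}

_LR_TOL = 1e-6


@dataclass(frozen=True)
class ThresholdSpec:
    """How to derive the critical value of the LR scan.

    method       : "permutation" or "bonferroni_chisq"
    alpha        : significance level (post-correction per-test level for
                   the chi-square method; genome-wide level for permutation)
    permutations : permutation count (>= 20)
    df           : chi-square degrees of freedom (chi-square method only)
    """

    method: str = "bonferroni_chisq"
    alpha: float = 0.05
    permutations: int = 100
    df: int | None = None

    def __post_init__(self):
        if self.method not in ("permutation", "bonferroni_chisq"):
            raise ValueError(f"unknown threshold method {self.method!r}")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.method == "permutation" and self.permutations < 20:
            raise ValueError("permutation count must be >= 20")


@dataclass(frozen=True)
class ScanResult:
    """One tested unit (a marker, or an ordered marker pair, species A first)."""

    marker: tuple
    lr: float
    threshold: float
    significant: bool
    test_type: str
    thetas: dict
    loglik_null: float
    loglik_alt: float


@dataclass
class ScanOutput:
    """Scan results plus the skipped-unit log and the threshold used."""

    results: list
    skipped: list
    threshold: float
    threshold_spec: ThresholdSpec


def lr_statistic(loglik_null: float, loglik_alt: float) -> float:
    """LR = 2 (l1 - l0), clipped at zero (warns beyond optimizer tolerance)."""
    if not (math.isfinite(loglik_null) and math.isfinite(loglik_alt)):
        raise ValueError("log-likelihoods must be finite")
    lr = 2.0 * (loglik_alt - loglik_null)
    if lr < -_LR_TOL:
        warnings.warn(
            f"negative LR {lr:.3g} clipped to 0 (optimizer noise beyond tolerance)",
            RuntimeWarning,
        )
    return max(lr, 0.0)


def bonferroni_chisq_threshold(n_tests: int, alpha: float, df: int) -> float:
    """Upper chi-square quantile at per-test level alpha / n_tests.

    Call with n_tests=1 when alpha is already the post-correction per-test
    level (e.g. the 1e-6 level of a two-genome scan).
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if df < 1:
        raise ValueError("df must be >= 1")
    if alpha == 1.0 and n_tests == 1:
        return 0.0
    return float(chi2.isf(alpha / n_tests, df))


def _allele_labels(alleles: np.ndarray, letter: str) -> np.ndarray:
    """Haploid labels: allele 1 -> uppercase, allele 0 -> lowercase."""
    return np.where(np.asarray(alleles) == 1, letter.upper(), letter.lower())


def _scan_markers_one_genome(Y, times, geno_rows, markers, h0, config, culture, species):
    """Per-marker alternative fits against a shared null; yields (marker, fit or reason)."""
    for marker in markers:
        alleles = geno_rows[marker].to_numpy()
        counts = np.bincount(alleles.astype(int), minlength=2)
        if counts.min() == 0:
            yield marker, None, "monomorphic"
            continue
        if counts.min() < 2:
            yield marker, None, "genotype class with <2 individuals"
            continue
        labels = _allele_labels(alleles, "a")
        alt = fit_parameters(
            Y,
            labels,
            times,
            mode="by_combination",
            config=config,
            culture=culture,
            species=species,
            warm_start=h0,
        )
        yield marker, alt, None


def _one_genome_setup(dataset: CommunityDataset, genome: str, culture_mode: str):
    if culture_mode == "coculture":
        Y = dataset.Y_coculture()
        culture, species = "coculture", None
    elif culture_mode == "monoculture":
        if genome == "A":
            if dataset.mono_E is None:
                raise ValueError("dataset has no species-A monoculture data")
            Y, species = dataset.mono_E, "E"
        else:
            if dataset.mono_S is None:
                raise ValueError("dataset has no species-B monoculture data")
            Y, species = dataset.mono_S, "S"
        culture = "monoculture"
    else:
        raise ValueError(f"unknown culture_mode {culture_mode!r}")
    if culture_mode == "coculture":
        col = "strain_a" if genome == "A" else "strain_b"
        geno = dataset.genotypes_a if genome == "A" else dataset.genotypes_b
        geno_rows = geno.loc[dataset.pairing[col]]
    else:
        geno_rows = dataset.genotypes_a if genome == "A" else dataset.genotypes_b
    return Y, geno_rows, culture, species


def scan_one_genome(
    dataset: CommunityDataset,
    genome: str = "A",
    culture_mode: str = "coculture",
    threshold: ThresholdSpec = ThresholdSpec(method="permutation", alpha=0.01),
    config: FitConfig = FitConfig(n_restarts=1),
    markers=None,
    seed: int = 0,
) -> ScanOutput:
    """Scan one genome's markers for growth-trajectory QTLs.

    In co-culture mode both species' trajectories are modelled jointly by
    the coupled Holling-LV system; in monoculture mode the scanned
    genome's own species is modelled by the interaction-free logistic
    reduction.  Markers whose minor allele count is below 2 are skipped
    and logged.
    """
    Y, geno_rows, culture, species = _one_genome_setup(dataset, genome, culture_mode)
    markers = list(geno_rows.columns if markers is None else markers)
    h0 = fit_parameters(
        Y, np.zeros(len(Y)), dataset.times, mode="null",
        config=config, culture=culture, species=species,
    )
    df = DF_PER_CLASS["monoculture" if culture == "monoculture" else "coculture_1d"]

    fits = {}
    skipped = []
    for marker, alt, reason in _scan_markers_one_genome(
        Y, dataset.times, geno_rows, markers, h0, config, culture, species
    ):
        if reason is not None:
            skipped.append((marker, reason))
            logger.info("marker %s skipped: %s", marker, reason)
        else:
            fits[marker] = alt

    if threshold.method == "permutation":
        crit = permutation_threshold(
            dataset,
            genome=genome,
            culture_mode=culture_mode,
            spec=threshold,
            seed=seed,
            config=config,
            markers=[m for m in markers if m in fits],
        )
    else:
        crit = bonferroni_chisq_threshold(
            max(len(fits), 1), threshold.alpha, threshold.df or df
        )

    results = []
    for marker, alt in fits.items():
        lr = lr_statistic(h0.loglik, alt.loglik)
        results.append(
            ScanResult(
                marker=(marker,),
                lr=lr,
                threshold=crit,
                significant=lr >= crit,
                test_type="overall",
                thetas=dict(alt.thetas),
                loglik_null=h0.loglik,
                loglik_alt=alt.loglik,
            )
        )
    return ScanOutput(results, skipped, crit, threshold)


def pair_labels(dataset: CommunityDataset, marker_a, marker_b) -> np.ndarray:
    """Four-combination labels AB/Ab/aB/ab for every co-culture pair."""
    al_a = dataset.genome_alleles("A", marker_a)
    al_b = dataset.genome_alleles("B", marker_b)
    first = np.where(al_a == 1, "A", "a")
    second = np.where(al_b == 1, "B", "b")
    return np.char.add(first, second)


def scan_two_genomes(
    dataset: CommunityDataset,
    threshold: ThresholdSpec = ThresholdSpec(method="bonferroni_chisq", alpha=1e-6, df=18),
    config: FitConfig = FitConfig(n_restarts=1),
    markers_a=None,
    markers_b=None,
    seed: int = 0,
) -> ScanOutput:
    """Pairwise two-genome scan over (marker_A, marker_B) combinations.

    For each pair the four interspecific genotype combinations get their
    own Holling-LV parameter set under the alternative; the null shares
    one set across all pairs.  Pairs with any combination cell below two
    members are skipped and flagged.
    """
    Y = dataset.Y_coculture()
    times = dataset.times
    markers_a = list(dataset.genotypes_a.columns if markers_a is None else markers_a)
    markers_b = list(dataset.genotypes_b.columns if markers_b is None else markers_b)
    h0 = fit_parameters(Y, np.zeros(len(Y)), times, mode="null", config=config)

    fits = {}
    skipped = []
    for ma in markers_a:
        for mb in markers_b:
            labels = pair_labels(dataset, ma, mb)
            _, cell_counts = np.unique(labels, return_counts=True)
            if len(cell_counts) < 4 or cell_counts.min() < 2:
                reason = (
                    "monomorphic marker in pair"
                    if len(cell_counts) < 4
                    else "combination cell with <2 pairs"
                )
                skipped.append(((ma, mb), reason))
                logger.info("pair (%s, %s) skipped: %s", ma, mb, reason)
                continue
            alt = fit_parameters(
                Y, labels, times, mode="by_combination", config=config, warm_start=h0
            )
            fits[(ma, mb)] = alt

    if threshold.method == "permutation":
        crit = _permutation_threshold_2d(dataset, threshold, seed, config, list(fits))
    else:
        crit = bonferroni_chisq_threshold(
            max(len(fits), 1), threshold.alpha, threshold.df or 18
        )

    results = []
    for (ma, mb), alt in fits.items():
        lr = lr_statistic(h0.loglik, alt.loglik)
        results.append(
            ScanResult(
                marker=(ma, mb),
                lr=lr,
                threshold=crit,
                significant=lr >= crit,
                test_type="overall",
                thetas=dict(alt.thetas),
                loglik_null=h0.loglik,
                loglik_alt=alt.loglik,
            )
        )
    return ScanOutput(results, skipped, crit, threshold)


def subset_test(
    dataset: CommunityDataset,
    assignment,
    which: str,
    threshold: ThresholdSpec = ThresholdSpec(method="bonferroni_chisq", alpha=0.05, df=12),
    config: FitConfig = FitConfig(n_restarts=1),
    full_model: GenotypeModel | None = None,
) -> ScanResult:
    """Test whether a significant locus acts on independent or interaction growth.

    which="independent": the constrained null shares (r_e, K_e, r_s, K_s)
    across combinations (interaction scalars stay free) -- rejecting it
    means the locus alters the species' intrinsic growth.
    which="interaction": the null shares (r_e, alpha_es, r_s, alpha_se) --
    rejecting it means the locus alters the interspecific interaction.
    """
    Y = dataset.Y_coculture()
    times = dataset.times
    labels = np.asarray(assignment)
    if full_model is None:
        h0 = fit_parameters(Y, labels, times, mode="null", config=config)
        full_model = fit_parameters(
            Y, labels, times, mode="by_combination", config=config, warm_start=h0
        )
    constrained = fit_constrained(
        Y, labels, times, which=which, config=config, warm_start=full_model
    )
    lr = lr_statistic(constrained.loglik, full_model.loglik)
    n_groups = len(np.unique(labels))
    df = 4 * (n_groups - 1)
    crit = (
        bonferroni_chisq_threshold(1, threshold.alpha, threshold.df or df)
        if threshold.method == "bonferroni_chisq"
        else float("nan")
    )
    return ScanResult(
        marker=("subset",),
        lr=lr,
        threshold=crit,
        significant=lr >= crit,
        test_type=f"{which}_subset",
        thetas=dict(full_model.thetas),
        loglik_null=constrained.loglik,
        loglik_alt=full_model.loglik,
    )


def _max_lr_over_markers(Y, times, geno_rows, markers, h0, config, culture, species):
    best = 0.0
    for _, alt, reason in _scan_markers_one_genome(
        Y, times, geno_rows, markers, h0, config, culture, species
    ):
        if reason is None:
            best = max(best, lr_statistic(h0.loglik, alt.loglik))
    return best


def _order_statistic_threshold(max_lrs: np.ndarray, alpha: float) -> float:
    B = len(max_lrs)
    k = int(alpha * B)
    if k < 1:
        raise ValueError(
            f"{B} permutations cannot resolve the {alpha} quantile; need >= {math.ceil(1 / alpha)}"
        )
    return float(np.sort(max_lrs)[-k])


def permutation_threshold(
    dataset: CommunityDataset,
    genome: str = "A",
    culture_mode: str = "coculture",
    spec: ThresholdSpec = ThresholdSpec(method="permutation", alpha=0.01),
    seed: int = 0,
    config: FitConfig = FitConfig(n_restarts=1),
    markers=None,
) -> float:
    """Genome-wide critical value by trajectory permutation.

    Whole phenotype trajectories are permuted against the genotype rows
    (preserving the longitudinal covariance and, in co-culture, the pair
    structure); the (1 - alpha) order statistic of the per-permutation
    maximum LR over markers is returned.
    """
    if spec.permutations < math.ceil(1.0 / spec.alpha):
        raise ValueError(
            f"{spec.permutations} permutations cannot resolve alpha={spec.alpha}"
        )
    Y, geno_rows, culture, species = _one_genome_setup(dataset, genome, culture_mode)
    markers = list(geno_rows.columns if markers is None else markers)
    h0 = fit_parameters(
        Y, np.zeros(len(Y)), dataset.times, mode="null",
        config=config, culture=culture, species=species,
    )
    rng = np.random.default_rng(seed)
    max_lrs = np.empty(spec.permutations)
    for b in range(spec.permutations):
        perm = rng.permutation(len(Y))
        max_lrs[b] = _max_lr_over_markers(
            Y[perm], dataset.times, geno_rows, markers, h0, config, culture, species
        )
    return _order_statistic_threshold(max_lrs, spec.alpha)


def _permutation_threshold_2d(dataset, spec, seed, config, pairs):
    Y = dataset.Y_coculture()
    times = dataset.times
    h0 = fit_parameters(Y, np.zeros(len(Y)), times, mode="null", config=config)
    rng = np.random.default_rng(seed)
    max_lrs = np.empty(spec.permutations)
    for b in range(spec.permutations):
        perm = rng.permutation(len(Y))
        Yp = Y[perm]
        best = 0.0
        for ma, mb in pairs:
            labels = pair_labels(dataset, ma, mb)
            alt = fit_parameters(
                Yp, labels, times, mode="by_combination", config=config, warm_start=h0
            )
            best = max(best, lr_statistic(h0.loglik, alt.loglik))
        max_lrs[b] = best
    return _order_statistic_threshold(max_lrs, spec.alpha)
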