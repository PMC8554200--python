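"""Time-varying genetic effect curves and the factorial effect partition.

For a single locus, the genetic effect curve is half the pointwise
difference between the two genotype mean curves (the haploid additive
effect).  For a cross-species locus pair with the four genotype
combinations AB, Ab, aB, ab, each species' genotypic value curves are
partitioned by orthogonal 2x2 factorial contrasts into

    mean      (mu_AB + mu_Ab + mu_aB + mu_ab) / 4
    direct    ((mu_AB + mu_Ab) - (mu_aB + mu_ab)) / 4     (own genome)
    indirect  ((mu_AB + mu_aB) - (mu_Ab + mu_ab)) / 4     (partner genome)
    epistatic (mu_AB - mu_Ab - mu_aB + mu_ab) / 4

where "direct" refers to the genome of the focal species (the first
index when the focal species is A, the second when it is B).  Each
combination's genotypic value is reconstructed exactly as mean plus the
signed sum of the three effects, and under equal combination frequencies
the three effect variances sum to the total genotypic variance at every
time point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EffectDecomposition",
    "genetic_effect_curve",
    "partition_genotypic_values",
    "effect_variance_curves",
]

# contrast signs for (direct_A, indirect_A) per combination, order AB, Ab, aB, ab
_COMBOS = ("AB", "Ab", "aB", "ab")
_SIGN_FIRST = {"AB": 1.0, "Ab": 1.0, "aB": -1.0, "ab": -1.0}  # first-genome allele
_SIGN_SECOND = {"AB": 1.0, "Ab": -1.0, "aB": 1.0, "ab": -1.0}  # second-genome allele


@dataclass(frozen=True)
class EffectDecomposition:
    """Effect curves for one focal species at a locus pair.

    ``mean``, ``direct``, ``indirect``, ``epistatic`` are curves on
    ``times``; signs are oriented so that for combination AB the
    genotypic value equals mean + direct + indirect + epistatic.
    """

    times: np.ndarray
    focal_species: str
    mean: np.ndarray
    direct: np.ndarray
    indirect: np.ndarray
    epistatic: np.ndarray

    def reconstruct(self, combination: str) -> np.ndarray:
        """Genotypic value curve of one combination from the effects."""
        if combination not in _COMBOS:
            raise ValueError(f"unknown combination {combination!r}")
        s_own = (
            _SIGN_FIRST[combination]
            if self.focal_species == "E"
            else _SIGN_SECOND[combination]
        )
        s_partner = (
            _SIGN_SECOND[combination]
            if self.focal_species == "E"
            else _SIGN_FIRST[combination]
        )
        return (
            self.mean
            + s_own * self.direct
            + s_partner * self.indirect
            + s_own * s_partner * self.epistatic
        )


def _check_grids(*curves):
    arrs = [np.asarray(c, dtype=float) for c in curves]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("curves must share one time grid (equal lengths)")
    return arrs


def genetic_effect_curve(mu_genotype1, mu_genotype2) -> np.ndarray:
    """Additive genetic effect curve of a single locus: (mu1 - mu2) / 2."""
    m1, m2 = _check_grids(mu_genotype1, mu_genotype2)
    return 0.5 * (m1 - m2)


def partition_genotypic_values(
    mu_AB, mu_Ab, mu_aB, mu_ab, focal_species: str = "E", times=None
) -> EffectDecomposition:
    """Partition four combination curves into direct/indirect/epistatic effects.

    ``focal_species`` "E" treats the first genotype index (species A
    genome) as the own genome; "S" treats the second index as own.
    """
    if focal_species not in ("E", "S"):
        raise ValueError("focal_species must be 'E' or 'S'")
    mAB, mAb, maB, mab = _check_grids(mu_AB, mu_Ab, mu_aB, mu_ab)
    t = np.arange(len(mAB)) if times is None else np.asarray(times, dtype=float)
    if len(t) != len(mAB):
        raise ValueError("times length must match curves")
    mean = (mAB + mAb + maB + mab) / 4.0
    first = ((mAB + mAb) - (maB + mab)) / 4.0  # first-genome main effect
    second = ((mAB + maB) - (mAb + mab)) / 4.0  # second-genome main effect
    epi = (mAB - mAb - maB + mab) / 4.0
    if focal_species == "E":
        direct, indirect = first, second
    else:
        direct, indirect = second, first
    return EffectDecomposition(
        times=t,
        focal_species=focal_species,
        mean=mean,
        direct=direct,
        indirect=indirect,
        epistatic=epi,
    )


def effect_variance_curves(
    decomposition: EffectDecomposition, combination_frequencies: dict | None = None
) -> dict:
    """Time-varying genetic variance explained by each effect component.

    For each component, the variance at time t is the frequency-weighted
    variance of that component's signed contribution across the four
    combinations.  Under equal frequencies this reduces to the squared
    effect curve, the three contrasts are orthogonal, and the variances
    sum to the total variance of the four genotypic values.
    """
    if combination_frequencies is None:
        freqs = {c: 0.25 for c in _COMBOS}
    else:
        freqs = dict(combination_frequencies)
        missing = set(_COMBOS) - set(freqs)
        if missing:
            raise ValueError(f"missing combination frequencies: {sorted(missing)}")
        vals = np.array([freqs[c] for c in _COMBOS], dtype=float)
        if np.any(vals < 0):
            raise ValueError("combination frequencies must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-8:
            raise ValueError("combination frequencies must sum to 1")

    f = np.array([freqs[c] for c in _COMBOS])
    own_sign = _SIGN_FIRST if decomposition.focal_species == "E" else _SIGN_SECOND
    partner_sign = _SIGN_SECOND if decomposition.focal_species == "E" else _SIGN_FIRST
    s_dir = np.array([own_sign[c] for c in _COMBOS])
    s_ind = np.array([partner_sign[c] for c in _COMBOS])
    s_epi = s_dir * s_ind

    def weighted_var(curve, signs):
        # contributions: signs[j] * curve(t); variance across combinations
        contrib = signs[:, None] * curve[None, :]
        m = (f[:, None] * contrib).sum(axis=0)
        return (f[:, None] * (contrib - m) ** 2).sum(axis=0)

    return {
        "direct": weighted_var(decomposition.direct, s_dir),
        "indirect": weighted_var(decomposition.indirect, s_ind),
        "epistatic": weighted_var(decomposition.epistatic, s_epi),
    }
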