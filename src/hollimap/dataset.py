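"""In-memory container for a two-species community mapping dataset.

Holds the genotype matrices of both mapping populations (strains x
biallelic markers, haploid 0/1 coding), the pairing of species-A strains
with species-B strains in co-culture, the longitudinal abundances
(co-culture per pair, monoculture per strain), and -- for simulated data
-- the generating truth record used for scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CommunityDataset"]


@dataclass
class CommunityDataset:
    """A complete mapping dataset.

    genotypes_a, genotypes_b : DataFrame, strain id index x marker columns (0/1)
    pairing   : DataFrame with columns pair_id, strain_a, strain_b
    times     : observation times in hours, shared by all series
    co_E, co_S: co-culture abundances, one row per pair (pairing order), T columns
    mono_E    : monoculture abundances of species A strains (genotypes_a order)
    mono_S    : monoculture abundances of species B strains (genotypes_b order)
    truth     : generating-model record for simulated data (None for real data)
    """

    genotypes_a: pd.DataFrame
    genotypes_b: pd.DataFrame
    pairing: pd.DataFrame
    times: np.ndarray
    co_E: np.ndarray
    co_S: np.ndarray
    mono_E: np.ndarray | None = None
    mono_S: np.ndarray | None = None
    truth: dict | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        n = len(self.pairing)
        for name in ("co_E", "co_S"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, len(self.times)):
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected ({n}, {len(self.times)})"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite abundances")
            setattr(self, name, arr)
        for col in ("pair_id", "strain_a", "strain_b"):
            if col not in self.pairing.columns:
                raise ValueError(f"pairing table lacks column {col!r}")
        unknown_a = set(self.pairing["strain_a"]) - set(self.genotypes_a.index)
        unknown_b = set(self.pairing["strain_b"]) - set(self.genotypes_b.index)
        if unknown_a or unknown_b:
            raise ValueError(
                f"pairing references unknown strains: {sorted(unknown_a | unknown_b)}"
            )

    @property
    def n_pairs(self) -> int:
        return len(self.pairing)

    @property
    def T(self) -> int:
        return len(self.times)

    def Y_coculture(self) -> np.ndarray:
        """Stacked (E block; S block) co-culture phenotype matrix, (n, 2T)."""
        return np.hstack([self.co_E, self.co_S])

    def genome_alleles(self, genome: str, marker) -> np.ndarray:
        """Alleles (0/1) of the tested genome's strains in pairing order."""
        if genome == "A":
            geno, col = self.genotypes_a, "strain_a"
        elif genome == "B":
            geno, col = self.genotypes_b, "strain_b"
        else:
            raise ValueError("genome must be 'A' or 'B'")
        return geno.loc[self.pairing[col], marker].to_numpy()
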