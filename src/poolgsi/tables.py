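"""Core in-memory containers shared across the pipeline.

The central object is the :class:`AlleleFrequencyTable`: a loci x populations
matrix of B-allele frequencies estimated either from pooled-DNA allelotyping
or from individual genotypes, together with the nominal number of diploid
individuals behind each population's estimate.  The "B" allele is, by
convention, the allele whose array theta increases with its dosage; fixing a
single orientation up front avoids allele-label switching when tables from
different sources are merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["AlleleFrequencyTable", "MultiallelicTable"]


@dataclass
class AlleleFrequencyTable:
    """Population allele frequencies for a panel of biallelic loci.

    Parameters
    ----------
    freq
        DataFrame indexed by locus id with one column per population;
        values are B-allele frequencies in [0, 1].
    n_individuals
        Number of diploid individuals per population (2n gene copies enter
        sample-size aware statistics such as the F_ST estimator).
    """

    freq: pd.DataFrame
    n_individuals: pd.Series

    def __post_init__(self) -> None:
        self.freq = self.freq.astype(float)
        if self.freq.index.has_duplicates:
            dups = self.freq.index[self.freq.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate locus ids: {dups[:5]}")
        if self.freq.columns.has_duplicates:
            raise ValueError("duplicate population names")
        vals = self.freq.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("missing cells in allele-frequency table")
        if (vals < 0).any() or (vals > 1).any():
            bad = np.argwhere((vals < 0) | (vals > 1))[0]
            raise ValueError(
                "frequency outside [0,1] at locus "
                f"{self.freq.index[bad[0]]!r}, population {self.freq.columns[bad[1]]!r}"
            )
        self.n_individuals = pd.Series(self.n_individuals, dtype=float).reindex(
            self.freq.columns
        )
        if self.n_individuals.isna().any():
            missing = self.n_individuals.index[self.n_individuals.isna()].tolist()
            raise ValueError(f"missing pool size for populations: {missing}")
        if (self.n_individuals < 1).any():
            raise ValueError("n_individuals must be >= 1 for every population")

    @property
    def populations(self) -> list[str]:
        return list(self.freq.columns)

    @property
    def loci(self) -> list[str]:
        return list(self.freq.index)

    @property
    def n_pops(self) -> int:
        return self.freq.shape[1]

    @property
    def n_loci(self) -> int:
        return self.freq.shape[0]

    def subset_populations(self, populations: Sequence[str]) -> "AlleleFrequencyTable":
        missing = [p for p in populations if p not in self.freq.columns]
        if missing:
            raise KeyError(f"unknown populations: {missing}")
        return AlleleFrequencyTable(
            self.freq.loc[:, list(populations)].copy(),
            self.n_individuals.loc[list(populations)].copy(),
        )

    def subset_loci(self, loci: Sequence[str]) -> "AlleleFrequencyTable":
        missing = [l for l in loci if l not in self.freq.index]
        if missing:
            raise KeyError(f"unknown loci: {missing[:5]}")
        return AlleleFrequencyTable(
            self.freq.loc[list(loci)].copy(), self.n_individuals.copy()
        )


@dataclass
class MultiallelicTable:
    """Allele frequencies for multiallelic (STR-like) loci.

    ``freqs`` maps locus id to an array of shape (n_populations, k_alleles);
    rows sum to 1.  Population order is shared across loci.
    """

    populations: list[str]
    freqs: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, arr in self.freqs.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[0] != len(self.populations):
                raise ValueError(f"locus {locus!r}: bad shape {arr.shape}")
            if arr.shape[1] < 2:
                raise ValueError(f"locus {locus!r}: needs >= 2 alleles")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"locus {locus!r}: frequencies do not sum to 1")

    @property
    def loci(self) -> list[str]:
        return list(self.freqs)

    def alleles_per_locus(self) -> dict[str, int]:
        return {l: a.shape[1] for l, a in self.freqs.items()}
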