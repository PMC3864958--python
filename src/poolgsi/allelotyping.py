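"""Pooled-DNA theta correction and replicate quality control.

On a two-colour SNP array the normalised signal ratio ("theta") of a pooled
DNA sample reflects the pool's allele frequency, but the genotype clusters
AA/AB/BB sit at locus-specific thetas rather than the theoretical 0 / 0.5 / 1.
The correction anchors each pool theta against the per-locus cluster means
estimated from individually genotyped reference samples and interpolates
linearly within each half of the cluster range.

A locus is kept only when its technical pool replicates agree (replicate
standard deviation of theta at or below a threshold, 0.02 by default) in
every population; frequencies are then estimated per replicate and averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import AlleleFrequencyTable

__all__ = [
    "ClusterReference",
    "theta_to_frequency",
    "frequency_to_theta",
    "filter_replicate_quality",
    "pool_frequencies",
]


@dataclass
class ClusterReference:
    """Per-locus mean thetas of the AA, AB and BB genotype clusters.

    ``table`` is indexed by locus id with columns theta_AA, theta_AB,
    theta_BB, strictly increasing within every row.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["theta_AA", "theta_AB", "theta_BB"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"cluster reference missing columns: {missing}")
        t = self.table[required].to_numpy(dtype=float)
        bad = ~((t[:, 0] < t[:, 1]) & (t[:, 1] < t[:, 2]))
        if bad.any():
            locus = self.table.index[np.argmax(bad)]
            raise ValueError(
                f"cluster thetas not strictly ordered AA<AB<BB at locus {locus!r}"
            )

    def aligned(self, loci) -> pd.DataFrame:
        missing = [l for l in loci if l not in self.table.index]
        if missing:
            raise ValueError(f"loci missing from cluster reference: {missing[:5]}")
        return self.table.loc[list(loci), ["theta_AA", "theta_AB", "theta_BB"]]


def theta_to_frequency(theta, ref_AA, ref_AB, ref_BB):
    """Convert array theta to B-allele frequency by piecewise-linear anchoring.

    Thetas at or below the AA cluster map to 0, at or above BB to 1; the
    AA->AB segment covers frequencies 0-0.5 and AB->BB covers 0.5-1.
    Accepts scalars or broadcastable arrays.
    """
    theta = np.asarray(theta, dtype=float)
    ref_AA = np.asarray(ref_AA, dtype=float)
    ref_AB = np.asarray(ref_AB, dtype=float)
    ref_BB = np.asarray(ref_BB, dtype=float)
    if not (np.all(ref_AA < ref_AB) and np.all(ref_AB < ref_BB)):
        raise ValueError("cluster references must satisfy AA < AB < BB")
    lower = 0.5 * (theta - ref_AA) / (ref_AB - ref_AA)
    upper = 0.5 + 0.5 * (theta - ref_AB) / (ref_BB - ref_AB)
    freq = np.where(theta <= ref_AB, lower, upper)
    freq = np.clip(freq, 0.0, 1.0)
    if freq.ndim == 0:
        return float(freq)
    return freq


def frequency_to_theta(freq, ref_AA, ref_AB, ref_BB):
    """Exact inverse of :func:`theta_to_frequency` on [0, 1].

    Used by the synthetic pool generator so that noiseless replicates
    round-trip to the input frequency.
    """
    freq = np.asarray(freq, dtype=float)
    ref_AA = np.asarray(ref_AA, dtype=float)
    ref_AB = np.asarray(ref_AB, dtype=float)
    ref_BB = np.asarray(ref_BB, dtype=float)
    if (freq < 0).any() or (freq > 1).any():
        raise ValueError("frequencies must lie in [0, 1]")
    lower = ref_AA + 2.0 * freq * (ref_AB - ref_AA)
    upper = ref_AB + 2.0 * (freq - 0.5) * (ref_BB - ref_AB)
    theta = np.where(freq <= 0.5, lower, upper)
    if theta.ndim == 0:
        return float(theta)
    return theta


def _check_theta_frame(thetas: pd.DataFrame) -> None:
    if not isinstance(thetas.index, pd.MultiIndex) or thetas.index.nlevels != 2:
        raise ValueError(
            "replicate thetas must be indexed by (population, replicate)"
        )
    vals = thetas.to_numpy(dtype=float)
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("theta values must lie in [0, 1]")


def filter_replicate_quality(
    thetas: pd.DataFrame, max_sd: float = 0.02
) -> tuple[list[str], pd.DataFrame]:
    """Panel-wide replicate QC on pool thetas.

    Parameters
    ----------
    thetas
        DataFrame indexed by (population, replicate) with one column per
        locus.
    max_sd
        Maximum allowed sample standard deviation of theta across a
        population's technical replicates.

    Returns
    -------
    retained
        Loci whose replicate SD is within ``max_sd`` in *every* population.
    flags
        Population x locus boolean DataFrame of per-cell passes.
    """
    if max_sd <= 0:
        raise ValueError("max_sd must be positive")
    _check_theta_frame(thetas)
    counts = thetas.groupby(level=0).size()
    if (counts == 1).any():
        singles = counts.index[counts == 1].tolist()
        warnings.warn(
            f"populations with a single replicate (SD taken as 0): {singles}",
            stacklevel=2,
        )
    sd = thetas.groupby(level=0).std(ddof=1).fillna(0.0)
    flags = sd <= max_sd
    retained = [l for l in thetas.columns if bool(flags[l].all())]
    return retained, flags


def pool_frequencies(
    thetas: pd.DataFrame,
    ref: ClusterReference,
    n_individuals: pd.Series | dict | int = 50,
    loci: list[str] | None = None,
) -> AlleleFrequencyTable:
    """Estimate population allele frequencies from replicate pool thetas.

    Each replicate's theta is converted to a frequency first and the
    per-replicate frequencies are then averaged (conversion before
    averaging; the two orders differ only through the kink at the AB
    cluster and the choice is fixed here for reproducibility).
    """
    _check_theta_frame(thetas)
    if loci is not None:
        thetas = thetas.loc[:, list(loci)]
    refs = ref.aligned(thetas.columns)
    freqs = theta_to_frequency(
        thetas.to_numpy(dtype=float),
        refs["theta_AA"].to_numpy(),
        refs["theta_AB"].to_numpy(),
        refs["theta_BB"].to_numpy(),
    )
    per_rep = pd.DataFrame(freqs, index=thetas.index, columns=thetas.columns)
    mean = per_rep.groupby(level=0).mean()
    populations = list(mean.index)
    if isinstance(n_individuals, int):
        sizes = pd.Series(float(n_individuals), index=populations)
    else:
        sizes = pd.Series(n_individuals, dtype=float).reindex(populations)
    return AlleleFrequencyTable(mean.T, sizes)
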