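"""Synthetic study-system generator.

Emulates the statistical structure of a pooled-DNA SNP-array survey of
hierarchically differentiated populations: a panel of biallelic loci on a
linkage map, per-population allele frequencies drawn under the
Balding-Nichols F-model (with a minority of loci carrying elevated,
"outlier" differentiation), per-locus genotype-cluster theta references,
technical pool replicates with additive theta noise, and multiallelic
STR-like loci for independent-allele comparisons.

Scale defaults follow the kind of survey the pipeline targets: tens of
populations, thousands of loci, pools of ~50 diploids with 3-6 technical
replicates, per-population expected heterozygosity around 0.25-0.35 and
pairwise F_ST of a few percent between close populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allelotyping import ClusterReference, frequency_to_theta
from .tables import AlleleFrequencyTable, MultiallelicTable

__all__ = [
    "SyntheticTruth",
    "make_truth",
    "generate_panel",
    "generate_population_frequencies",
    "generate_cluster_reference",
    "generate_pool_replicates",
    "generate_multiallelic_loci",
]


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic frequency table.

    ``pop_fst`` holds one divergence parameter per population (the F of the
    Balding-Nichols Beta); loci flagged in ``outlier_flag`` use
    F * ``outlier_multiplier`` instead, mimicking divergent selection.
    """

    ancestral_freq: np.ndarray
    pop_fst: np.ndarray
    outlier_flag: np.ndarray
    outlier_multiplier: float
    seed: int

    def __post_init__(self) -> None:
        self.ancestral_freq = np.asarray(self.ancestral_freq, dtype=float)
        self.pop_fst = np.asarray(self.pop_fst, dtype=float)
        self.outlier_flag = np.asarray(self.outlier_flag, dtype=bool)
        if ((self.ancestral_freq <= 0) | (self.ancestral_freq >= 1)).any():
            raise ValueError("ancestral frequencies must lie strictly in (0, 1)")
        if ((self.pop_fst <= 0) | (self.pop_fst > 0.5)).any():
            raise ValueError("pop_fst must lie in (0, 0.5]")
        if self.outlier_multiplier <= 1:
            raise ValueError("outlier_multiplier must exceed 1")
        if self.outlier_flag.shape != self.ancestral_freq.shape:
            raise ValueError("outlier_flag must match ancestral_freq in length")


def make_truth(
    n_loci: int,
    n_pops: int,
    pop_fst: float | np.ndarray = 0.05,
    outlier_fraction: float = 0.05,
    outlier_multiplier: float = 8.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Draw ancestral frequencies and plant outlier flags.

    Ancestral B-allele frequencies are uniform on (0.05, 0.95) — a
    polymorphism-ascertained array panel — and exactly
    ``round(outlier_fraction * n_loci)`` loci are flagged as outliers.
    """
    if n_loci < 1 or n_pops < 1:
        raise ValueError("n_loci and n_pops must be positive")
    rng = np.random.default_rng(seed)
    anc = rng.uniform(0.05, 0.95, size=n_loci)
    n_out = int(round(outlier_fraction * n_loci))
    flags = np.zeros(n_loci, dtype=bool)
    if n_out:
        flags[rng.choice(n_loci, size=n_out, replace=False)] = True
    fst = np.broadcast_to(np.asarray(pop_fst, dtype=float), (n_pops,)).copy()
    return SyntheticTruth(anc, fst, flags, float(outlier_multiplier), int(seed))


def _locus_ids(n_loci: int) -> list[str]:
    width = max(4, len(str(n_loci)))
    return [f"L{i:0{width}d}" for i in range(1, n_loci + 1)]


def generate_panel(
    n_loci: int, n_chromosomes: int, chrom_length_cM: float, seed: int
) -> pd.DataFrame:
    """Place loci uniformly at random on a linkage map.

    Returns a DataFrame (locus_id, chromosome, position_cM) sorted by
    chromosome then position.
    """
    if n_loci < 1 or n_chromosomes < 1:
        raise ValueError("n_loci and n_chromosomes must be positive")
    if chrom_length_cM <= 0:
        raise ValueError("chrom_length_cM must be positive")
    rng = np.random.default_rng(seed)
    cwidth = len(str(n_chromosomes))
    chroms = rng.integers(1, n_chromosomes + 1, size=n_loci)
    pos = rng.uniform(0.0, chrom_length_cM, size=n_loci)
    df = pd.DataFrame(
        {
            "locus_id": _locus_ids(n_loci),
            "chromosome": [f"chr{c:0{cwidth}d}" for c in chroms],
            "position_cM": pos,
        }
    )
    return df.sort_values(["chromosome", "position_cM"], kind="mergesort").reset_index(
        drop=True
    )


def generate_population_frequencies(
    truth: SyntheticTruth,
    n_pops: int | None = None,
    n_loci: int | None = None,
    n_individuals: int = 50,
    pop_names: list[str] | None = None,
) -> tuple[AlleleFrequencyTable, pd.Series]:
    """Draw per-population frequencies under the Balding-Nichols model.

    Population j's frequency at locus l is Beta with mean the ancestral
    frequency and variance p(1-p)F, F = pop_fst[j] (times the outlier
    multiplier at flagged loci).  Draws at the Beta boundary (monomorphic
    populations) are retained.

    Returns the frequency table and a per-locus boolean Series of outlier
    flags.
    """
    if n_pops is None:
        n_pops = len(truth.pop_fst)
    if n_loci is None:
        n_loci = len(truth.ancestral_freq)
    if n_pops != len(truth.pop_fst) or n_loci != len(truth.ancestral_freq):
        raise ValueError("n_pops/n_loci inconsistent with truth")
    F = np.broadcast_to(truth.pop_fst, (n_loci, n_pops)).copy()
    F[truth.outlier_flag, :] *= truth.outlier_multiplier
    if (F >= 1).any():
        raise ValueError("effective F >= 1 after outlier multiplication")
    rng = np.random.default_rng(truth.seed)
    p = truth.ancestral_freq[:, None]
    scale = (1.0 - F) / F
    freq = rng.beta(p * scale, (1.0 - p) * scale)
    loci = _locus_ids(n_loci)
    if pop_names is None:
        pop_names = [f"pop{j:02d}" for j in range(1, n_pops + 1)]
    table = AlleleFrequencyTable(
        pd.DataFrame(freq, index=loci, columns=pop_names),
        pd.Series(float(n_individuals), index=pop_names),
    )
    flags = pd.Series(truth.outlier_flag, index=loci, name="outlier")
    return table, flags


def generate_cluster_reference(
    n_loci: int,
    center_AA: float = 0.05,
    center_AB: float = 0.5,
    center_BB: float = 0.95,
    jitter_sd: float = 0.02,
    seed: int = 0,
    max_retries: int = 100,
) -> ClusterReference:
    """Per-locus genotype-cluster theta means with Gaussian jitter.

    Jittered values are clipped to [0, 1]; loci whose clipped values lose
    the strict AA < AB < BB ordering are redrawn (bounded retries).
    """
    if not (0 <= center_AA < center_AB < center_BB <= 1):
        raise ValueError("cluster centers must satisfy 0 <= AA < AB < BB <= 1")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    rng = np.random.default_rng(seed)
    centers = np.array([center_AA, center_AB, center_BB])
    out = np.tile(centers, (n_loci, 1))
    if jitter_sd > 0:
        out = np.clip(out + rng.normal(0.0, jitter_sd, size=(n_loci, 3)), 0.0, 1.0)
        bad = ~((out[:, 0] < out[:, 1]) & (out[:, 1] < out[:, 2]))
        tries = 0
        while bad.any():
            tries += 1
            if tries > max_retries:
                raise RuntimeError(
                    "could not generate strictly ordered cluster thetas"
                )
            redraw = np.clip(
                centers + rng.normal(0.0, jitter_sd, size=(int(bad.sum()), 3)),
                0.0,
                1.0,
            )
            out[bad] = redraw
            bad = ~((out[:, 0] < out[:, 1]) & (out[:, 1] < out[:, 2]))
    table = pd.DataFrame(
        out, index=_locus_ids(n_loci), columns=["theta_AA", "theta_AB", "theta_BB"]
    )
    return ClusterReference(table)


def generate_pool_replicates(
    freqs: AlleleFrequencyTable,
    ref: ClusterReference,
    n_replicates: int = 4,
    theta_noise_sd: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate technical pool replicates as noisy thetas.

    The noiseless theta is the exact inverse of the piecewise-linear
    cluster correction, so at zero noise the allelotyping round trip is the
    identity; replicate noise is additive Gaussian truncated to [0, 1].

    Returns a DataFrame indexed by (population, replicate) with one column
    per locus, matching :func:`poolgsi.allelotyping.pool_frequencies`.
    """
    if not 1 <= n_replicates <= 10:
        raise ValueError("n_replicates must be in [1, 10]")
    if theta_noise_sd < 0:
        raise ValueError("theta_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    loci = freqs.loci
    refs = ref.aligned(loci)
    base = frequency_to_theta(
        freqs.freq.to_numpy().T,  # pops x loci
        refs["theta_AA"].to_numpy(),
        refs["theta_AB"].to_numpy(),
        refs["theta_BB"].to_numpy(),
    )
    reps = np.repeat(base[:, None, :], n_replicates, axis=1)
    if theta_noise_sd > 0:
        reps = reps + rng.normal(0.0, theta_noise_sd, size=reps.shape)
    reps = np.clip(reps, 0.0, 1.0)
    index = pd.MultiIndex.from_product(
        [freqs.populations, range(1, n_replicates + 1)],
        names=["population", "replicate"],
    )
    return pd.DataFrame(
        reps.reshape(len(freqs.populations) * n_replicates, len(loci)),
        index=index,
        columns=loci,
    )


def generate_multiallelic_loci(
    n_pops: int,
    alleles_per_locus: list[int],
    fst: float,
    seed: int = 0,
    pop_names: list[str] | None = None,
) -> MultiallelicTable:
    """STR-like multiallelic frequencies under a Dirichlet F-model.

    Each locus gets a random ancestral simplex point; population vectors
    are Dirichlet with concentration ancestral * (1-F)/F — the multiallelic
    analogue of the Balding-Nichols Beta.
    """
    if not 0 < fst < 1:
        raise ValueError("fst must lie in (0, 1)")
    if any(k < 2 for k in alleles_per_locus):
        raise ValueError("every locus needs at least 2 alleles")
    rng = np.random.default_rng(seed)
    if pop_names is None:
        pop_names = [f"pop{j:02d}" for j in range(1, n_pops + 1)]
    scale = (1.0 - fst) / fst
    freqs = {}
    for i, k in enumerate(alleles_per_locus, start=1):
        anc = rng.dirichlet(np.ones(k))
        # keep ancestral proportions away from 0 so concentrations stay valid
        anc = (anc + 0.01) / (1.0 + 0.01 * k)
        freqs[f"STR{i:03d}"] = rng.dirichlet(anc * scale, size=n_pops)
    return MultiallelicTable(pop_names, freqs)
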