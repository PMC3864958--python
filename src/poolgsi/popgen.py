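"""Frequency-based population-genetic summaries.

Expected heterozygosity, Weir-Cockerham F_ST (global and pairwise), the
allele-frequency differential Delta, Nei's D_A distance, and
neighbor-joining trees with bootstrap support.  All statistics operate on
population allele-frequency tables (pooled-DNA estimates or frequencies
derived from genotypes); no individual-level F-statistics are computed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd

from .tables import AlleleFrequencyTable, MultiallelicTable

__all__ = [
    "expected_heterozygosity",
    "weir_cockerham_components",
    "fst_global",
    "fst_pairwise",
    "delta",
    "nei_da",
    "nj_tree",
    "bootstrap_consensus",
    "split_support",
    "FstResult",
    "PairwiseFstResult",
]


def expected_heterozygosity(
    freqs: AlleleFrequencyTable,
) -> tuple[pd.DataFrame, pd.Series, float]:
    """Biallelic expected heterozygosity He = 2p(1-p).

    Returns (per-locus-per-population He, per-population mean over loci,
    across-locus median of the locus means).
    """
    p = freqs.freq
    he = 2.0 * p * (1.0 - p)
    per_pop = he.mean(axis=0)
    median = float(he.mean(axis=1).median())
    return he, per_pop, median


def weir_cockerham_components(
    p: np.ndarray, n_diploid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) variance components from allele frequencies.

    Parameters
    ----------
    p
        Loci x populations matrix of B-allele frequencies.
    n_diploid
        Diploid sample size per population.  Heterozygote frequencies are
        taken at Hardy-Weinberg expectation (pool data carry no genotype
        information).

    Returns
    -------
    a, total
        Per-locus among-population component ``a`` and total ``a+b+c``.
        F_ST is ``a / (a+b+c)``; loci monomorphic in every population have
        total 0 and an undefined ratio.
    """
    p = np.asarray(p, dtype=float)
    n = np.asarray(n_diploid, dtype=float)
    r = p.shape[1]
    if r < 2:
        raise ValueError("need at least two populations")
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum(axis=1) / (r * nbar)
    s2 = (n * (p - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * nbar)
    hbar = (n * 2.0 * p * (1.0 - p)).sum(axis=1) / (r * nbar)
    pq = pbar * (1.0 - pbar)
    a = (nbar / nc) * (s2 - (pq - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (
        pq - (r - 1) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, a + b + c


@dataclass
class FstResult:
    """Per-locus F_ST with summaries; undefined loci carry NaN."""

    per_locus: pd.Series
    mean: float
    median: float
    ratio_of_sums: float


def fst_global(freqs: AlleleFrequencyTable) -> FstResult:
    """Weir-Cockerham F_ST over all populations.

    ``mean``/``median`` summarise the per-locus estimates (negative values
    retained); ``ratio_of_sums`` is the multilocus estimator
    sum(a)/sum(a+b+c).  Loci monomorphic in all populations are NaN and
    excluded from summaries.
    """
    a, tot = weir_cockerham_components(
        freqs.freq.to_numpy(), freqs.n_individuals.to_numpy()
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(tot != 0.0, a / np.where(tot == 0.0, 1.0, tot), np.nan)
    per_locus = pd.Series(theta, index=freqs.freq.index, name="fst_global")
    defined = per_locus.dropna()
    ros = float(a[tot != 0].sum() / tot[tot != 0].sum()) if len(defined) else float("nan")
    return FstResult(per_locus, float(defined.mean()), float(defined.median()), ros)


@dataclass
class PairwiseFstResult:
    """Pairwise Weir-Cockerham F_ST.

    ``per_locus_pair`` has one column per unordered population pair,
    ``per_locus_mean`` averages defined pairs per locus, ``matrix`` holds
    the per-pair mean over loci (symmetric DataFrame).
    """

    per_locus_pair: pd.DataFrame
    per_locus_mean: pd.Series
    matrix: pd.DataFrame


def fst_pairwise(freqs: AlleleFrequencyTable) -> PairwiseFstResult:
    pops = freqs.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    p = freqs.freq.to_numpy()
    n = freqs.n_individuals.to_numpy()
    cols = {}
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, j in combinations(range(len(pops)), 2):
        a, tot = weir_cockerham_components(p[:, [i, j]], n[[i, j]])
        with np.errstate(divide="ignore", invalid="ignore"):
            theta = np.where(tot != 0.0, a / np.where(tot == 0.0, 1.0, tot), np.nan)
        cols[(pops[i], pops[j])] = theta
        pair_mean = float(np.nanmean(theta)) if np.isfinite(theta).any() else np.nan
        mat.iloc[i, j] = mat.iloc[j, i] = pair_mean
    per_pair = pd.DataFrame(cols, index=freqs.freq.index)
    per_pair.columns = pd.MultiIndex.from_tuples(per_pair.columns)
    per_locus_mean = per_pair.mean(axis=1)
    per_locus_mean.name = "fst_pairwise_mean"
    return PairwiseFstResult(per_pair, per_locus_mean, mat)


def delta(freqs: AlleleFrequencyTable) -> pd.Series:
    """Per-locus mean absolute frequency difference over population pairs."""
    p = freqs.freq.to_numpy()
    r = p.shape[1]
    if r < 2:
        raise ValueError("need at least two populations")
    total = np.zeros(p.shape[0])
    npairs = 0
    for i, j in combinations(range(r), 2):
        total += np.abs(p[:, i] - p[:, j])
        npairs += 1
    return pd.Series(total / npairs, index=freqs.freq.index, name="delta")


def nei_da(freqs: AlleleFrequencyTable | MultiallelicTable) -> pd.DataFrame:
    """Nei's D_A genetic distance.

    D_A(i,j) = 1 - (1/L) sum_l sum_alleles sqrt(p_il * p_jl); for biallelic
    loci both alleles enter the sum.  Returns a symmetric DataFrame with a
    zero diagonal.
    """
    if isinstance(freqs, AlleleFrequencyTable):
        pops = freqs.populations
        p = freqs.freq.to_numpy().T  # pops x loci
        stacked = [np.sqrt(p), np.sqrt(1.0 - p)]  # allele B, allele A
        n_loci = p.shape[1]
        sqrt_freqs = np.concatenate(stacked, axis=1)  # pops x (2*loci)
    else:
        pops = freqs.populations
        arrs = [np.sqrt(np.asarray(freqs.freqs[l], dtype=float)) for l in freqs.loci]
        n_loci = len(arrs)
        sqrt_freqs = np.concatenate(arrs, axis=1)
    share = sqrt_freqs @ sqrt_freqs.T / n_loci
    d = 1.0 - share
    np.fill_diagonal(d, 0.0)
    d = np.clip(0.5 * (d + d.T), 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=pops, columns=pops)


def _distance_to_pdm(d: pd.DataFrame) -> dendropy.PhylogeneticDistanceMatrix:
    if not np.allclose(d.to_numpy(), d.to_numpy().T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    buf = io.StringIO()
    buf.write("." + "".join(f",{t}" for t in d.columns) + "\n")
    for t in d.index:
        buf.write(t + "".join(f",{v:.17g}" for v in d.loc[t]) + "\n")
    buf.seek(0)
    return dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")


def nj_tree(d: pd.DataFrame) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; negative branch lengths truncated to 0."""
    if d.shape[0] < 3:
        raise ValueError("need at least three populations")
    tree = _distance_to_pdm(d).nj_tree()
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree


def bootstrap_consensus(
    freqs: AlleleFrequencyTable,
    B: int = 1000,
    seed: int = 0,
    min_freq: float = 0.5,
) -> tuple[dendropy.Tree, dendropy.TreeList]:
    """Majority-rule consensus of NJ trees over locus bootstrap replicates.

    Loci are resampled with replacement; D_A and NJ are recomputed per
    replicate.  The consensus tree's nodes carry percent support in
    ``node.support`` (equivalently ``node.label``).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace(freqs.populations)
    trees = dendropy.TreeList(taxon_namespace=tns)
    n_loci = freqs.n_loci
    for _ in range(B):
        take = rng.integers(0, n_loci, size=n_loci)
        boot = AlleleFrequencyTable(
            freqs.freq.iloc[take].reset_index(drop=True).rename(lambda i: f"b{i}"),
            freqs.n_individuals,
        )
        t = nj_tree(nei_da(boot))
        trees.append(
            dendropy.Tree.get(
                data=t.as_string(schema="newick"),
                schema="newick",
                taxon_namespace=tns,
            )
        )
    cons = trees.consensus(min_freq=min_freq, support_as_percentages=True)
    for nd in cons:
        if nd.support is not None:
            nd.label = f"{nd.support:g}"
    return cons, trees


def split_support(tree: dendropy.Tree, taxa: set[str]) -> float | None:
    """Percent support of the split separating ``taxa`` from the rest.

    Returns None when the consensus tree does not contain that split.
    """
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    target = frozenset(taxa)
    complement = frozenset(leaves - taxa)
    for nd in tree.preorder_internal_node_iter():
        side = frozenset(l.taxon.label for l in nd.leaf_iter())
        if side in (target, complement):
            return float(nd.support) if nd.support is not None else 100.0
    return None
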