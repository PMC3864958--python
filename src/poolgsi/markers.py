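"""Marker-informativeness ranking, outlier scanning and panel construction.

Loci are ranked by one of four divergence scores (global F_ST, mean pairwise
F_ST, Delta, or the posterior odds of a Bayesian F_ST-outlier scan), the
upper quartile is classified as highly differentiated, linked loci are
pruned greedily on a centimorgan map, and nested top-K subsets (plus random
controls) are cut for downstream assignment experiments.

The outlier scan re-implements the standard F-model genome scan: B-allele
counts are beta-binomial given a locus ancestral frequency and a
locus-by-population F_ST whose logit decomposes into a locus effect alpha
(present only under "selection") and a population effect beta.  A
reversible-jump MCMC switches each alpha in and out of the model; posterior
odds and Bayesian q-values follow from the posterior inclusion
probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .tables import AlleleFrequencyTable

__all__ = [
    "RankingResult",
    "MarkerSubset",
    "McmcSettings",
    "OutlierResult",
    "rank_loci",
    "classify_upper_quartile",
    "prune_linked",
    "make_subsets",
    "counts_from_frequencies",
    "scan_outliers",
    "log10_posterior_odds",
    "top_overlap",
]

RANKING_METHODS = ("global_fst", "pairwise_fst", "delta", "outlier", "random")


@dataclass
class RankingResult:
    """Ordered loci (best first) with their scores and provenance."""

    method: str
    loci: list[str]
    scores: pd.Series
    populations: list[str] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.loci) != len(set(self.loci)):
            raise ValueError("ranking contains duplicate loci")

    def top(self, k: int) -> list[str]:
        if k > len(self.loci):
            raise ValueError(f"requested top {k} of {len(self.loci)} loci")
        return self.loci[:k]


@dataclass
class MarkerSubset:
    size: int
    loci: list[str]
    method: str
    seed: int | None = None


def rank_loci(
    method: str,
    divergence: pd.DataFrame | pd.Series,
    populations: list[str] | None = None,
    seed: int | None = None,
) -> RankingResult:
    """Sort loci by a divergence score, best first.

    ``divergence`` is either a Series of scores or a DataFrame with a
    column named after the method (``outlier`` uses ``log10_PO``).  Ties
    break lexicographically on locus id; undefined (NaN) scores sink to
    the bottom.  ``method='random'`` shuffles loci with ``seed``.
    """
    if method not in RANKING_METHODS:
        raise ValueError(f"unknown ranking method {method!r}")
    if isinstance(divergence, pd.Series):
        scores = divergence
    else:
        column = {"outlier": "log10_PO"}.get(method, method)
        if method == "random":
            scores = pd.Series(0.0, index=divergence.index)
        elif column not in divergence.columns:
            raise ValueError(f"divergence table lacks column {column!r}")
        else:
            scores = divergence[column]
    scores = scores.astype(float)
    if method == "random":
        if seed is None:
            raise ValueError("random ranking requires a seed")
        rng = np.random.default_rng(seed)
        order = list(scores.index[rng.permutation(len(scores))])
        return RankingResult(method, order, scores.loc[order], populations or [], seed)
    frame = pd.DataFrame({"score": scores, "locus": scores.index})
    frame["defined"] = np.isfinite(frame["score"])
    frame = frame.sort_values(
        ["defined", "score", "locus"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    order = list(frame["locus"])
    return RankingResult(method, order, scores.loc[order], populations or [], seed)


def classify_upper_quartile(scores: pd.Series) -> pd.Series:
    """Flag loci at or above the 75th percentile (linear interpolation)."""
    values = scores.dropna()
    if len(values) < 4:
        raise ValueError("need at least 4 defined scores")
    q75 = float(np.percentile(values.to_numpy(), 75))
    return scores >= q75


def prune_linked(
    ranking: RankingResult, panel_map: pd.DataFrame, min_cM: float = 1.0
) -> RankingResult:
    """Greedy linkage pruning: best-first, keep a locus only if it is more
    than ``min_cM`` from every kept locus on the same chromosome.

    Loci absent from the map are treated as unlinked and always kept.
    """
    pos = panel_map.set_index("locus_id")[["chromosome", "position_cM"]]
    kept: list[str] = []
    kept_by_chrom: dict[str, list[float]] = {}
    for locus in ranking.loci:
        if locus not in pos.index:
            kept.append(locus)
            continue
        chrom = pos.at[locus, "chromosome"]
        x = float(pos.at[locus, "position_cM"])
        taken = kept_by_chrom.get(chrom, [])
        if all(abs(x - y) > min_cM for y in taken):
            kept.append(locus)
            kept_by_chrom.setdefault(chrom, []).append(x)
    return RankingResult(
        ranking.method, kept, ranking.scores.loc[kept], ranking.populations,
        ranking.seed,
    )


def make_subsets(
    ranking: RankingResult,
    sizes: list[int],
    random: bool = False,
    seed: int | None = None,
) -> list[MarkerSubset]:
    """Nested top-K prefixes of a ranking, or random draws of each size."""
    out = []
    for k in sizes:
        if k < 1:
            raise ValueError("subset sizes must be positive")
        if k > len(ranking.loci):
            raise ValueError(f"subset size {k} exceeds {len(ranking.loci)} loci")
        if random:
            if seed is None:
                raise ValueError("random subsets require a seed")
            rng = np.random.default_rng((seed, k))
            loci = list(
                np.asarray(ranking.loci)[rng.choice(len(ranking.loci), k, replace=False)]
            )
            out.append(MarkerSubset(k, loci, "random", seed))
        else:
            out.append(MarkerSubset(k, ranking.top(k), ranking.method, ranking.seed))
    return out


def top_overlap(a: RankingResult, b: RankingResult, k: int = 100) -> int:
    """Number of shared loci among the two rankings' top k."""
    return len(set(a.top(k)) & set(b.top(k)))


def counts_from_frequencies(freqs: AlleleFrequencyTable) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-counts for the outlier scan from pool frequencies.

    B-allele counts are round(2 n p) of 2n gene copies per population — an
    approximation standing in for the genotype counts the likelihood
    expects, using the nominal pool sizes.
    """
    n_copies = (2 * freqs.n_individuals.to_numpy()).astype(int)
    n = np.broadcast_to(n_copies, freqs.freq.shape)
    counts = np.rint(freqs.freq.to_numpy() * n).astype(int)
    return counts, n.copy()


@dataclass
class McmcSettings:
    """Reversible-jump MCMC schedule for the outlier scan.

    ``iterations`` counts retained samples; total sweeps are
    ``burn_in + iterations * thinning``.  ``rj_pilot`` sweeps adapt the
    random-walk proposal scales during burn-in.
    """

    burn_in: int = 2000
    iterations: int = 1200
    thinning: int = 3
    rj_pilot: int = 10
    prop_sd_pbar: float = 0.35
    prop_sd_alpha: float = 0.7
    prop_sd_beta: float = 0.25


@dataclass
class OutlierResult:
    """Per-locus posterior summaries of the outlier scan."""

    table: pd.DataFrame  # columns: log10_PO, q_value, alpha, post_incl, selected
    prior_odds: float
    acceptance: dict[str, float] = field(default_factory=dict)


def log10_posterior_odds(post_incl: np.ndarray, n_samples: int) -> np.ndarray:
    """log10 of posterior odds of the selection model, capped away from
    infinity at the Monte-Carlo resolution (half a sample)."""
    lo = 0.5 / n_samples
    p = np.clip(post_incl, lo, 1.0 - lo)
    return np.log10(p / (1.0 - p))


def _loglik_matrix(a, n, pbar, alpha, beta):
    """Beta-binomial log likelihood (constants dropped), loci x pops."""
    theta = np.exp(-(alpha[:, None] + beta[None, :]))
    m1 = theta * pbar[:, None]
    m2 = theta - m1
    return (
        gammaln(a + m1)
        - gammaln(m1)
        + gammaln(n - a + m2)
        - gammaln(m2)
        - gammaln(n + theta)
        + gammaln(theta)
    )


def scan_outliers(
    counts: np.ndarray,
    n_copies: np.ndarray,
    loci: list[str] | None = None,
    prior_odds: float = 10.0,
    mcmc: McmcSettings | None = None,
    seed: int = 0,
    po_threshold: float = 1.0,
    q_threshold: float = 0.05,
) -> OutlierResult:
    """F-model genome scan for loci under divergent selection.

    Parameters
    ----------
    counts, n_copies
        Loci x populations integer matrices of B-allele counts and total
        gene copies.
    prior_odds
        Prior odds in favour of the neutral model (prior inclusion
        probability 1/(1+prior_odds)).
    seed
        Seeds the sampler; identical seeds reproduce results exactly.

    Returns per-locus log10 posterior odds, Bayesian q-values, posterior
    mean locus effect alpha, and the ``selected`` flag
    (log10_PO > ``po_threshold`` and q < ``q_threshold``).
    """
    counts = np.asarray(counts)
    n_copies = np.asarray(n_copies)
    if counts.shape != n_copies.shape:
        raise ValueError("counts and n_copies must have the same shape")
    if not np.issubdtype(counts.dtype, np.integer) or (counts < 0).any():
        raise ValueError("counts must be non-negative integers")
    if (counts > n_copies).any():
        raise ValueError("counts exceed gene copies")
    if mcmc is None:
        mcmc = McmcSettings()
    L, J = counts.shape
    if loci is None:
        loci = [f"L{i:04d}" for i in range(1, L + 1)]
    rng = np.random.default_rng(seed)
    a = counts.astype(float)
    n = n_copies.astype(float)

    # initial state: moment estimates
    pbar = np.clip((a.sum(axis=1) + 0.5) / (n.sum(axis=1) + 1.0), 1e-4, 1 - 1e-4)
    alpha = np.zeros(L)
    included = np.zeros(L, dtype=bool)
    beta = np.full(J, -1.0)
    ll = _loglik_matrix(a, n, pbar, alpha, beta)
    rowll = ll.sum(axis=1)

    log_prior_incl = -math.log1p(prior_odds)          # log P(selection model)
    log_prior_excl = math.log(prior_odds) - math.log1p(prior_odds)
    sd_p, sd_a, sd_b = mcmc.prop_sd_pbar, mcmc.prop_sd_alpha, mcmc.prop_sd_beta
    acc = {"pbar": 0, "alpha": 0, "beta": 0, "rj": 0}
    tries = {"pbar": 0, "alpha": 1, "beta": 0, "rj": 0}

    total_sweeps = mcmc.burn_in + mcmc.iterations * mcmc.thinning
    incl_sum = np.zeros(L)
    alpha_sum = np.zeros(L)
    n_kept = 0
    adapt_every = max(1, mcmc.burn_in // max(mcmc.rj_pilot, 1)) if mcmc.rj_pilot else 0
    window = {"pbar": [0, 0], "alpha": [0, 0], "beta": [0, 0]}

    for sweep in range(total_sweeps):
        # --- ancestral frequency update (logit random walk, uniform prior)
        z = logit(pbar) + rng.normal(0.0, sd_p, size=L)
        pbar_new = np.clip(expit(z), 1e-9, 1 - 1e-9)
        ll_new = _loglik_matrix(a, n, pbar_new, alpha, beta)
        rownew = ll_new.sum(axis=1)
        # Jacobian of the logit transform under a uniform prior on pbar
        log_acc = (
            rownew
            - rowll
            + np.log(pbar_new * (1 - pbar_new))
            - np.log(pbar * (1 - pbar))
        )
        take = np.log(rng.random(L)) < log_acc
        pbar = np.where(take, pbar_new, pbar)
        ll[take] = ll_new[take]
        rowll = np.where(take, rownew, rowll)
        window["pbar"][0] += int(take.sum())
        window["pbar"][1] += L

        # --- alpha random walk for included loci, prior N(0,1)
        if included.any():
            idx = np.flatnonzero(included)
            alpha_new = alpha.copy()
            alpha_new[idx] = alpha[idx] + rng.normal(0.0, sd_a, size=len(idx))
            ll_new = _loglik_matrix(
                a[idx], n[idx], pbar[idx], alpha_new[idx], beta
            )
            rownew = ll_new.sum(axis=1)
            log_acc = (
                rownew
                - rowll[idx]
                + 0.5 * (alpha[idx] ** 2 - alpha_new[idx] ** 2)
            )
            take = np.log(rng.random(len(idx))) < log_acc
            hit = idx[take]
            alpha[hit] = alpha_new[hit]
            ll[hit] = ll_new[take]
            rowll[hit] = rownew[take]
            window["alpha"][0] += int(take.sum())
            window["alpha"][1] += len(idx)

        # --- reversible jump: toggle alpha in/out using the prior N(0,1)
        # as independence proposal (prior and proposal densities cancel)
        prop_alpha = rng.normal(0.0, 1.0, size=L)
        alpha_new = np.where(included, 0.0, prop_alpha)
        ll_new = _loglik_matrix(a, n, pbar, alpha_new, beta)
        rownew = ll_new.sum(axis=1)
        log_prior_move = np.where(
            included,
            log_prior_excl - log_prior_incl,   # death
            log_prior_incl - log_prior_excl,   # birth
        )
        log_acc = rownew - rowll + log_prior_move
        take = np.log(rng.random(L)) < log_acc
        alpha = np.where(take, alpha_new, alpha)
        included = np.where(take, ~included, included)
        ll[take] = ll_new[take]
        rowll = np.where(take, rownew, rowll)
        acc["rj"] += int(take.sum())
        tries["rj"] += L

        # --- beta updates, one population at a time, prior N(-1,1)
        for j in range(J):
            bj = beta[j] + rng.normal(0.0, sd_b)
            theta = np.exp(-(alpha + bj))
            m1 = theta * pbar
            m2 = theta - m1
            col = (
                gammaln(a[:, j] + m1)
                - gammaln(m1)
                + gammaln(n[:, j] - a[:, j] + m2)
                - gammaln(m2)
                - gammaln(n[:, j] + theta)
                + gammaln(theta)
            )
            log_acc = (
                col.sum()
                - ll[:, j].sum()
                + 0.5 * ((beta[j] + 1.0) ** 2 - (bj + 1.0) ** 2)
            )
            if math.log(rng.random()) < log_acc:
                rowll = rowll - ll[:, j] + col
                ll[:, j] = col
                beta[j] = bj
                window["beta"][0] += 1
            window["beta"][1] += 1

        # --- proposal adaptation during burn-in
        if adapt_every and sweep < mcmc.burn_in and (sweep + 1) % adapt_every == 0:
            for key, sd_name in (("pbar", "sd_p"), ("alpha", "sd_a"), ("beta", "sd_b")):
                got, tried = window[key]
                if tried == 0:
                    continue
                rate = got / tried
                factor = 1.3 if rate > 0.45 else (1 / 1.3 if rate < 0.15 else 1.0)
                if key == "pbar":
                    sd_p *= factor
                elif key == "alpha":
                    sd_a *= factor
                else:
                    sd_b *= factor
                window[key] = [0, 0]

        if sweep >= mcmc.burn_in and (sweep - mcmc.burn_in) % mcmc.thinning == 0:
            incl_sum += included
            alpha_sum += np.where(included, alpha, 0.0)
            n_kept += 1

    post_incl = incl_sum / n_kept
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_mean = np.where(incl_sum > 0, alpha_sum / np.maximum(incl_sum, 1), 0.0)
    lpo = log10_posterior_odds(post_incl, n_kept)

    # Bayesian q-value: mean posterior exclusion probability among loci at
    # least as extreme (sorted by decreasing posterior odds)
    order = np.argsort(-lpo, kind="mergesort")
    excl_sorted = 1.0 - post_incl[order]
    q_sorted = np.cumsum(excl_sorted) / np.arange(1, L + 1)
    # loci tied on posterior odds share the q of the last tied member
    lpo_sorted = lpo[order]
    for end in range(L - 2, -1, -1):
        if lpo_sorted[end] == lpo_sorted[end + 1]:
            q_sorted[end] = q_sorted[end + 1]
    q = np.empty(L)
    q[order] = q_sorted
    selected = (lpo > po_threshold) & (q < q_threshold)

    table = pd.DataFrame(
        {
            "log10_PO": lpo,
            "q_value": q,
            "alpha": alpha_mean,
            "post_incl": post_incl,
            "selected": selected,
        },
        index=pd.Index(loci, name="locus_id"),
    )
    rates = {k: acc[k] / max(tries[k], 1) for k in acc}
    rates["n_samples"] = n_kept
    return OutlierResult(table, prior_odds, rates)
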