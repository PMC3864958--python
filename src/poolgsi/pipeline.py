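"""End-to-end pipeline: synthesis/loading -> allelotyping -> summaries ->
rankings -> assignment curves -> marker-requirement fits.

The configuration names population datasets (ascertainment subsets used for
ranking), the QC threshold, the subset-size grid, MCMC settings and
simulation sizes; every stochastic artifact records the seed it was
produced with.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import allelotyping, gsi, io, markers, popgen, synthetic

log = logging.getLogger("poolgsi")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Pipeline settings; defaults give a minutes-scale synthetic run."""

    n_pops: int = 20
    n_loci: int = 1000
    n_chromosomes: int = 20
    chrom_length_cM: float = 120.0
    pop_fst: float = 0.05
    outlier_fraction: float = 0.05
    outlier_multiplier: float = 8.0
    n_individuals: int = 50
    n_replicates: int = 4
    theta_noise_sd: float = 0.01
    qc_max_sd: float = 0.02
    min_cM: float = 1.0
    datasets: dict[str, list[str] | None] = field(default_factory=dict)
    methods: list[str] = field(
        default_factory=lambda: ["global_fst", "pairwise_fst", "delta", "random"]
    )
    run_outlier_scan: bool = False
    subset_sizes: list[int] = field(
        default_factory=lambda: [25, 50, 75, 100, 125, 150, 200, 250, 300]
    )
    n_baseline: int = 100
    n_mixture: int = 500
    targets: list[float] = field(default_factory=lambda: [80.0, 90.0, 95.0])
    mcmc: markers.McmcSettings = field(default_factory=markers.McmcSettings)
    seed: int = 0
    out_dir: str = "poolgsi_out"
    frequency_table: str | None = None  # load instead of synthesising

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        mcmc = raw.pop("mcmc", None)
        cfg = cls(**raw)
        if mcmc:
            cfg.mcmc = markers.McmcSettings(**mcmc)
        return cfg

    def validate_against(self, populations: list[str]) -> None:
        for name, pops in self.datasets.items():
            if pops is None:
                continue
            unknown = [p for p in pops if p not in populations]
            if unknown:
                raise ValueError(
                    f"dataset {name!r} references unknown populations: {unknown}"
                )


def _stage(name: str, t0: float, **shapes) -> float:
    t1 = time.perf_counter()
    info = " ".join(f"{k}={v}" for k, v in shapes.items())
    log.info("stage=%s elapsed=%.2fs %s", name, t1 - t0, info)
    return t1


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and write artifacts under ``out_dir``.

    Returns a report dict with the key in-memory results (frequency table,
    divergence table, rankings, accuracy curves, fits).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"seed": config.seed, "tool": "poolgsi"}
    t0 = time.perf_counter()
    report: dict = {}

    panel = synthetic.generate_panel(
        config.n_loci, config.n_chromosomes, config.chrom_length_cM, config.seed
    )
    io.write_panel_map(panel, out / "panel_map.tsv", prov)

    if config.frequency_table:
        freqs = io.read_frequency_table(config.frequency_table)
        truth_flags = None
    else:
        truth = synthetic.make_truth(
            config.n_loci,
            config.n_pops,
            pop_fst=config.pop_fst,
            outlier_fraction=config.outlier_fraction,
            outlier_multiplier=config.outlier_multiplier,
            seed=config.seed,
        )
        true_freqs, truth_flags = synthetic.generate_population_frequencies(
            truth, n_individuals=config.n_individuals
        )
        ref = synthetic.generate_cluster_reference(
            config.n_loci, seed=config.seed + 1
        )
        thetas = synthetic.generate_pool_replicates(
            true_freqs, ref, config.n_replicates, config.theta_noise_sd,
            seed=config.seed + 2,
        )
        io.write_replicate_thetas(thetas, out / "replicate_thetas.tsv", prov)
        t0 = _stage("synthesis", t0, loci=config.n_loci, pops=config.n_pops)

        retained, _ = allelotyping.filter_replicate_quality(
            thetas, config.qc_max_sd
        )
        freqs = allelotyping.pool_frequencies(
            thetas, ref, config.n_individuals, loci=retained
        )
        if truth_flags is not None:
            truth_flags.to_frame().to_csv(out / "truth_outliers.tsv", sep="\t")
        t0 = _stage("allelotyping", t0, retained=len(retained))

    config.validate_against(freqs.populations)
    io.write_frequency_table(freqs, out / "allele_frequencies.tsv", prov)
    report["frequencies"] = freqs

    he, he_per_pop, he_median = popgen.expected_heterozygosity(freqs)
    he_per_pop.rename("He").to_csv(out / "heterozygosity.tsv", sep="\t")
    d_a = popgen.nei_da(freqs)
    io.write_distance_matrix(d_a, out / "nei_da.tsv", prov)
    io.write_phylip_matrix(d_a, out / "nei_da.phy")
    tree = popgen.nj_tree(d_a)
    (out / "nj_tree.nwk").write_text(tree.as_string(schema="newick"))
    report["he_per_pop"] = he_per_pop
    report["nei_da"] = d_a
    t0 = _stage("popgen", t0)

    datasets = config.datasets or {"I": None}
    report["rankings"] = {}
    report["curves"] = {}
    report["fits"] = {}
    for ds_name, pops in datasets.items():
        sub = freqs if pops is None else freqs.subset_populations(pops)
        div = pd.DataFrame(
            {
                "global_fst": popgen.fst_global(sub).per_locus,
                "pairwise_fst": popgen.fst_pairwise(sub).per_locus_mean,
                "delta": popgen.delta(sub),
            }
        )
        div.to_csv(out / f"divergence_{ds_name}.tsv", sep="\t")
        method_scores: dict[str, pd.Series | pd.DataFrame] = {
            m: div for m in config.methods
        }
        if config.run_outlier_scan:
            counts, ncop = markers.counts_from_frequencies(sub)
            scan = markers.scan_outliers(
                counts, ncop, loci=sub.loci, mcmc=config.mcmc, seed=config.seed + 7
            )
            scan.table.to_csv(out / f"outliers_{ds_name}.tsv", sep="\t")
            method_scores["outlier"] = scan.table["log10_PO"]
            t0 = _stage("outlier_scan", t0, dataset=ds_name)
        for method in method_scores:
            ranking = markers.rank_loci(
                method, method_scores[method], populations=sub.populations,
                seed=config.seed,
            )
            if method != "random":
                ranking = markers.prune_linked(ranking, panel, config.min_cM)
            pd.DataFrame(
                {
                    "rank": range(1, len(ranking.loci) + 1),
                    "locus_id": ranking.loci,
                    "score": ranking.scores.to_numpy(),
                    "method": method,
                }
            ).to_csv(out / f"ranking_{ds_name}_{method}.tsv", sep="\t", index=False)
            sizes = [s for s in config.subset_sizes if s <= len(ranking.loci)]
            if not sizes:
                continue
            if method == "random":
                subs = markers.make_subsets(
                    ranking, sizes, random=True, seed=config.seed
                )
                order = None
                curve = _random_curve(freqs, subs, config)
            else:
                curve = gsi.accuracy_curve(
                    freqs, ranking, sizes,
                    n_baseline=config.n_baseline,
                    n_mixture=config.n_mixture,
                    seed=config.seed + 11,
                )
            curve.to_csv(
                out / f"curve_{ds_name}_{method}.tsv", sep="\t", index=False
            )
            fit = gsi.fit_required_markers(curve, targets=config.targets)
            io.write_fit_json(
                fit, out / f"fit_{ds_name}_{method}.json",
                extra={"dataset": ds_name, "method": method, "seed": config.seed},
            )
            report["rankings"][(ds_name, method)] = ranking
            report["curves"][(ds_name, method)] = curve
            report["fits"][(ds_name, method)] = fit
            t0 = _stage("gsi_curve", t0, dataset=ds_name, method=method)
    return report


def _random_curve(freqs, subsets, config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for sub in sorted(subsets, key=lambda s: s.size):
        base = gsi.simulate_genotypes(
            freqs, config.n_baseline, sub.loci, role="baseline",
            seed=config.seed + 100 + sub.size,
        )
        mix = gsi.simulate_genotypes(
            freqs, config.n_mixture, sub.loci, role="mixture",
            seed=config.seed + 200 + sub.size,
        )
        result = gsi.assign(mix, gsi.BaselineSet.from_genotypes(base))
        overall, per_pop = gsi.evaluate_accuracy(result)
        row = {
            "size": sub.size,
            "independent_alleles": sub.size,
            "overall_pct": overall,
        }
        row.update({f"pct_{p}": v for p, v in per_pop.items()})
        rows.append(row)
    return pd.DataFrame(rows)
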