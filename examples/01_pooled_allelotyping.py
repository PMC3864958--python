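"""Estimate population allele frequencies from pooled-DNA array signals.

Simulates 8 populations typed at 500 SNPs as DNA pools (50 diploids per
pool, 4 technical replicates), applies the replicate-quality filter, and
converts the replicate thetas to allele frequencies against the
per-locus cluster reference.
"""

import numpy as np

from poolgsi import allelotyping, synthetic

truth = synthetic.make_truth(500, 8, pop_fst=0.05, outlier_fraction=0.0,
                             seed=11)
freqs, _ = synthetic.generate_population_frequencies(truth)
ref = synthetic.generate_cluster_reference(500, seed=12)
thetas = synthetic.generate_pool_replicates(freqs, ref, n_replicates=4,
                                            theta_noise_sd=0.01, seed=13)

retained, flags = allelotyping.filter_replicate_quality(thetas, max_sd=0.02)
print(f"replicate QC retained {len(retained)} / 500 loci "
      f"(SD of theta across replicates <= 0.02 in every population)")

est = allelotyping.pool_frequencies(thetas, ref, n_individuals=50,
                                    loci=retained)
true_sub = freqs.freq.loc[est.loci, est.populations].to_numpy()
r = np.corrcoef(est.freq.to_numpy().ravel(), true_sub.ravel())[0, 1]
mae = np.abs(est.freq.to_numpy() - true_sub).mean()
print(f"Pearson r between pool estimates and true frequencies: {r:.4f}")
print(f"mean absolute frequency error: {mae:.4f}")
print("-> at theta noise SD 0.01 the pools recover individual-level "
      "frequencies almost exactly")
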