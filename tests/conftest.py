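import numpy as np
import pandas as pd
import pytest

from poolgsi import synthetic
from poolgsi.tables import AlleleFrequencyTable


@pytest.fixture(scope="session")
def small_system():
    """A 5-population x 200-locus synthetic system with pools (seeded)."""
    truth = synthetic.make_truth(200, 5, pop_fst=0.08, outlier_fraction=0.05,
                                 outlier_multiplier=6.0, seed=101)
    freqs, flags = synthetic.generate_population_frequencies(truth)
    ref = synthetic.generate_cluster_reference(200, seed=102)
    thetas = synthetic.generate_pool_replicates(freqs, ref, 4, 0.01, seed=103)
    return {"truth": truth, "freqs": freqs, "flags": flags, "ref": ref,
            "thetas": thetas}


@pytest.fixture()
def random_table():
    """Random 5-population x 20-locus frequency table for brute-force oracles."""
    rng = np.random.default_rng(7)
    freq = pd.DataFrame(
        rng.uniform(0.02, 0.98, size=(20, 5)),
        index=[f"L{i:04d}" for i in range(1, 21)],
        columns=[f"pop{j}" for j in range(1, 6)],
    )
    return AlleleFrequencyTable(freq, pd.Series(50.0, index=freq.columns))


@pytest.fixture()
def clustered_table():
    """Two well-separated population clusters (deep split) over 300 loci."""
    rng = np.random.default_rng(42)
    n_loci = 300
    anc = rng.uniform(0.1, 0.9, size=n_loci)

    def bn(p, F, size):
        scale = (1 - F) / F
        return rng.beta(p * scale, (1 - p) * scale, size=size)

    left_anc = bn(anc, 0.25, n_loci)
    right_anc = bn(anc, 0.25, n_loci)
    pops = {}
    for j in range(3):
        pops[f"west{j+1}"] = np.clip(bn(np.clip(left_anc, 0.01, 0.99), 0.02, n_loci), 0, 1)
    for j in range(3):
        pops[f"east{j+1}"] = np.clip(bn(np.clip(right_anc, 0.01, 0.99), 0.02, n_loci), 0, 1)
    freq = pd.DataFrame(pops, index=[f"L{i:04d}" for i in range(1, n_loci + 1)])
    return AlleleFrequencyTable(freq, pd.Series(50.0, index=freq.columns))
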