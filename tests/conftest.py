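import numpy as np
import pandas as pd
import pytest

import trfkin as tk

SMALL_GENES = {
    "tRF-1": 6, "tRF-5": 4, "tRF-3": 4, "tRF-leader": 2,
    "intron-tRF": 3, "misc-tRF": 3, "miRNA": 8,
}


@pytest.fixture(scope="session")
def small_params():
    return tk.SimParams(seed=7, n_genes_per_class=SMALL_GENES)


@pytest.fixture(scope="session")
def small_data(small_params):
    return tk.simulate_dataset(small_params)


@pytest.fixture(scope="session")
def default_data():
    """One full-size generator run at the default study conditions."""
    return tk.simulate_dataset(tk.SimParams(seed=1))


@pytest.fixture(scope="session")
def default_result(default_data):
    return tk.run_halflife(default_data.timecourse)


def make_custom_truth(k, a0, classes="misc-tRF", n_spikes=52,
                      spike_abundance=300.0):
    """Truth table with prescribed kinetics plus a constant spike-in block."""
    k = np.asarray(k, float)
    a0 = np.asarray(a0, float)
    n = len(k)
    if isinstance(classes, str):
        classes = [classes] * n
    rows = pd.DataFrame({
        "sequence_id": [f"s{i:04d}" for i in range(n)],
        "sequence": ["A" * 20] * n,
        "true_class": classes,
        "parent_locus": "synthetic",
        "a0_true": a0, "k_true": k, "rip_enrichment_true": 1.0,
    })
    spikes = pd.DataFrame({
        "sequence_id": [f"spike-{j:02d}" for j in range(n_spikes)],
        "sequence": ["C" * 20] * n_spikes,
        "true_class": "spike-in", "parent_locus": "spike",
        "a0_true": spike_abundance, "k_true": 0.0,
        "rip_enrichment_true": np.nan,
    })
    return tk.SimTruth(pd.concat([rows, spikes], ignore_index=True))
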