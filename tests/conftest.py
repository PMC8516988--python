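from pathlib import Path

import pandas as pd
import pytest

from m6array import SimulationConfig, generate_dataset, quantify

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_probes=200, n_spikeins=8, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    dataset, truth = generate_dataset(small_config)
    return dataset, truth


@pytest.fixture(scope="session")
def small_profile(small_dataset):
    dataset, _ = small_dataset
    return quantify(dataset)


@pytest.fixture(scope="session")
def noiseless_profile_and_truth():
    """Zero-noise, zero-effect dataset with a fixed 0.6 baseline methylation."""
    cfg = SimulationConfig(
        n_probes=60, n_spikeins=4, noise_log2_sd=0.0, frac_diff_meth=0.0,
        frac_diff_expr=0.0, flag_absent_rate=0.0,
        meth_baseline_low=0.6, meth_baseline_high=0.6, seed=5,
    )
    dataset, truth = generate_dataset(cfg)
    return quantify(dataset), truth


@pytest.fixture(scope="session")
def table3_records():
    """The published top-20 hypo-methylated mRNA table, as a differential table.

    The source prints fold changes and regulation classes but not the
    per-probe p-values, so every row is given an (arbitrarily) significant
    p on both axes and a distinct probe id for classification/sorting tests.
    """
    t = pd.read_csv(DATA_DIR / "table3_top20_mrna.tsv", sep="\t")
    t.index = pd.Index([f"PUB{i:03d}" for i in range(len(t))], name="probe_id")
    t["rna_type"] = "mRNA"
    t["fc_meth_ratio"] = 2.0 ** t["fc_m6a_log2"]
    t["p_meth"] = t["p_m6a"] = t["p_ge"] = 0.001
    return t


@pytest.fixture(scope="session")
def table4_records():
    t = pd.read_csv(DATA_DIR / "table4_top20_other.tsv", sep="\t")
    t.index = pd.Index([f"PUB{i:03d}" for i in range(len(t))], name="probe_id")
    return t
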