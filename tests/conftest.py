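import numpy as np
import pandas as pd
import pytest

from npcg.annotation import annotate_sites
from npcg.containers import SampleTable
from npcg.methylation import filter_coverage
from npcg.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small coupled dataset with signal in both omics."""
    cfg = SimulationConfig(seed=7, n_cpg=800, n_genes=120)
    ann, meth, counts, samples, truth = simulate_dataset(cfg)
    return {"config": cfg, "annotation": ann, "methylome": meth,
            "counts": counts, "samples": samples, "truth": truth}


@pytest.fixture(scope="session")
def small_filtered(small_dataset):
    filt = filter_coverage(small_dataset["methylome"])
    site_ann = annotate_sites(filt.sites, small_dataset["annotation"])
    return filt, site_ann


@pytest.fixture
def two_group_samples():
    """Plain 4-vs-4 sample sheet."""
    return SampleTable(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(8)],
        "group": ["A"] * 4 + ["B"] * 4,
    }), reference="A")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
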