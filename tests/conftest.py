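import numpy as np
import pandas as pd
import pytest

from brulechip.model import ProbeLibrary, ProbePair, TaxonomyTable, RANKS
from brulechip.simulate import SimulationConfig, simulate_array


@pytest.fixture
def toy_library() -> ProbeLibrary:
    """Two OTUs x 4 pairs plus 2 spike probes."""
    sets = {
        otu: [ProbePair(f"p{k}", f"{otu}.p{k}.pm", f"{otu}.p{k}.mm") for k in range(4)]
        for otu in ("otuA", "otuB")
    }
    return ProbeLibrary(sets, spike_probes=["sp0", "sp1"])


@pytest.fixture
def toy_taxonomy() -> TaxonomyTable:
    rows = {
        "otuA": ("Bacteria", "Firmicutes", "Bacilli", "Bacillales", "Bacillaceae", "Bacillus"),
        "otuB": ("Archaea", "Crenarchaeota", "", "", "", ""),
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    df.index.name = "otu_id"
    return TaxonomyTable(df)


@pytest.fixture
def design_3v3() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": ["IN"] * 3 + ["OUT"] * 3,
            "site": "S1",
            "pool": [1, 2, 3, 1, 2, 3],
        },
        index=pd.Index([f"In_{i}" for i in (1, 2, 3)] + [f"Out_{i}" for i in (1, 2, 3)],
                       name="sample_id"),
    )


def noise_free_config(seed: int, rng: np.random.Generator) -> SimulationConfig:
    """A random desk-scale config in the exactly-recoverable regime."""
    return SimulationConfig(
        seed=seed,
        n_phyla=int(rng.integers(2, 5)),
        otus_per_phylum=int(rng.integers(4, 10)),
        pairs_per_probe_set=int(rng.integers(8, 14)),
        lognormal_sigma=0.0,
        mm_leak_fraction=0.0,
        crosshyb_rate=0.0,
        pm_signal_mean=10000.0,
        background_mean=20.0,
        presence_prob=float(rng.uniform(0.3, 0.9)),
        n_archaeal_phyla=1,
        array_scale_jitter=float(rng.uniform(0.0, 0.2)),
    )


@pytest.fixture
def small_noisy_sim():
    cfg = SimulationConfig(seed=11, n_phyla=4, otus_per_phylum=10, crosshyb_rate=0.1)
    return simulate_array(cfg)
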