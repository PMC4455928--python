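import numpy as np
import pandas as pd
import pytest

from yolkde import CountMatrix, IntensityMatrix, SimConfig


@pytest.fixture
def small_config():
    return SimConfig(n_genes=500, n_spiked=25, spike_log2fc=3.0, seed=11)


@pytest.fixture
def null_config():
    return SimConfig(n_genes=500, n_spiked=0, seed=11)


@pytest.fixture
def tiny_counts():
    """Hand-sized paired count matrix: 3 batches x (YD, SP)."""
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.poisson(50, size=(40, 6)),
        index=pd.Index([f"g{i:02d}" for i in range(40)], name="gene_id"),
        columns=["YD_b1", "SP_b1", "YD_b2", "SP_b2", "YD_b3", "SP_b3"],
    )
    meta = pd.DataFrame(
        {
            "condition": ["YD", "SP"] * 3,
            "batch": ["b1", "b1", "b2", "b2", "b3", "b3"],
        },
        index=pd.Index(counts.columns, name="sample_id"),
    )
    return CountMatrix(counts, meta)


def make_intensity_matrix(values, flags=None, probe_map=None):
    """Wrap a probes x 6 array into an IntensityMatrix (3 YD + 3 SP)."""
    values = np.asarray(values, dtype=float)
    arrays = ["YD_a1", "YD_a2", "YD_a3", "SP_a1", "SP_a2", "SP_a3"]
    pidx = pd.Index([f"p{i:03d}" for i in range(values.shape[0])],
                    name="probe_id")
    if flags is None:
        flags = np.ones_like(values, dtype=bool)
    if probe_map is None:
        probe_map = pd.Series([f"t{i:03d}" for i in range(values.shape[0])],
                              index=pidx)
    else:
        probe_map = pd.Series(probe_map, index=pidx)
    meta = pd.DataFrame({"condition": ["YD"] * 3 + ["SP"] * 3},
                        index=pd.Index(arrays, name="array_id"))
    return IntensityMatrix(
        pd.DataFrame(values, index=pidx, columns=arrays),
        pd.DataFrame(np.asarray(flags, dtype=bool), index=pidx, columns=arrays),
        probe_map, meta,
    )
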