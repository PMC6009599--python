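import numpy as np
import pandas as pd
import pytest

from thx import ArraySample, ProbeTable, SimConfig, simulate

SMALL_GROUPS = {
    "potentiated": 4,
    "te_up_t_unchanged": 6,
    "te_up_t_down": 4,
    "t_up_only": 4,
    "t_down_only": 6,
    "te_down": 2,
    "mono_shift": 4,
}


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(
        n_genes=150,
        n_replicates=3,
        probes_per_gene=2,
        group_sizes=dict(SMALL_GROUPS),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate(small_cfg)


@pytest.fixture()
def make_probe_table():
    """Build a ProbeTable from (probe_id, gene_id, is_control, signal, reference) rows."""

    def _make(rows, sample=None):
        sample = sample or ArraySample("a1", "total", 30, 1)
        df = pd.DataFrame(
            rows, columns=["probe_id", "gene_id", "is_control", "signal", "reference"]
        )
        return ProbeTable(df, sample)

    return _make


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
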