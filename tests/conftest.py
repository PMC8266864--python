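import numpy as np
import pandas as pd
import pytest

import natraj as nj


@pytest.fixture(scope="session")
def sim_default():
    """One default-config simulated dataset shared across tests."""
    cfg = nj.SimulationConfig(seed=11)
    counts, meta, ann, truth = nj.simulate_dataset(cfg)
    return cfg, counts, meta, ann, truth


@pytest.fixture(scope="session")
def sim_filtered(sim_default):
    _, counts, meta, ann, truth = sim_default
    kept, report = nj.filter_low_expression(counts, meta)
    return kept, meta, ann, truth, report


@pytest.fixture()
def tiny_counts():
    df = pd.DataFrame(
        [[0, 5], [10, 1], [2, 3]],
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        columns=["s1", "s2"],
    )
    return nj.CountMatrix(df)


@pytest.fixture()
def tiny_meta():
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s2"],
            "tissue_group": ["NAT", "N"],
            "sex": ["F", "M"],
            "age": [45.0, 60.0],
            "lt_status": ["LT+", "NA"],
            "patient_id": ["P1", None],
        }
    )
    return meta.set_index("sample_id", drop=False)


def make_deg_list(gene_ids, log2fcs, padjs, contrast="test"):
    table = pd.DataFrame(
        {
            "log2fc": np.asarray(log2fcs, float),
            "padj": np.asarray(padjs, float),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    table["direction"] = np.where(table["log2fc"] > 0, "up", "down")
    return nj.DEGList(contrast=contrast, table=table)
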