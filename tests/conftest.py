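import numpy as np
import pandas as pd
import pytest

from mirstem.synthetic import SyntheticConfig, simulate_derepression_profiles


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_genes=2000, n_targets=200, seed=11)


@pytest.fixture(scope="session")
def small_derepression(small_config):
    return simulate_derepression_profiles(small_config)


@pytest.fixture
def ct_table():
    """Tiny hand-built Ct table: 2 groups x 3 samples, 2 assays + 1 housekeeping."""
    rows = []
    hk = {"A_1": 20.0, "A_2": 20.1, "A_3": 19.9, "B_1": 20.0, "B_2": 20.2, "B_3": 19.8}
    # assay m1: dCt 4 in A, 5 in B (log2FC = +1, higher in A)
    m1 = {"A_1": 24.0, "A_2": 24.2, "A_3": 23.9, "B_1": 25.0, "B_2": 25.3, "B_3": 24.7}
    # assay m2: identical in both groups
    m2 = {s: h + 3.0 for s, h in hk.items()}
    for sample, ct in hk.items():
        group, rep = sample.split("_")
        rows.append(("hk1", sample, group, int(rep), ct, True))
    for assay, table in (("m1", m1), ("m2", m2)):
        for sample, ct in table.items():
            group, rep = sample.split("_")
            rows.append((assay, sample, group, int(rep), ct, False))
    return pd.DataFrame(
        rows, columns=["assay_id", "sample_id", "group", "replicate", "ct", "is_housekeeping"]
    )
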