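import numpy as np
import pandas as pd
import pytest

from rhizocore import AbundanceTable


def make_table(values, mode="proportion", otu_ids=None, sample_ids=None, groups=None):
    """Build an AbundanceTable from a 2D array-like (rows = OTUs)."""
    values = np.asarray(values, dtype=float)
    n_otus, n_samples = values.shape
    otu_ids = otu_ids or [f"OTU{i + 1}" for i in range(n_otus)]
    sample_ids = sample_ids or [f"S{j + 1}" for j in range(n_samples)]
    groups = groups or {s: "all" for s in sample_ids}
    return AbundanceTable(
        data=pd.DataFrame(values, index=otu_ids, columns=sample_ids),
        mode=mode,
        groups=groups,
    )


def random_proportion_table(rng, n_otus=20, n_samples=4, zero_prob=0.3, group="G"):
    """Random proportion-mode table with sporadic absences (one group)."""
    w = rng.random((n_otus, n_samples)) + 0.05
    mask = rng.random((n_otus, n_samples)) < zero_prob
    mask[0, :] = False  # keep every column non-degenerate
    w[mask] = 0.0
    w = w / w.sum(axis=0)
    sample_ids = [f"{group}{j + 1}" for j in range(n_samples)]
    return make_table(
        w,
        mode="proportion",
        sample_ids=sample_ids,
        groups={s: group for s in sample_ids},
    )


@pytest.fixture
def counts_table():
    """3 OTUs x 2 samples of raw counts, two groups."""
    return make_table(
        [[2.0, 1.0], [3.0, 1.0], [5.0, 8.0]],
        mode="counts",
        sample_ids=["W1", "L1"],
        groups={"W1": "W", "L1": "L"},
    )
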