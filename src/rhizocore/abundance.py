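"""Normalisation and per-group summary statistics for abundance tables.

Relative abundances are stored internally as proportions (columns sum to 1);
all reported summary statistics are on the percent scale, matching how
core-microbiome tables are conventionally printed.  The per-OTU standard
deviation of relative abundance across a group's samples (SDRA) computed
here is the statistic thresholded by the composition-based core method.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .tables_io import (
    MODE_COUNTS,
    MODE_PERCENT,
    MODE_PROPORTION,
    AbundanceTable,
)

__all__ = ["to_relative", "summarize_group"]


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Normalise a table to proportion mode (each sample column sums to 1).

    Counts are divided by their column sum; percent values by 100;
    proportion tables are returned unchanged.  An all-zero sample column is
    an error (its composition is undefined).
    """
    if table.mode == MODE_PROPORTION:
        return table
    values = table.data.to_numpy(dtype=float)
    if table.mode == MODE_PERCENT:
        out = values / 100.0
    else:
        sums = values.sum(axis=0)
        zero = np.flatnonzero(sums == 0)
        if zero.size:
            raise ValueError(
                f"sample {table.sample_ids[zero[0]]!r} has zero total count; "
                "cannot normalise"
            )
        out = values / sums
    data = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    return AbundanceTable(data=data, mode=MODE_PROPORTION, groups=dict(table.groups))


def summarize_group(
    table: AbundanceTable,
    group: str,
    presence_epsilon: float = 0.0,
    sd_ddof: int = 1,
) -> pd.DataFrame:
    """Per-OTU summary statistics over one group's samples.

    Returns a DataFrame indexed by OTU ID with columns:

    mean_ra
        100 x mean proportion over the group's samples (percent scale).
    sd_ra
        100 x standard deviation of the proportions (percent scale).  The
        sample convention (``sd_ddof=1``) is the default; a one-sample group
        gets sd_ra = 0 under either convention.
    prevalence
        Fraction of the group's samples where the OTU's proportion exceeds
        ``presence_epsilon`` (default 0: any detection counts).

    The table must already be in proportion mode.
    """
    if table.mode != MODE_PROPORTION:
        raise ValueError(
            f"summarize_group requires proportion mode, got {table.mode!r}; "
            "apply to_relative first"
        )
    if sd_ddof not in (0, 1):
        raise ValueError(f"sd_ddof must be 0 or 1, got {sd_ddof!r}")
    samples = table.samples_in(group)
    sub = table.data[samples].to_numpy(dtype=float)
    n = sub.shape[1]
    mean_ra = 100.0 * sub.mean(axis=1)
    if n == 1:
        sd_ra = np.zeros(sub.shape[0])
    else:
        sd_ra = 100.0 * sub.std(axis=1, ddof=sd_ddof)
    prevalence = (sub > presence_epsilon).mean(axis=1)
    return pd.DataFrame(
        {
            "group": group,
            "mean_ra": mean_ra,
            "sd_ra": sd_ra,
            "prevalence": prevalence,
        },
        index=pd.Index(table.otu_ids, name="otu_id"),
    )
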