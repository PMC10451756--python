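"""Bundled reference core-microbiome tables and their sample-level expansion.

The four tables are the published per-group summaries from a wheat
rhizosphere forecrop comparison (wheat forecrop W vs legume forecrop L,
four samples per group): the top-10 membership cores for each forecrop
("table1" = W, "table2" = L, plain relative abundances on the percent
scale) and the shared-OTU composition candidates with mean +/- SD
("table3" = W, "table4" = L, percent scale).

Only per-group summaries were published, never the underlying per-sample
matrix.  :func:`fixture_sample_table` therefore reconstructs a synthetic
4-sample proportion table whose per-OTU group mean (and, where printed,
sample standard deviation) reproduce the summary exactly, so the core
methods can be exercised end-to-end against the printed numbers.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .tables_io import (
    MODE_PROPORTION,
    AbundanceTable,
    CoreMember,
    CoreSet,
    Lineage,
    parse_lineage,
)

__all__ = [
    "fixture_tables",
    "fixture_core_set",
    "fixture_sample_table",
    "fixture_lineages",
    "REPORTED_TOTALS",
]

# (otu_id, taxonomy label, mean relative abundance in percent, sd or None)
_TABLE1: Tuple[Tuple[str, str, float, Optional[float]], ...] = (
    ("OTU1", "Hyphomicrobiaceae", 0.0334, None),
    ("OTU2", "Sphingomonas sp.", 0.0328, None),
    ("OTU14", "Bradyrhizobiaceae", 0.0213, None),
    ("OTU5", "Burkholderiales", 0.0207, None),
    ("OTU3", "Nitrospira sp.", 0.0199, None),
    ("OTU7", "Rhizobiales", 0.0153, None),
    ("OTU26", "Baekduia sp.", 0.0145, None),
    ("OTU4", "Pseudarthrobacter sp.", 0.0144, None),
    ("OTU9", "Bradyrhizobium sp.", 0.0135, None),
    ("OTU12", "Bradyrhizobium sp.", 0.0118, None),
)

_TABLE2: Tuple[Tuple[str, str, float, Optional[float]], ...] = (
    ("OTU1", "Hyphomicrobiaceae", 0.0325, None),
    ("OTU3", "Nitrospira sp.", 0.0248, None),
    ("OTU11", "Bradyrhizobiaceae", 0.0206, None),
    ("OTU4", "Pseudarthrobacter sp.", 0.0197, None),
    ("OTU10", "Gp16", 0.0195, None),
    ("OTU6", "Rhizobiales", 0.0182, None),
    ("OTU13", "Gp3", 0.0173, None),
    ("OTU16", "Bradyrhizobiaceae", 0.0169, None),
    ("OTU8", "Pseudarthrobacter sp.", 0.0165, None),
    ("OTU7", "Rhizobiales", 0.0149, None),
)

_TABLE3: Tuple[Tuple[str, str, float, Optional[float]], ...] = (
    ("OTU1", "Hyphomicrobiaceae", 1.232, 0.1780),
    ("OTU3", "Nitrospira sp.", 0.913, 0.2790),
    ("OTU7", "Bradyrhizobiaceae", 0.3840, 0.0033),
    ("OTU4", "Pseudarthrobacter sp.", 0.6180, 0.0021),
    ("OTU9", "Bradyrhizobium sp.", 0.3380, 0.0016),
    ("OTU8", "Pseudarthrobacter sp.", 0.2950, 0.0003),
    ("OTU17", "Nitrospira sp.", 0.1350, 0.0005),
    ("OTU36", "Streptosporangium sp.", 0.3041, 0.0023),
    ("OTU13", "Acidobacteria_Gp3", 0.2954, 0.0001),
    ("OTU69", "Devosia sp.", 0.2575, 0.0001),
)

_TABLE4: Tuple[Tuple[str, str, float, Optional[float]], ...] = (
    ("OTU1", "Hyphomicrobiaceae", 1.0240, 0.1810),
    ("OTU3", "Nitrospira sp.", 0.7360, 0.0930),
    ("OTU11", "Rhodoplanes sp.", 0.6750, 0.1420),
    ("OTU4", "Pseudarthrobacter sp.", 0.5760, 0.2663),
    ("OTU10", "Acidobacteria_Gp16", 0.5599, 0.1328),
    ("OTU13", "Acidobacteria_Gp3", 0.6360, 0.1460),
    ("OTU16", "Rhizobiales", 0.4457, 0.0129),
    ("OTU8", "Pseudarthrobacter sp.", 0.3634, 0.0500),
    ("OTU9", "Nitrospira sp.", 0.3072, 0.0663),
    ("OTU7", "Bradyrhizobiaceae", 0.3451, 0.1095),
)

_TABLES = {
    "table1": ("membership", "W", _TABLE1),
    "table2": ("membership", "L", _TABLE2),
    "table3": ("composition_candidates", "W", _TABLE3),
    "table4": ("composition_candidates", "L", _TABLE4),
}

#: Summary totals as reported in the source text.  The membership-L total
#: is quoted there as 0.2006 although the printed rows sum to 0.2009; the
#: rows are authoritative here (see docs/methods.md).
REPORTED_TOTALS = {"table1": 0.1976, "table2": 0.2006}


def fixture_tables() -> Dict[str, List[CoreMember]]:
    """All four bundled summary tables as CoreMember records, as printed."""
    return {
        name: [CoreMember(o, t, m, s) for (o, t, m, s) in rows]
        for name, (_, _, rows) in _TABLES.items()
    }


def fixture_core_set(name: str) -> CoreSet:
    """One bundled table as a CoreSet (group W/L per the table)."""
    if name not in _TABLES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_TABLES)}")
    method, group, rows = _TABLES[name]
    members = tuple(CoreMember(o, t, m, s) for (o, t, m, s) in rows)
    return CoreSet(
        method="membership" if method == "membership" else "composition",
        group=group,
        members=members,
        params={"fixture": name},
    )


def fixture_lineages(name: str) -> Dict[str, Lineage]:
    """Taxonomy labels of one bundled table as minimal Lineage records."""
    if name not in _TABLES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_TABLES)}")
    _, _, rows = _TABLES[name]
    return {o: parse_lineage(o, t) for (o, t, _, _) in rows}


# Symmetric per-sample offsets with zero mean and unit sample SD (ddof=1),
# used to realise a printed mean +/- SD exactly over four samples.
_OFFSETS = np.array([-1.5, -0.5, 0.5, 1.5])
_OFFSETS = _OFFSETS / _OFFSETS.std(ddof=1)


def fixture_sample_table(name: str, n_fillers: int = 4) -> AbundanceTable:
    """Expand a bundled summary table into a synthetic 4-sample proportion table.

    Each tabulated OTU receives four per-sample proportions whose group mean
    equals the printed relative abundance and — for tables carrying an SD
    column — whose sample standard deviation equals the printed SD (via
    symmetric offsets).  Patchy "filler" OTUs, each absent from exactly one
    sample, absorb the remaining column mass so every sample sums to 1;
    having prevalence 0.75 they can never enter the shared-OTU candidate
    set, so the core methods see exactly the tabulated OTUs.
    """
    if name not in _TABLES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_TABLES)}")
    if n_fillers < 2:
        raise ValueError("need >= 2 fillers to cover every sample")
    _, group, rows = _TABLES[name]
    samples = [f"{group}{i}" for i in range(1, 5)]
    otu_ids = [r[0] for r in rows]
    values = np.empty((len(rows), 4))
    for i, (_, _, mean_pct, sd_pct) in enumerate(rows):
        if sd_pct is None:
            values[i, :] = mean_pct / 100.0
        else:
            values[i, :] = (mean_pct + sd_pct * _OFFSETS) / 100.0
    if (values <= 0).any():
        raise ValueError(f"fixture {name!r} yields non-positive proportions")
    filler_ids = [f"FILL{k}" for k in range(1, n_fillers + 1)]
    fill = np.zeros((n_fillers, 4))
    remainder = 1.0 - values.sum(axis=0)
    for j in range(4):
        absent = j % n_fillers  # filler `absent` missing from sample j
        present = [k for k in range(n_fillers) if k != absent]
        fill[present, j] = remainder[j] / len(present)
    data = pd.DataFrame(
        np.vstack([values, fill]), index=otu_ids + filler_ids, columns=samples
    )
    # exact column sums: fold rounding residue into the largest filler cell
    resid = 1.0 - data.to_numpy().sum(axis=0)
    for j, r in enumerate(resid):
        k = int(np.argmax(fill[:, j]))
        data.iloc[len(otu_ids) + k, j] += r
    return AbundanceTable(
        data=data,
        mode=MODE_PROPORTION,
        groups={s: group for s in samples},
    )
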