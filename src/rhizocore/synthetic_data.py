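"""Synthetic rhizosphere amplicon communities with a planted core.

The generator emulates the study design every method here assumes: a small
number of groups (forecrops W and L), four samples per group at sequencing
depths of a few thousand reads, each group carrying a small ubiquitous
low-variance *core* of taxa on top of a large pool of patchy, rarer
*peripheral* taxa.

Expected proportions follow a lognormal law (the standard null for
amplicon communities): each planted core taxon draws a between-taxon base
abundance, jittered per sample with a configurable coefficient of
variation; peripheral taxa are present in a sample with probability
``peripheral_prevalence`` and draw abundances one order of magnitude lower.
Per-sample proportions are renormalised and observed counts drawn
multinomially at the requested depth.  Randomness comes from a single
``numpy.random.default_rng`` (PCG64) seeded from the spec, so identical
specs reproduce identical tables.

Taxonomy strings are cycled from a bundled lineage pool that covers the
genera and families typical of wheat rhizosphere cores (Hyphomicrobiaceae,
Bradyrhizobiaceae, Nitrospira, Sphingomonas, Pseudarthrobacter,
Bradyrhizobium, Rhodoplanes, Burkholderiales, ...), so the rule-based
functional methods find matches without any external database.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple, Union

import numpy as np
import pandas as pd

from .fixtures import fixture_tables  # re-exported: bundled summary tables
from .tables_io import (
    MODE_COUNTS,
    AbundanceTable,
    Lineage,
    parse_lineage,
    write_abundance_table,
    write_group_map,
    write_taxonomy,
)

__all__ = ["SyntheticSpec", "generate", "write_outputs", "fixture_tables", "LINEAGE_POOL"]

#: Plain semicolon lineages (domain;phylum;class;order;family;genus).
LINEAGE_POOL: Tuple[str, ...] = (
    "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;Hyphomicrobiaceae;Hyphomicrobium",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;Hyphomicrobiaceae;Rhodoplanes",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;Bradyrhizobiaceae;Bradyrhizobium",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;Hyphomicrobiaceae;Devosia",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Sphingomonadales;Sphingomonadaceae;Sphingomonas",
    "Bacteria;Nitrospirae;Nitrospira;Nitrospirales;Nitrospiraceae;Nitrospira",
    "Bacteria;Actinobacteria;Actinobacteria;Micrococcales;Micrococcaceae;Pseudarthrobacter",
    "Bacteria;Proteobacteria;Betaproteobacteria;Burkholderiales;Burkholderiaceae;Burkholderia",
    "Bacteria;Actinobacteria;Thermoleophilia;Solirubrobacterales;Solirubrobacteraceae;Solirubrobacter",
    "Bacteria;Actinobacteria;Actinobacteria;Streptosporangiales;Streptosporangiaceae;Streptosporangium",
    "Bacteria;Actinobacteria;Actinobacteria;Baekduiales;Baekduiaceae;Baekduia",
    "Bacteria;Acidobacteria;Acidobacteria_Gp3;Gp3;;",
    "Bacteria;Acidobacteria;Acidobacteria_Gp16;Gp16;;",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;;",
    "Bacteria;Firmicutes;Clostridia;Clostridiales;Clostridiaceae;Clostridium",
    "Bacteria;Actinobacteria;Actinobacteria;Micrococcales;Cellulomonadaceae;Cellulomonas",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic community draw.

    Defaults mirror the emulated study design: two forecrop groups of four
    rhizosphere samples each, ~5,000 reads per sample, ten planted core
    taxa per group over a pool of patchy peripherals.
    """

    n_groups: int = 2
    group_labels: Tuple[str, ...] = ("W", "L")
    samples_per_group: int = 4
    n_core: int = 10
    n_peripheral: int = 90
    depth: int = 5000
    #: log expected (pre-normalisation) proportion of a core taxon
    core_mean_logra: float = math.log(0.01)
    #: between-taxon spread of core log-abundance
    core_sigma: float = 0.3
    #: per-sample lognormal jitter CV of core taxa (0 = noise-free)
    core_cv: float = 0.2
    peripheral_prevalence: float = 0.5
    peripheral_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or len(self.group_labels) < self.n_groups:
            raise ValueError("need a label for every group")
        if min(self.samples_per_group, self.n_core, self.depth) < 1:
            raise ValueError("samples_per_group, n_core and depth must be >= 1")
        if self.n_peripheral < 0:
            raise ValueError("n_peripheral must be >= 0")
        if not 0.0 <= self.peripheral_prevalence <= 1.0:
            raise ValueError("peripheral_prevalence must be in [0, 1]")
        if self.core_cv < 0 or self.core_sigma < 0 or self.peripheral_sigma < 0:
            raise ValueError("dispersion parameters must be >= 0")


def generate(
    spec: SyntheticSpec,
) -> Tuple[AbundanceTable, Dict[str, Lineage], Dict[str, object]]:
    """Draw one synthetic community.

    Returns the counts-mode :class:`AbundanceTable` (columns sum exactly to
    ``spec.depth``), a taxonomy map, and a truth record listing the planted
    core OTU IDs per group (plus any depth warnings).
    """
    rng = np.random.default_rng(spec.seed)
    groups = list(spec.group_labels[: spec.n_groups])
    n_total = spec.n_core * len(groups) + spec.n_peripheral
    otu_ids = [f"OTU{i}" for i in range(1, n_total + 1)]

    core_of: Dict[str, List[str]] = {}
    offset = 0
    for g in groups:
        core_of[g] = otu_ids[offset : offset + spec.n_core]
        offset += spec.n_core

    # between-taxon base abundance of each group's core taxa
    core_base = {
        g: np.exp(rng.normal(spec.core_mean_logra, spec.core_sigma, spec.n_core))
        for g in groups
    }
    mu_peri = spec.core_mean_logra - math.log(10.0)
    sigma_jitter = math.sqrt(math.log(1.0 + spec.core_cv**2)) if spec.core_cv else 0.0

    sample_ids: List[str] = []
    group_map: Dict[str, str] = {}
    columns: List[np.ndarray] = []
    index = {o: i for i, o in enumerate(otu_ids)}
    for g in groups:
        for s in range(1, spec.samples_per_group + 1):
            sid = f"{g}{s}"
            sample_ids.append(sid)
            group_map[sid] = g
            w = np.zeros(n_total)
            core_idx = [index[o] for o in core_of[g]]
            if sigma_jitter:
                jitter = np.exp(
                    rng.normal(-0.5 * sigma_jitter**2, sigma_jitter, spec.n_core)
                )
            else:
                jitter = np.ones(spec.n_core)
            w[core_idx] = core_base[g] * jitter
            # everything not core-in-this-group behaves peripherally
            others = [i for i in range(n_total) if i not in set(core_idx)]
            if others:
                present = rng.random(len(others)) < spec.peripheral_prevalence
                abund = np.exp(
                    rng.normal(mu_peri, spec.peripheral_sigma, len(others))
                )
                w[others] = np.where(present, abund, 0.0)
            p = w / w.sum()
            columns.append(rng.multinomial(spec.depth, p).astype(float))

    data = pd.DataFrame(
        np.column_stack(columns), index=otu_ids, columns=sample_ids
    )
    table = AbundanceTable(data=data, mode=MODE_COUNTS, groups=group_map)

    lineages = {
        o: parse_lineage(o, LINEAGE_POOL[int(rng.integers(len(LINEAGE_POOL)))])
        for o in otu_ids
    }

    warnings_list: List[str] = []
    expected_total = (
        spec.n_core * math.exp(spec.core_mean_logra)
        + (n_total - spec.n_core)
        * spec.peripheral_prevalence
        * math.exp(mu_peri + 0.5 * spec.peripheral_sigma**2)
    )
    min_expected_reads = spec.depth * math.exp(
        spec.core_mean_logra - 2 * spec.core_sigma
    ) / expected_total
    if min_expected_reads < 1.0:
        warnings_list.append(
            "depth too small to represent the planted core: expected core "
            f"counts fall below 1 read ({min_expected_reads:.3g})"
        )
    truth: Dict[str, object] = {
        "core": core_of,
        "spec": asdict(spec),
        "warnings": warnings_list,
        "rng": "numpy.random.default_rng (PCG64)",
    }
    return table, lineages, truth


def write_outputs(
    table: AbundanceTable,
    lineages: Dict[str, Lineage],
    truth: Dict[str, object],
    out_dir: Union[str, Path],
) -> None:
    """Write abundance.tsv, taxonomy.tsv, groups.tsv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_abundance_table(table, out / "abundance.tsv")
    write_taxonomy(lineages, out / "taxonomy.tsv")
    write_group_map(table.groups, out / "groups.tsv")
    (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
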