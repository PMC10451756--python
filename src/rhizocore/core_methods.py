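"""Core-microbiome definition methods and cross-core comparison.

Two definitions are implemented, both restricted to the group's *shared*
OTUs (prevalence 1.0 — detected in every sample of the group):

membership
    Rank the shared OTUs by mean relative abundance and keep the top N
    ("top-10" in the usual presentation).
composition
    Keep the shared OTUs whose standard deviation of relative abundance
    across the group's samples (SDRA) is strictly below a threshold —
    taxa present everywhere at similar proportions.

:func:`overlap` partitions two core sets into shared and method- or
group-unique members, the set algebra behind Venn-style comparisons of
cores across methods and forecrops (generalists vs specialists).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

from .abundance import summarize_group
from .tables_io import (
    AbundanceTable,
    CoreMember,
    CoreSet,
    Lineage,
    natural_key,
)

__all__ = ["membership_core", "composition_core", "overlap", "OverlapReport"]


def _label(otu_id: str, taxonomy: Optional[Mapping[str, Lineage]]) -> str:
    if taxonomy is None or otu_id not in taxonomy:
        return otu_id
    return taxonomy[otu_id].label


def _shared_summaries(table, group, presence_epsilon, sd_ddof):
    summaries = summarize_group(
        table, group, presence_epsilon=presence_epsilon, sd_ddof=sd_ddof
    )
    shared = summaries[summaries["prevalence"] == 1.0]
    order = sorted(
        shared.index, key=lambda o: (-shared.at[o, "mean_ra"], natural_key(o))
    )
    return shared.loc[order]


def membership_core(
    table: AbundanceTable,
    group: str,
    top_n: int = 10,
    taxonomy: Optional[Mapping[str, Lineage]] = None,
    presence_epsilon: float = 0.0,
    sd_ddof: int = 1,
) -> CoreSet:
    """Membership-based core: the top-N most abundant shared OTUs.

    Candidates are OTUs detected in every one of the group's samples;
    they are ranked by mean relative abundance descending (ties broken by
    natural OTU-ID order) and the first ``top_n`` kept.  Fewer candidates
    than ``top_n`` yields a smaller core.
    """
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    shared = _shared_summaries(table, group, presence_epsilon, sd_ddof)
    chosen = shared.iloc[:top_n]
    members = tuple(
        CoreMember(
            otu_id=o,
            taxonomy=_label(o, taxonomy),
            mean_ra=float(chosen.at[o, "mean_ra"]),
            sd_ra=None,
        )
        for o in chosen.index
    )
    return CoreSet(
        method="membership",
        group=group,
        members=members,
        params={
            "top_n": top_n,
            "presence_epsilon": presence_epsilon,
            "sd_ddof": sd_ddof,
        },
    )


def composition_core(
    table: AbundanceTable,
    group: str,
    sd_threshold: float = 0.01,
    threshold_scale: str = "percent",
    taxonomy: Optional[Mapping[str, Lineage]] = None,
    presence_epsilon: float = 0.0,
    sd_ddof: int = 1,
) -> CoreSet:
    """Composition-based core: shared OTUs with SDRA strictly below a threshold.

    The candidate set is the same shared-OTU set as the membership method;
    an OTU is retained when its standard deviation of relative abundance is
    ``< sd_threshold`` (strict).  The threshold is read on the percent scale
    by default — the scale on which core tables print their +/- SD columns —
    or on the proportion scale with ``threshold_scale="proportion"``.
    Requires at least two samples in the group (SD is undefined otherwise).
    """
    if sd_threshold <= 0:
        raise ValueError(f"sd_threshold must be > 0, got {sd_threshold}")
    if threshold_scale not in ("percent", "proportion"):
        raise ValueError(f"unknown threshold_scale: {threshold_scale!r}")
    if len(table.samples_in(group)) < 2:
        raise ValueError(
            f"group {group!r} has a single sample: the standard deviation of "
            "relative abundance is undefined; the composition method needs >= 2"
        )
    shared = _shared_summaries(table, group, presence_epsilon, sd_ddof)
    # sd_ra is on the percent scale; a proportion-scale threshold maps to x100
    threshold_pct = sd_threshold if threshold_scale == "percent" else sd_threshold * 100.0
    kept = shared[shared["sd_ra"] < threshold_pct]
    members = tuple(
        CoreMember(
            otu_id=o,
            taxonomy=_label(o, taxonomy),
            mean_ra=float(kept.at[o, "mean_ra"]),
            sd_ra=float(kept.at[o, "sd_ra"]),
        )
        for o in kept.index
    )
    return CoreSet(
        method="composition",
        group=group,
        members=members,
        params={
            "sd_threshold": sd_threshold,
            "threshold_scale": threshold_scale,
            "presence_epsilon": presence_epsilon,
            "sd_ddof": sd_ddof,
        },
    )


@dataclass
class OverlapReport:
    """Set-algebra partition of two core sets by OTU ID.

    ``shared`` holds IDs in both cores (ordered by the first core's
    abundance ranking), ``unique_a`` / ``unique_b`` the IDs in exactly one
    (each in its own core's order); ``labels`` maps every involved ID to its
    taxonomy label.
    """

    set_a: CoreSet
    set_b: CoreSet
    shared: List[str] = field(default_factory=list)
    unique_a: List[str] = field(default_factory=list)
    unique_b: List[str] = field(default_factory=list)
    labels: Dict[str, str] = field(default_factory=dict)


def overlap(a: CoreSet, b: CoreSet) -> OverlapReport:
    """Partition two core sets into shared and unique members."""
    ids_a = a.member_ids
    ids_b = set(b.member_ids)
    shared = [o for o in ids_a if o in ids_b]
    unique_a = [o for o in ids_a if o not in ids_b]
    shared_set = set(shared)
    unique_b = [o for o in b.member_ids if o not in shared_set]
    labels: Dict[str, str] = {m.otu_id: m.taxonomy for m in b.members}
    labels.update({m.otu_id: m.taxonomy for m in a.members})
    return OverlapReport(
        set_a=a,
        set_b=b,
        shared=shared,
        unique_a=unique_a,
        unique_b=unique_b,
        labels=labels,
    )
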