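"""Plain-text I/O and in-memory containers for OTU abundance data.

Everything downstream operates on three structures defined here:

* :class:`AbundanceTable` — an OTU x sample matrix (pandas DataFrame) with a
  mode flag (``counts`` / ``proportion`` / ``percent``) and a sample-to-group
  map (e.g. forecrop ``W`` vs ``L``).
* :class:`Lineage` — one OTU's ordered taxonomy path, domain down to species.
* :class:`CoreSet` — the output of a core-microbiome definition method:
  member OTUs with their per-group summary abundance (percent scale), the
  method's parameters, and the summed core abundance.

All file formats are tab-separated text: abundance tables are row-per-OTU
with a sample-ID header, group maps and taxonomy maps are two-column TSV,
and core reports mirror the layout of published core-microbiome tables
(OTU ID, taxonomy, relative abundance to 4 decimals, optional SD, and a
footer with the total).
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "MODE_COUNTS",
    "MODE_PROPORTION",
    "MODE_PERCENT",
    "RANKS",
    "AbundanceTable",
    "Lineage",
    "CoreMember",
    "CoreSet",
    "natural_key",
    "parse_lineage",
    "read_abundance_table",
    "write_abundance_table",
    "read_group_map",
    "write_group_map",
    "read_taxonomy",
    "write_taxonomy",
    "read_core_report",
    "write_core_report",
]

MODE_COUNTS = "counts"
MODE_PROPORTION = "proportion"
MODE_PERCENT = "percent"
_MODES = (MODE_COUNTS, MODE_PROPORTION, MODE_PERCENT)

#: Canonical rank order used by positional (plain semicolon) lineages.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

_PREFIX_TO_RANK = {
    "d": "domain",
    "k": "domain",  # greengenes-style kingdom prefix
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}

_NUM_RE = re.compile(r"(\d+)")


def natural_key(identifier: str) -> Tuple:
    """Sort key treating digit runs numerically, so OTU2 < OTU10."""
    parts = _NUM_RE.split(str(identifier))
    return tuple(int(p) if p.isdigit() else p for p in parts)


# ---------------------------------------------------------------------------
# Lineage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Lineage:
    """Ordered taxonomy path for one OTU.

    ``ranks`` is a tuple of (rank-name, taxon-name) pairs ordered domain to
    species; empty taxon names mean "unclassified at that rank".  ``raw``
    keeps the original lineage string for exact-path matching.
    """

    otu_id: str
    ranks: Tuple[Tuple[str, str], ...]
    raw: str = ""

    def name(self, rank: str) -> str:
        for r, n in self.ranks:
            if r == rank:
                return n
        return ""

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(n for _, n in self.ranks)

    @property
    def path(self) -> str:
        """Semicolon path used for full-lineage pattern matching."""
        if self.raw:
            return self.raw
        return ";".join(self.names)

    @property
    def label(self) -> str:
        """Deepest classified taxon name, or 'Unclassified'."""
        for _, n in reversed(self.ranks):
            if n:
                return n
        return "Unclassified"

    @property
    def is_unclassified(self) -> bool:
        return all(not n for _, n in self.ranks)


def parse_lineage(otu_id: str, text: str, dialect: str = "plain_semicolon") -> Lineage:
    """Parse a semicolon lineage string into a :class:`Lineage`.

    ``plain_semicolon`` assigns ranks positionally domain -> species;
    ``rank_prefixed`` reads prefixes like ``g__Sphingomonas`` (greengenes /
    SILVA style), falling back to positional assignment for unprefixed
    segments.
    """
    if dialect not in ("plain_semicolon", "rank_prefixed"):
        raise ValueError(f"unknown taxonomy dialect: {dialect!r}")
    raw = text.strip()
    segments = [s.strip() for s in raw.split(";")] if raw else []
    assigned: Dict[str, str] = {r: "" for r in RANKS}
    pos = 0
    for seg in segments:
        rank = None
        name = seg
        if dialect == "rank_prefixed" and len(seg) >= 3 and seg[1:3] == "__":
            rank = _PREFIX_TO_RANK.get(seg[0])
            name = seg[3:].strip()
        if rank is None:
            if pos >= len(RANKS):
                break  # deeper than species: ignore
            rank = RANKS[pos]
        assigned[rank] = name
        pos = RANKS.index(rank) + 1
    ranks = tuple((r, assigned[r]) for r in RANKS)
    return Lineage(otu_id=otu_id, ranks=ranks, raw=raw)


# ---------------------------------------------------------------------------
# AbundanceTable
# ---------------------------------------------------------------------------

@dataclass
class AbundanceTable:
    """OTU x sample abundance matrix with a mode flag and group labels.

    ``data`` rows are OTUs (index) and columns are samples.  ``mode`` states
    the scale of the values; proportions must column-sum to 1 and percent to
    100.  ``groups`` maps every sample ID to a group label.
    """

    data: pd.DataFrame
    mode: str
    groups: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if not self.groups:
            self.groups = {s: "all" for s in self.data.columns}
        self.validate()

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown mode: {self.mode!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.duplicated().any():
            dupes = sorted(set(idx[idx.duplicated()]))
            raise ValueError(f"duplicate OTU IDs: {dupes}")
        if cols.duplicated().any():
            dupes = sorted(set(cols[cols.duplicated()]))
            raise ValueError(f"duplicate sample IDs: {dupes}")
        values = self.data.to_numpy()
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValueError(f"missing value at OTU {idx[r]!r}, sample {cols[c]!r}")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at OTU {idx[r]!r}, sample {cols[c]!r}"
            )
        missing = [s for s in cols if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        if self.mode in (MODE_PROPORTION, MODE_PERCENT) and len(idx):
            target = 1.0 if self.mode == MODE_PROPORTION else 100.0
            tol = 1e-9 if self.mode == MODE_PROPORTION else 1e-6
            sums = values.sum(axis=0)
            bad = np.abs(sums - target) > tol
            if bad.any():
                c = int(np.argmax(bad))
                raise ValueError(
                    f"sample {cols[c]!r} sums to {sums[c]!r}, expected {target} "
                    f"(mode={self.mode})"
                )

    # -- convenience -------------------------------------------------------

    @property
    def otu_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.columns)

    @property
    def n_otus(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def group_labels(self) -> List[str]:
        seen: List[str] = []
        for s in self.sample_ids:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen

    def samples_in(self, group: str) -> List[str]:
        hits = [s for s in self.sample_ids if self.groups[s] == group]
        if not hits:
            raise KeyError(f"unknown group label: {group!r}")
        return hits

    def subset_samples(self, samples: Sequence[str]) -> "AbundanceTable":
        return AbundanceTable(
            data=self.data[list(samples)].copy(),
            mode=self.mode,
            groups={s: self.groups[s] for s in samples},
        )

    def equals(self, other: "AbundanceTable", tol: float = 1e-9) -> bool:
        return (
            self.mode == other.mode
            and self.otu_ids == other.otu_ids
            and self.sample_ids == other.sample_ids
            and self.groups == other.groups
            and bool(np.allclose(self.data.to_numpy(), other.data.to_numpy(), atol=tol))
        )


def _infer_mode(values: np.ndarray) -> str:
    if values.size == 0:
        return MODE_COUNTS
    if np.allclose(values, np.round(values), atol=1e-12):
        return MODE_COUNTS
    sums = values.sum(axis=0)
    if np.allclose(sums, 1.0, atol=1e-6):
        return MODE_PROPORTION
    if np.allclose(sums, 100.0, atol=1e-4):
        return MODE_PERCENT
    # arbitrary non-negative weights (e.g. per-group mean-abundance tables)
    return MODE_COUNTS


def read_abundance_table(
    path: Union[str, Path],
    dialect: str = "otus_by_rows",
    groups: Union[None, str, Path, Mapping[str, str]] = None,
    mode: Optional[str] = None,
) -> AbundanceTable:
    """Read a row-per-OTU TSV abundance table.

    First column holds OTU IDs, the header row holds sample IDs, every body
    cell is numeric.  ``groups`` may be a sidecar two-column TSV path or a
    mapping; left out, every sample falls in a single group ``"all"``.
    ``mode`` overrides the best-effort inference (integers -> counts,
    column sums ~1 -> proportion, ~100 -> percent, otherwise counts).
    """
    if dialect != "otus_by_rows":
        raise ValueError(f"unknown abundance dialect: {dialect!r}")
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    dupes = {s for s in sample_ids if sample_ids.count(s) > 1}
    if dupes:
        raise ValueError(f"duplicate sample IDs in {path.name}: {sorted(dupes)}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell {raw.iat[r, c]!r} at OTU {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r} in {path.name}"
        )
    if raw.index.duplicated().any():
        dupes_o = sorted(set(raw.index[raw.index.duplicated()]))
        raise ValueError(f"duplicate OTU IDs in {path.name}: {dupes_o}")
    if isinstance(groups, (str, Path)):
        group_map = read_group_map(groups)
    elif groups is not None:
        group_map = dict(groups)
    else:
        group_map = {}
    inferred = mode or _infer_mode(numeric.to_numpy(dtype=float))
    return AbundanceTable(data=numeric, mode=inferred, groups=group_map)


def write_abundance_table(table: AbundanceTable, path: Union[str, Path]) -> None:
    df = table.data.copy()
    df.index.name = "OTU ID"
    df.to_csv(path, sep="\t")


def read_group_map(path: Union[str, Path]) -> Dict[str, str]:
    """Two-column TSV: sample_id <TAB> group label. '#' lines are comments."""
    out: Dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"group map line without a group: {line!r}")
        sample, group = fields[0], fields[1]
        if sample in out:
            raise ValueError(f"duplicate sample in group map: {sample!r}")
        out[sample] = group
    return out


def write_group_map(groups: Mapping[str, str], path: Union[str, Path]) -> None:
    with Path(path).open("w") as fh:
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------------------
# Taxonomy maps
# ---------------------------------------------------------------------------

def read_taxonomy(
    path: Union[str, Path],
    dialect: str = "plain_semicolon",
    table: Optional[AbundanceTable] = None,
    missing: str = "warn",
) -> Dict[str, Lineage]:
    """Read a two-column TSV mapping otu_id -> lineage string.

    When ``table`` is given, OTUs present in the table but absent from the
    file get an all-empty "Unclassified" lineage with a warning
    (``missing="warn"``) or raise (``missing="error"``).
    """
    if missing not in ("warn", "error"):
        raise ValueError(f"missing must be 'warn' or 'error', got {missing!r}")
    out: Dict[str, Lineage] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        otu_id = fields[0].strip()
        lineage_text = fields[1] if len(fields) > 1 else ""
        out[otu_id] = parse_lineage(otu_id, lineage_text, dialect=dialect)
    if table is not None:
        absent = [o for o in table.otu_ids if o not in out]
        if absent:
            if missing == "error":
                raise ValueError(f"OTUs missing from taxonomy: {absent}")
            warnings.warn(
                f"{len(absent)} OTUs missing from taxonomy; treated as Unclassified",
                stacklevel=2,
            )
            for o in absent:
                out[o] = parse_lineage(o, "")
    return out


def write_taxonomy(lineages: Mapping[str, Lineage], path: Union[str, Path]) -> None:
    with Path(path).open("w") as fh:
        for otu_id, lin in lineages.items():
            fh.write(f"{otu_id}\t{lin.path}\n")


# ---------------------------------------------------------------------------
# CoreSet and reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoreMember:
    otu_id: str
    taxonomy: str
    mean_ra: float  # percent scale
    sd_ra: Optional[float] = None  # percent scale; None for membership cores


@dataclass
class CoreSet:
    """Result of one core-microbiome definition method for one group.

    Members are kept sorted by summary abundance descending, ties broken by
    natural OTU-ID order; ``total_core_abundance`` is their sum on the
    percent scale.
    """

    method: str  # membership | composition | functional
    group: str
    members: Tuple[CoreMember, ...]
    params: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.members = tuple(
            sorted(self.members, key=lambda m: (-m.mean_ra, natural_key(m.otu_id)))
        )

    @property
    def member_ids(self) -> List[str]:
        return [m.otu_id for m in self.members]

    @property
    def total_core_abundance(self) -> float:
        return float(sum(m.mean_ra for m in self.members))

    def __len__(self) -> int:
        return len(self.members)


def write_core_report(core: CoreSet, path: Union[str, Path]) -> None:
    """Write a core-microbiome report mirroring published core tables.

    Columns: OTU ID, Taxonomy, Relative Abundance (4 decimals), SD (blank
    for the membership method); footer row carries the summed abundance.
    """
    params = " ".join(f"{k}={v}" for k, v in core.params.items())
    lines = [f"# method={core.method} group={core.group} {params}".rstrip()]
    lines.append("OTU ID\tTaxonomy\tRelative Abundance\tSD")
    for m in core.members:
        sd = "" if m.sd_ra is None else f"{m.sd_ra:.4f}"
        lines.append(f"{m.otu_id}\t{m.taxonomy}\t{m.mean_ra:.4f}\t{sd}")
    lines.append(f"Total\t\t{core.total_core_abundance:.4f}\t")
    Path(path).write_text("\n".join(lines) + "\n")


def read_core_report(path: Union[str, Path]) -> CoreSet:
    """Parse a report written by :func:`write_core_report` back to a CoreSet."""
    text = Path(path).read_text().splitlines()
    method, group, params = "membership", "", {}
    members: List[CoreMember] = []
    for line in text:
        if line.startswith("#"):
            tokens = line[1:].split()
            kv = dict(t.split("=", 1) for t in tokens if "=" in t)
            method = kv.pop("method", method)
            group = kv.pop("group", group)
            params = {k: _coerce(v) for k, v in kv.items()}
            continue
        if not line.strip() or line.startswith("OTU ID"):
            continue
        fields = line.split("\t")
        if fields[0] == "Total":
            continue
        otu_id, taxonomy, mean_ra = fields[0], fields[1], float(fields[2])
        sd = float(fields[3]) if len(fields) > 3 and fields[3] != "" else None
        members.append(CoreMember(otu_id, taxonomy, mean_ra, sd))
    return CoreSet(method=method, group=group, members=tuple(members), params=params)


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value
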