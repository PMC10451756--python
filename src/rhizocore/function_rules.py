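"""Rule-based taxonomy-to-function assignment (FAPROTAX-style).

A rule file maps ecological functions (nitrification, nitrogen fixation,
chemoheterotrophy, ...) to taxon patterns.  The flat-file dialect follows
the FAPROTAX convention: an unindented header line opens a function
(name, then free-text metadata), each following indented line carries one
taxon pattern, ``#`` starts a comment, and a pattern of the form
``add_group:other_function`` includes all of another function's clauses
(resolved acyclically).

Patterns are case-sensitive and support a greedy ``*`` wildcard; a pattern
matches an OTU when it matches the full semicolon lineage path or any
single rank name.  OTUs with a wholly unclassified lineage are never
assigned — rule databases describe characterised strains, so only
identified taxa participate in the functional core.

Per-group functional profiles report, for each function, the percentage of
the group's *detected* OTUs assigned to it (presence-based, independent of
abundance); two groups' percentages are compared with Fisher's exact test
on the 2x2 assignment counts (a two-proportion z-test is available as an
option).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

from scipy import stats

from .tables_io import AbundanceTable, Lineage

__all__ = [
    "FunctionRule",
    "FunctionalProfile",
    "ProportionComparison",
    "parse_rules",
    "parse_rules_text",
    "bundled_rules",
    "clause_matches",
    "assign_functions",
    "functional_profile",
    "compare_groups",
    "write_profile",
    "write_comparisons",
]

_INCLUDE_PREFIX = "add_group:"


class RuleParseError(ValueError):
    pass


@dataclass(frozen=True)
class FunctionRule:
    """One ecological function with its taxon-matching clauses."""

    name: str
    clauses: Tuple[str, ...]
    metadata: str = ""


def parse_rules(path: Union[str, Path]) -> List[FunctionRule]:
    """Parse a FAPROTAX-style flat rule file."""
    return parse_rules_text(Path(path).read_text())


def parse_rules_text(text: str) -> List[FunctionRule]:
    raw: List[Tuple[str, str, List[str]]] = []  # (name, metadata, patterns)
    current: Optional[Tuple[str, str, List[str]]] = None

    def close(entry):
        if entry is None:
            return
        if not entry[2]:
            warnings.warn(f"rule {entry[0]!r} has no clauses; dropped", stacklevel=3)
            return
        raw.append(entry)

    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if line[0] in " \t":  # continuation: one taxon pattern
            if current is None:
                raise RuleParseError(
                    f"line {lineno}: clause before any function header"
                )
            pattern = stripped.split("\t")[0].strip()
            if pattern:
                current[2].append(pattern)
            continue
        close(current)
        fields = line.rstrip("\n").split("\t")
        if len(fields) == 1:
            fields = line.split(None, 1)
        name = fields[0].strip()
        metadata = fields[1].strip() if len(fields) > 1 else ""
        current = (name, metadata, [])
    close(current)

    names = [r[0] for r in raw]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise RuleParseError(f"duplicate function names: {sorted(dupes)}")
    return _resolve_includes(raw)


def _resolve_includes(raw) -> List[FunctionRule]:
    by_name = {name: (metadata, patterns) for name, metadata, patterns in raw}
    resolved: Dict[str, Tuple[str, ...]] = {}

    def expand(name: str, stack: Tuple[str, ...]) -> Tuple[str, ...]:
        if name in resolved:
            return resolved[name]
        if name in stack:
            cycle = " -> ".join(stack + (name,))
            raise RuleParseError(f"cyclic include: {cycle}")
        if name not in by_name:
            raise RuleParseError(f"include of undefined function {name!r}")
        clauses: List[str] = []
        for pattern in by_name[name][1]:
            if pattern.startswith(_INCLUDE_PREFIX):
                target = pattern[len(_INCLUDE_PREFIX):].strip()
                for c in expand(target, stack + (name,)):
                    if c not in clauses:
                        clauses.append(c)
            elif pattern not in clauses:
                clauses.append(pattern)
        resolved[name] = tuple(clauses)
        return resolved[name]

    return [
        FunctionRule(name=name, clauses=expand(name, ()), metadata=metadata)
        for name, metadata, _ in raw
    ]


def bundled_rules() -> List[FunctionRule]:
    """The small rule set shipped with the package (no download needed).

    Covers the functions and taxa relevant to wheat rhizosphere communities:
    chemoheterotrophy, fermentation, the nitrogen-cycle functions, lytic
    activities and aromatic-compound degradation.
    """
    text = (
        resources.files("rhizocore").joinpath("data/mini_faprotax.txt").read_text()
    )
    return parse_rules_text(text)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def _pattern_regex(pattern: str) -> re.Pattern:
    return re.compile(".*".join(re.escape(p) for p in pattern.split("*")))


def clause_matches(pattern: str, lineage: Lineage) -> bool:
    """True when the wildcard pattern matches the full path or any rank name."""
    rx = _pattern_regex(pattern)
    if rx.fullmatch(lineage.path):
        return True
    return any(n and rx.fullmatch(n) for n in lineage.names)


def assign_functions(
    lineages: Mapping[str, Lineage],
    rules: Sequence[FunctionRule],
) -> Dict[str, Set[str]]:
    """Assign every OTU the set of functions with >= 1 matching clause.

    Functions are not mutually exclusive; wholly unclassified OTUs get the
    empty set regardless of the rules.
    """
    compiled = [
        (rule.name, [_pattern_regex(c) for c in rule.clauses]) for rule in rules
    ]
    out: Dict[str, Set[str]] = {}
    for otu_id, lineage in lineages.items():
        if lineage.is_unclassified:
            out[otu_id] = set()
            continue
        targets = [lineage.path] + [n for n in lineage.names if n]
        out[otu_id] = {
            name
            for name, rxs in compiled
            if any(rx.fullmatch(t) for rx in rxs for t in targets)
        }
    return out


# ---------------------------------------------------------------------------
# Profiles and comparison
# ---------------------------------------------------------------------------

@dataclass
class FunctionalProfile:
    """Per-group functional profile: % of detected OTUs assigned per function."""

    group: str
    total_otus: int
    per_function: Dict[str, Tuple[int, float]] = field(default_factory=dict)

    def n_assigned(self, function_name: str) -> int:
        return self.per_function.get(function_name, (0, 0.0))[0]

    def pct(self, function_name: str) -> float:
        return self.per_function.get(function_name, (0, 0.0))[1]


@dataclass(frozen=True)
class ProportionComparison:
    function_name: str
    group_a: str
    group_b: str
    n_a: int
    total_a: int
    n_b: int
    total_b: int
    p_value: float
    test: str = "fisher"


def functional_profile(
    table: AbundanceTable,
    group: str,
    assignments: Mapping[str, Set[str]],
    functions: Optional[Sequence[str]] = None,
) -> FunctionalProfile:
    """Percentage of the group's detected OTUs assigned to each function.

    An OTU is *detected* when its abundance is > 0 in at least one of the
    group's samples; the percentages depend only on detection, never on the
    abundance values.  ``functions`` fixes the reported function universe
    (default: every function appearing in ``assignments``).
    """
    samples = table.samples_in(group)
    sub = table.data[samples]
    detected = [o for o in table.otu_ids if (sub.loc[o] > 0).any()]
    total = len(detected)
    if total == 0:
        raise ValueError(f"no OTUs detected in group {group!r}")
    if functions is None:
        functions = sorted({f for s in assignments.values() for f in s})
    per_function: Dict[str, Tuple[int, float]] = {}
    for fn in functions:
        n = sum(1 for o in detected if fn in assignments.get(o, ()))
        per_function[fn] = (n, 100.0 * n / total)
    return FunctionalProfile(group=group, total_otus=total, per_function=per_function)


def compare_groups(
    profile_a: FunctionalProfile,
    profile_b: FunctionalProfile,
    function_name: str,
    test: str = "fisher",
) -> ProportionComparison:
    """Two-sided test of equal assignment proportions between two groups.

    Default is Fisher's exact test on the 2x2 table of (assigned,
    not-assigned) counts per group; ``test="ztest"`` uses the pooled
    two-proportion z approximation instead.  A function absent from a
    profile counts as 0 assigned.
    """
    n_a, total_a = profile_a.n_assigned(function_name), profile_a.total_otus
    n_b, total_b = profile_b.n_assigned(function_name), profile_b.total_otus
    if total_a == 0 or total_b == 0:
        raise ValueError("both groups need a nonzero detected-OTU total")
    if test == "fisher":
        _, p = stats.fisher_exact(
            [[n_a, total_a - n_a], [n_b, total_b - n_b]], alternative="two-sided"
        )
    elif test == "ztest":
        p = _two_proportion_z(n_a, total_a, n_b, total_b)
    else:
        raise ValueError(f"unknown test: {test!r}")
    return ProportionComparison(
        function_name=function_name,
        group_a=profile_a.group,
        group_b=profile_b.group,
        n_a=n_a,
        total_a=total_a,
        n_b=n_b,
        total_b=total_b,
        p_value=float(p),
        test=test,
    )


def _two_proportion_z(n_a: int, total_a: int, n_b: int, total_b: int) -> float:
    pooled = (n_a + n_b) / (total_a + total_b)
    se = (pooled * (1 - pooled) * (1 / total_a + 1 / total_b)) ** 0.5
    if se == 0:
        return 1.0
    z = (n_a / total_a - n_b / total_b) / se
    return float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# TSV output
# ---------------------------------------------------------------------------

def write_profile(profile: FunctionalProfile, path: Union[str, Path]) -> None:
    lines = ["function\tgroup\tn_assigned\ttotal\tpct"]
    for fn, (n, pct) in profile.per_function.items():
        lines.append(f"{fn}\t{profile.group}\t{n}\t{profile.total_otus}\t{pct:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_comparisons(
    comparisons: Iterable[ProportionComparison], path: Union[str, Path]
) -> None:
    lines = [
        "function\tgroup_a\tn_a\ttotal_a\tgroup_b\tn_b\ttotal_b\tp_value\ttest"
    ]
    for c in comparisons:
        lines.append(
            f"{c.function_name}\t{c.group_a}\t{c.n_a}\t{c.total_a}\t"
            f"{c.group_b}\t{c.n_b}\t{c.total_b}\t{c.p_value:.6g}\t{c.test}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
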