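"""End-to-end orchestration: normalise, cores, functions, overlaps, summary.

:func:`run_pipeline` takes a :class:`RunConfig` (buildable from YAML),
runs the full analysis sequence and writes per-group membership and
composition core reports, functional profiles, pairwise overlap reports
and a machine-readable ``summary.json`` into the output directory.  Any
stage failure raises :class:`PipelineError` naming the stage; nothing
partial is reported as success.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Dict, List, Optional, Union

import yaml

from . import core_methods, function_rules, tables_io
from .abundance import to_relative

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("rhizocore")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Inputs, method parameters and output location for one pipeline run."""

    abundance: Path
    out_dir: Path
    groups: Optional[Path] = None
    taxonomy: Optional[Path] = None
    rules: Optional[Path] = None  # None -> bundled mini rule set
    taxonomy_dialect: str = "plain_semicolon"
    mode: Optional[str] = None  # override abundance-mode inference
    top_n: int = 10
    sd_threshold: float = 0.01
    threshold_scale: str = "percent"
    sd_ddof: int = 1
    presence_epsilon: float = 0.0
    test: str = "fisher"
    log_level: str = "INFO"
    timestamp: bool = False  # header timestamps off -> byte-identical reruns
    seed: int = 0

    def __post_init__(self) -> None:
        self.abundance = Path(self.abundance)
        self.out_dir = Path(self.out_dir)
        for name in ("groups", "taxonomy", "rules"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be > 0")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                log.error("stage %s failed: %s", name, exc)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.3fs", name, time.perf_counter() - t0)
            return result
        return wrapper
    return deco


@_stage("load")
def _load(config: RunConfig):
    table = tables_io.read_abundance_table(
        config.abundance, groups=config.groups, mode=config.mode
    )
    if table.n_otus == 0 or table.n_samples == 0:
        raise ValueError("abundance table is empty")
    taxonomy = None
    if config.taxonomy is not None:
        taxonomy = tables_io.read_taxonomy(
            config.taxonomy, dialect=config.taxonomy_dialect, table=table
        )
    return table, taxonomy


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Run the full analysis and return (and write) the run summary."""
    logging.basicConfig(level=config.log_level)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    table, taxonomy = _load(config)
    rel = _stage("normalize")(to_relative)(table)
    groups = rel.group_labels()

    summary: Dict[str, object] = {
        "groups": groups,
        "n_otus": rel.n_otus,
        "params": {
            "top_n": config.top_n,
            "sd_threshold": config.sd_threshold,
            "threshold_scale": config.threshold_scale,
            "sd_ddof": config.sd_ddof,
            "presence_epsilon": config.presence_epsilon,
            "test": config.test,
        },
        "cores": {},
        "overlaps": {},
        "functions": {},
    }
    if config.timestamp:
        summary["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")

    cores: Dict[str, Dict[str, tables_io.CoreSet]] = {"membership": {}, "composition": {}}
    for g in groups:
        mem = _stage(f"membership[{g}]")(core_methods.membership_core)(
            rel,
            g,
            top_n=config.top_n,
            taxonomy=taxonomy,
            presence_epsilon=config.presence_epsilon,
            sd_ddof=config.sd_ddof,
        )
        cores["membership"][g] = mem
        tables_io.write_core_report(mem, out / f"membership_{g}.tsv")
        comp = _stage(f"composition[{g}]")(core_methods.composition_core)(
            rel,
            g,
            sd_threshold=config.sd_threshold,
            threshold_scale=config.threshold_scale,
            taxonomy=taxonomy,
            presence_epsilon=config.presence_epsilon,
            sd_ddof=config.sd_ddof,
        )
        cores["composition"][g] = comp
        tables_io.write_core_report(comp, out / f"composition_{g}.tsv")
        for method in ("membership", "composition"):
            core = cores[method][g]
            summary["cores"][f"{method}_{g}"] = {
                "n_members": len(core),
                "total_core_abundance": round(core.total_core_abundance, 6),
                "members": core.member_ids,
            }

    # overlaps: membership across groups, and methods within each group
    pairs = [
        (f"membership_{a}_vs_membership_{b}", cores["membership"][a], cores["membership"][b])
        for a, b in combinations(groups, 2)
    ] + [
        (f"membership_{g}_vs_composition_{g}", cores["membership"][g], cores["composition"][g])
        for g in groups
    ]
    for name, a, b in pairs:
        rep = _stage(f"overlap[{name}]")(core_methods.overlap)(a, b)
        _write_overlap(rep, out / f"overlap_{name}.tsv")
        summary["overlaps"][name] = {
            "shared": rep.shared,
            "unique_a": rep.unique_a,
            "unique_b": rep.unique_b,
        }

    if taxonomy is not None:
        rules = _stage("rules")(
            lambda: function_rules.parse_rules(config.rules)
            if config.rules
            else function_rules.bundled_rules()
        )()
        assignments = _stage("assign")(function_rules.assign_functions)(taxonomy, rules)
        functions = [r.name for r in rules]
        profiles = {}
        for g in groups:
            prof = _stage(f"profile[{g}]")(function_rules.functional_profile)(
                rel, g, assignments, functions=functions
            )
            profiles[g] = prof
            function_rules.write_profile(prof, out / f"functional_profile_{g}.tsv")
            summary["functions"][g] = {
                "total_otus": prof.total_otus,
                "pct": {fn: round(prof.pct(fn), 4) for fn in functions},
            }
        comparisons: List[function_rules.ProportionComparison] = []
        for a, b in combinations(groups, 2):
            for fn in functions:
                comparisons.append(
                    function_rules.compare_groups(
                        profiles[a], profiles[b], fn, test=config.test
                    )
                )
        if comparisons:
            function_rules.write_comparisons(comparisons, out / "comparisons.tsv")
            summary["functions"]["comparisons"] = [
                {
                    "function": c.function_name,
                    "groups": [c.group_a, c.group_b],
                    "p_value": c.p_value,
                }
                for c in comparisons
            ]

    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary


def _write_overlap(report: core_methods.OverlapReport, path: Path) -> None:
    lines = ["section\totu_id\ttaxonomy"]
    for section, ids in (
        ("shared", report.shared),
        ("unique_a", report.unique_a),
        ("unique_b", report.unique_b),
    ):
        for o in ids:
            lines.append(f"{section}\t{o}\t{report.labels.get(o, o)}")
    path.write_text("\n".join(lines) + "\n")
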