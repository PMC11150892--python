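"""Event-log abstraction: renaming, subprocess collapsing, exclusion, coverage.

Raw care-record event logs are noisy at the stage level — duplicated stage
names with minor spelling variants, fine-grained treatment stages, and
administrative events (waiting-list joins, step-intensity changes) that
carry no extra information for flow analysis.  An :class:`AbstractionSpec`
declares how to simplify a log:

1. ``rename_map`` — canonicalise duplicated stage names;
2. ``subprocess_groups`` — replace each maximal run of *consecutive*
   events belonging to one subprocess by a single event labelled with the
   subprocess name and carrying the run's first timestamp;
3. ``exclusions`` — drop administrative stages;
4. coverage filtering — keep only the cases on the most frequent routes
   until a target fraction of cases is covered.

Two abstraction levels are packaged: level A keeps individual treatment
stages and drops waiting lists (the process-map view); level B pools
treatments into step-level subprocesses and keeps waiting lists (the
route-analysis view).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import stages as st
from .eventlog import EventLog
from .synthlog import RAW_NAMES


@dataclass
class AbstractionSpec:
    name: str
    rename_map: dict[str, str] = field(default_factory=dict)
    subprocess_groups: dict[str, set[str]] = field(default_factory=dict)
    exclusions: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for group, members in self.subprocess_groups.items():
            for label in members:
                if label in seen:
                    raise ValueError(
                        f"label {label!r} maps into both {seen[label]!r} and {group!r}")
                seen[label] = group
        bad = self.exclusions & set(self.subprocess_groups)
        if bad:
            raise ValueError(f"exclusions overlap subprocess outputs: {sorted(bad)}")

    @property
    def member_to_group(self) -> dict[str, str]:
        return {m: g for g, ms in self.subprocess_groups.items() for m in ms}

    @classmethod
    def from_yaml(cls, path_or_text) -> "AbstractionSpec":
        if isinstance(path_or_text, str) and "\n" in path_or_text:
            data = yaml.safe_load(path_or_text)
        else:
            with open(path_or_text) as fh:
                data = yaml.safe_load(fh)
        return cls(
            name=data["name"],
            rename_map=dict(data.get("rename_map", {})),
            subprocess_groups={k: set(v) for k, v in data.get("subprocess_groups", {}).items()},
            exclusions=set(data.get("exclusions", [])),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump({
            "name": self.name,
            "rename_map": dict(sorted(self.rename_map.items())),
            "subprocess_groups": {k: sorted(v) for k, v in sorted(self.subprocess_groups.items())},
            "exclusions": sorted(self.exclusions),
        }, sort_keys=False)


def _canonical_rename_map() -> dict[str, str]:
    """Map every raw stage-name variant onto its canonical label."""
    return {raw: canon for canon, raws in RAW_NAMES.items() for raw in raws}


def level_a_spec() -> AbstractionSpec:
    """Packaged level A: canonical names, discharge collapsed, waitlists excluded."""
    ref = importlib.resources.files("careflow.data") / "abstraction_a.yaml"
    return AbstractionSpec.from_yaml(ref.read_text())


def level_b_spec() -> AbstractionSpec:
    """Packaged level B: treatments pooled per step, waitlists retained."""
    ref = importlib.resources.files("careflow.data") / "abstraction_b.yaml"
    return AbstractionSpec.from_yaml(ref.read_text())


def get_spec(level: str) -> AbstractionSpec:
    if level.upper() == "A":
        return level_a_spec()
    if level.upper() == "B":
        return level_b_spec()
    return AbstractionSpec.from_yaml(level)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def remap_stages(log: EventLog, spec: AbstractionSpec) -> EventLog:
    """Replace every activity by its rename-map image (identity if absent)."""
    out = log.copy()
    out.events["activity"] = out.events["activity"].map(
        lambda a: spec.rename_map.get(a, a))
    return out


def collapse_subprocesses(log: EventLog, spec: AbstractionSpec) -> EventLog:
    """Collapse maximal runs of consecutive same-subprocess events.

    Each run becomes one event labelled with the subprocess name and
    stamped with the run's *first* timestamp (the subprocess entry time),
    so the duration to the following stage spans the whole subprocess.
    Idempotent; never increases the event count.
    """
    member = spec.member_to_group
    if not member:
        return log.copy()
    ev = log.events.sort_values(["case_id", "source_order"])
    group = ev["activity"].map(lambda a: member.get(a))
    label = group.fillna(ev["activity"])
    # a new run starts when the case changes or the (group-or-activity) label changes;
    # consecutive non-member events with equal labels must NOT merge
    new_case = ev["case_id"] != ev["case_id"].shift()
    new_label = label != label.shift()
    is_member = group.notna()
    run_id = (new_case | new_label | ~is_member).cumsum()
    first = ev.groupby(run_id, sort=False).head(1).copy()
    first["activity"] = label.loc[first.index].values
    first["source_order"] = first.groupby("case_id").cumcount()
    out = log.copy()
    out.events = first.reset_index(drop=True)
    return out


def exclude_stages(log: EventLog, spec: AbstractionSpec) -> tuple[EventLog, int]:
    """Remove events with excluded activities; drop cases left empty.

    Returns ``(filtered log, number of cases dropped empty)``.
    """
    ev = log.events[~log.events["activity"].isin(spec.exclusions)].copy()
    surviving = set(ev["case_id"])
    dropped = int(log.cases["case_id"].nunique() - len(surviving & set(log.cases["case_id"])))
    ev["source_order"] = ev.sort_values(["case_id", "source_order"]).groupby("case_id").cumcount()
    out = log.restrict(surviving)
    ev = ev.sort_values(["case_id", "source_order"]).reset_index(drop=True)
    out.events = ev
    return out, dropped


def filter_by_coverage(log: EventLog, coverage: float) -> tuple[EventLog, int]:
    """Keep the cases on the most frequent routes up to a coverage level.

    Routes are ranked by descending case count (ties broken
    lexicographically by route string); routes are retained in rank order
    until the cumulative retained fraction first reaches ``coverage``,
    including the route that crosses the threshold.  Returns the
    restricted log and the retained case count.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError(f"coverage must lie in (0, 1], got {coverage}")
    routes = log.case_routes()
    total = len(routes)
    if total == 0:
        return log.copy(), 0
    counts = routes.value_counts()
    order = sorted(counts.index, key=lambda r: (-counts[r], r))
    kept_routes, cum = [], 0
    for r in order:
        kept_routes.append(r)
        cum += int(counts[r])
        if cum / total >= coverage:
            break
    keep_set = set(kept_routes)
    keep_cases = routes[routes.isin(keep_set)].index
    return log.restrict(keep_cases), len(keep_cases)


@dataclass
class AbstractionSummary:
    level: str
    n_stages: int
    n_routes: int
    n_cases: int
    n_cases_dropped_empty: int
    coverage: float
    n_cases_retained: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def apply_abstraction(log: EventLog, spec: AbstractionSpec,
                      coverage: float = 1.0) -> tuple[EventLog, AbstractionSummary]:
    """Full abstraction: rename → collapse → exclude → coverage filter.

    Exclusion runs after collapsing so administrative events cannot split
    a subprocess run in two.  Returns the abstracted log plus a summary of
    distinct stages and routes (computed before coverage filtering, on the
    processed log) and of the coverage cut.
    """
    out = remap_stages(log, spec)
    out = collapse_subprocesses(out, spec)
    out, dropped = exclude_stages(out, spec)
    n_stages = int(out.events["activity"].nunique())
    n_routes = int(out.case_routes().nunique())
    out, retained = filter_by_coverage(out, coverage)
    summary = AbstractionSummary(
        level=spec.name, n_stages=n_stages, n_routes=n_routes,
        n_cases=int(log.cases["case_id"].nunique()),
        n_cases_dropped_empty=dropped, coverage=coverage,
        n_cases_retained=retained,
    )
    return out, summary
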