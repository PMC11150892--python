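"""Directly-follows graph mining, performance annotation, and DOT export.

The directly-follows graph (DFG) is the descriptive backbone of the
pipeline: nodes are pathway stages, an edge (a, b) counts how often stage
b immediately follows stage a within a case.  Edges carry traversal
counts, distinct-case counts, branching probabilities, and transition
duration statistics (median/IQR, weeks); nodes carry case counts and
stage-duration statistics (time from entering the stage to the next
event).  A per-edge bottleneck score — distinct cases crossing the edge
times the median transition duration — flags edges that are both highly
travelled and slow.

Branching probabilities are computed over *traversals*, with end-of-trace
treated as an implicit sink, so the probabilities out of any node
(including its end-of-trace share) sum to one.  Repeat visits contribute
one traversal each but a single distinct case; the bottleneck score uses
distinct cases ("number of patients"), branching probabilities use
traversals.  Both statistics are exposed on every edge.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .eventlog import EventLog, WEEK

_Q = dict(method="linear")  # linear-interpolation quantiles throughout


def _median_iqr(values: np.ndarray) -> tuple[float, float, float]:
    if len(values) == 0:
        return (float("nan"),) * 3
    return (
        float(np.percentile(values, 50, **_Q)),
        float(np.percentile(values, 25, **_Q)),
        float(np.percentile(values, 75, **_Q)),
    )


@dataclass
class NodeStats:
    label: str
    n_cases: int = 0
    n_traversals: int = 0
    n_starts: int = 0
    n_ends: int = 0
    median_duration_weeks: float = float("nan")
    q1_duration_weeks: float = float("nan")
    q3_duration_weeks: float = float("nan")


@dataclass
class EdgeStats:
    source: str
    target: str
    n_traversals: int = 0
    n_cases: int = 0
    probability: float = 0.0
    median_weeks: float = float("nan")
    q1_weeks: float = float("nan")
    q3_weeks: float = float("nan")
    bottleneck_score: float = float("nan")
    bottleneck: bool = False
    attrition: bool = False       # discharge before the intended assessment/treatment
    step_up: bool = False         # low- to high-intensity transition


@dataclass
class ProcessMap:
    """Annotated directly-follows graph of one event log."""

    nodes: dict[str, NodeStats] = field(default_factory=dict)
    edges: dict[tuple[str, str], EdgeStats] = field(default_factory=dict)
    total_cases: int = 0
    coverage_used: float = 1.0
    bottleneck_percentile: float | None = None

    def out_traversals(self, node: str) -> int:
        """Total outgoing traversals including the implicit end-of-trace sink."""
        out = sum(e.n_traversals for (a, _), e in self.edges.items() if a == node)
        return out + self.nodes[node].n_ends

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(total_cases=self.total_cases, coverage_used=self.coverage_used)
        for label, ns in self.nodes.items():
            g.add_node(label, **asdict(ns))
        for (a, b), es in self.edges.items():
            g.add_edge(a, b, **asdict(es))
        return g

    def to_json(self) -> str:
        payload = {
            "total_cases": self.total_cases,
            "coverage_used": self.coverage_used,
            "bottleneck_percentile": self.bottleneck_percentile,
            "nodes": {k: asdict(v) for k, v in sorted(self.nodes.items())},
            "edges": {f"{a} -> {b}": asdict(e) for (a, b), e in sorted(self.edges.items())},
        }
        return json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)


def mine_dfg(log: EventLog) -> ProcessMap:
    """Mine the directly-follows graph of an event log.

    Requires per-case non-decreasing timestamps in source order (repair
    first if needed).  An empty log yields an empty map.
    """
    pmap = ProcessMap(total_cases=int(log.events["case_id"].nunique()))
    if len(log.events) == 0:
        return pmap

    ev = log.events.sort_values(["case_id", "source_order"])
    node_durations: dict[str, list[float]] = {}
    edge_durations: dict[tuple[str, str], list[float]] = {}
    edge_cases: dict[tuple[str, str], set[str]] = {}

    for cid, grp in ev.groupby("case_id", sort=True):
        acts = grp["activity"].tolist()
        times = grp["timestamp"].tolist()
        for a in set(acts):
            pmap.nodes.setdefault(a, NodeStats(label=a)).n_cases += 1
        for a in acts:
            pmap.nodes[a].n_traversals += 1
        pmap.nodes[acts[0]].n_starts += 1
        pmap.nodes[acts[-1]].n_ends += 1
        for i in range(len(acts) - 1):
            a, b = acts[i], acts[i + 1]
            dur = (times[i + 1] - times[i]) / WEEK
            key = (a, b)
            es = pmap.edges.setdefault(key, EdgeStats(source=a, target=b))
            es.n_traversals += 1
            edge_durations.setdefault(key, []).append(dur)
            edge_cases.setdefault(key, set()).add(cid)
            node_durations.setdefault(a, []).append(dur)

    for label, ns in pmap.nodes.items():
        med, q1, q3 = _median_iqr(np.asarray(node_durations.get(label, []), dtype=float))
        ns.median_duration_weeks, ns.q1_duration_weeks, ns.q3_duration_weeks = med, q1, q3

    for key, es in pmap.edges.items():
        es.n_cases = len(edge_cases[key])
        med, q1, q3 = _median_iqr(np.asarray(edge_durations[key], dtype=float))
        es.median_weeks, es.q1_weeks, es.q3_weeks = med, q1, q3

    for key, es in pmap.edges.items():
        es.probability = es.n_traversals / pmap.out_traversals(key[0])
    return pmap


def score_bottlenecks(pmap: ProcessMap, percentile: float = 0.99) -> ProcessMap:
    """Score every edge and flag the top-percentile bottlenecks.

    Score = distinct cases crossing the edge × median transition duration
    (weeks).  Edges whose score reaches the given quantile of all edge
    scores are flagged; zero-score edges are never flagged.  The flag set
    is invariant under uniform rescaling of all durations.
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError(f"percentile must lie in (0, 1), got {percentile}")
    pmap.bottleneck_percentile = percentile
    scores = {}
    for key, es in pmap.edges.items():
        med = 0.0 if np.isnan(es.median_weeks) else es.median_weeks
        scores[key] = es.n_cases * med
    if scores:
        threshold = float(np.quantile(np.array(list(scores.values())), percentile, **_Q))
        for key, es in pmap.edges.items():
            es.bottleneck_score = scores[key]
            es.bottleneck = bool(scores[key] >= threshold and scores[key] > 0)
    return pmap


def annotate_semantics(pmap: ProcessMap, stage_roles: dict[str, frozenset[str] | set[str]]) -> ProcessMap:
    """Mark waiting-list-attrition and step-up edges from stage roles.

    An edge from a ``waitlist``-role stage into a ``discharge``-role stage
    is attrition (discharge before the intended assessment or treatment);
    an edge from a ``step2``-role stage into a ``step3``-role stage is a
    step-up.  Raises KeyError if a map stage has no role entry.
    """
    for label in pmap.nodes:
        if label not in stage_roles:
            raise KeyError(f"no role defined for stage {label!r}")
    for (a, b), es in pmap.edges.items():
        ra, rb = set(stage_roles[a]), set(stage_roles[b])
        es.attrition = "waitlist" in ra and "discharge" in rb
        es.step_up = "step2" in ra and "step3" in rb
    return pmap


def _fmt(x: float, dp: int = 1) -> str:
    return "n/a" if x != x else f"{x:.{dp}f}"


def export_dot(pmap: ProcessMap, bottleneck_color: str = "red") -> str:
    """Deterministic DOT rendering of an annotated process map.

    Node labels carry case counts and median stage duration; edge labels
    carry traversal counts, branching probability, and median wait.
    Bottleneck-flagged edges are coloured; attrition and step-up edges are
    marked in their labels.
    """
    lines = ["digraph process_map {", "  rankdir=TB;",
             '  node [shape=box, style=rounded];']
    for label in sorted(pmap.nodes):
        ns = pmap.nodes[label]
        text = f"{label}\\ncases={ns.n_cases} med={_fmt(ns.median_duration_weeks)}wk"
        lines.append(f'  "{label}" [label="{text}"];')
    for a, b in sorted(pmap.edges):
        es = pmap.edges[(a, b)]
        marks = ""
        if es.attrition:
            marks += " [attrition]"
        if es.step_up:
            marks += " [step-up]"
        text = (f"n={es.n_traversals} p={100 * es.probability:.1f}% "
                f"med={_fmt(es.median_weeks)}wk{marks}")
        attrs = [f'label="{text}"']
        if es.bottleneck:
            attrs.append(f'color="{bottleneck_color}"')
            attrs.append("penwidth=2.5")
        lines.append(f'  "{a}" -> "{b}" [{", ".join(attrs)}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
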