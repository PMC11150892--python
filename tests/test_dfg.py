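"""Directly-follows graph mining, bottleneck scoring, DOT export."""

import re

import numpy as np
import pandas as pd
import pytest

from careflow.abstraction import apply_abstraction, level_b_spec
from careflow.dfg import (
    EdgeStats,
    NodeStats,
    ProcessMap,
    annotate_semantics,
    export_dot,
    mine_dfg,
    score_bottlenecks,
)
from careflow.stages import DEFAULT_STAGE_ROLES

from conftest import make_log


def brute_force_pairs(traces: dict[str, list[tuple[str, float]]]):
    """Independent oracle: exhaustive consecutive-pair enumeration."""
    counts: dict[tuple[str, str], int] = {}
    cases: dict[tuple[str, str], set] = {}
    durations: dict[tuple[str, str], list[float]] = {}
    for cid, seq in traces.items():
        for (a, da), (b, db) in zip(seq, seq[1:]):
            key = (a, b)
            counts[key] = counts.get(key, 0) + 1
            cases.setdefault(key, set()).add(cid)
            durations.setdefault(key, []).append((db - da) / 7.0)
    return counts, cases, durations


def test_single_case_example():
    log = make_log({"c1": [("A", 0), ("B", 14), ("C", 35)]})
    pmap = mine_dfg(log)
    assert pmap.edges[("A", "B")].n_traversals == 1
    assert pmap.edges[("A", "B")].median_weeks == pytest.approx(2.0)
    assert pmap.edges[("B", "C")].median_weeks == pytest.approx(3.0)
    assert pmap.nodes["A"].median_duration_weeks == pytest.approx(2.0)
    assert np.isnan(pmap.nodes["C"].median_duration_weeks)  # terminal: no duration


def test_empty_log_gives_empty_map():
    from careflow.eventlog import EventLog, _empty_events
    pmap = mine_dfg(EventLog(events=_empty_events()))
    assert pmap.nodes == {} and pmap.edges == {}


def test_matches_bruteforce_on_random_small_logs():
    """Edge counts/cases/durations equal the exhaustive pair enumeration."""
    rng = np.random.default_rng(17)
    stages = list("ABCDEFGH")
    for _ in range(60):
        traces = {}
        for i in range(rng.integers(1, 11)):
            n = int(rng.integers(1, 9))
            acts = [stages[j] for j in rng.integers(0, len(stages), n)]
            days = np.sort(rng.integers(0, 400, n)).astype(float)
            traces[f"c{i}"] = list(zip(acts, days))
        pmap = mine_dfg(make_log(traces))
        counts, cases, durations = brute_force_pairs(traces)
        assert {k: e.n_traversals for k, e in pmap.edges.items()} == counts
        assert {k: e.n_cases for k, e in pmap.edges.items()} == {k: len(v) for k, v in cases.items()}
        for k, e in pmap.edges.items():
            assert e.median_weeks == pytest.approx(np.percentile(durations[k], 50))


def test_repeat_traversals_count_once_per_case():
    log = make_log({"c1": [("A", 0), ("B", 7), ("A", 14), ("B", 21)]})
    e = mine_dfg(log).edges[("A", "B")]
    assert e.n_traversals == 2
    assert e.n_cases == 1


def test_branching_probabilities_sum_to_one_with_end_share(site5000):
    lb, _ = apply_abstraction(site5000, level_b_spec(), 1.0)
    pmap = mine_dfg(lb)
    for label, ns in pmap.nodes.items():
        out = pmap.out_traversals(label)
        probs = sum(e.probability for (a, _), e in pmap.edges.items() if a == label)
        assert probs + ns.n_ends / out == pytest.approx(1.0)


def test_flow_conservation_and_source_total(site5000):
    """Unique source/sink: interior in-traversals equal out-traversals."""
    lb, _ = apply_abstraction(site5000, level_b_spec(), 1.0)
    pmap = mine_dfg(lb)
    assert pmap.nodes["referral_received"].n_starts == pmap.total_cases
    assert pmap.nodes["discharged"].n_ends == pmap.total_cases
    source_out = sum(e.n_traversals for (a, _), e in pmap.edges.items()
                     if a == "referral_received")
    assert source_out == pmap.total_cases
    for label in pmap.nodes:
        if label in ("referral_received", "discharged"):
            continue
        incoming = sum(e.n_traversals for (_, b), e in pmap.edges.items() if b == label)
        outgoing = sum(e.n_traversals for (a, _), e in pmap.edges.items() if a == label)
        assert incoming == outgoing, label


# -- bottleneck scoring -----------------------------------------------------

def _toy_map(edges: dict[tuple[str, str], tuple[int, float]]) -> ProcessMap:
    pmap = ProcessMap(total_cases=sum(c for c, _ in edges.values()))
    for (a, b), (cases, med) in edges.items():
        pmap.nodes.setdefault(a, NodeStats(label=a))
        pmap.nodes.setdefault(b, NodeStats(label=b))
        pmap.edges[(a, b)] = EdgeStats(source=a, target=b, n_traversals=cases,
                                       n_cases=cases, median_weeks=med)
    return pmap


def test_bottleneck_flags_only_top_percentile():
    pmap = _toy_map({("a", "b"): (100, 10.0), ("b", "c"): (500, 1.0), ("c", "d"): (10, 5.0)})
    score_bottlenecks(pmap, percentile=0.67)
    flags = {k: e.bottleneck for k, e in pmap.edges.items()}
    assert flags == {("a", "b"): True, ("b", "c"): False, ("c", "d"): False}
    assert pmap.edges[("a", "b")].bottleneck_score == pytest.approx(1000.0)


def test_zero_score_edge_never_flagged_among_positive():
    pmap = _toy_map({("a", "b"): (0, 10.0), ("b", "c"): (5, 0.0), ("c", "d"): (10, 5.0)})
    score_bottlenecks(pmap, percentile=0.01)
    assert not pmap.edges[("a", "b")].bottleneck
    assert not pmap.edges[("b", "c")].bottleneck
    assert pmap.edges[("c", "d")].bottleneck


def test_bottleneck_flags_scale_equivariant():
    base = {("a", "b"): (100, 10.0), ("b", "c"): (500, 1.0), ("c", "d"): (10, 5.0),
            ("d", "e"): (40, 2.5)}
    pmap1 = score_bottlenecks(_toy_map(base), percentile=0.7)
    scaled = {k: (c, m * 3.7) for k, (c, m) in base.items()}
    pmap2 = score_bottlenecks(_toy_map(scaled), percentile=0.7)
    assert {k: e.bottleneck for k, e in pmap1.edges.items()} == \
           {k: e.bottleneck for k, e in pmap2.edges.items()}


def test_bottleneck_matches_bruteforce_quantile_on_random_maps():
    rng = np.random.default_rng(3)
    for _ in range(40):
        n = int(rng.integers(2, 9))
        edges = {(f"s{i}", f"s{i+1}"): (int(rng.integers(0, 200)),
                                        float(rng.uniform(0, 30)))
                 for i in range(n)}
        p = float(rng.uniform(0.1, 0.95))
        pmap = score_bottlenecks(_toy_map(edges), percentile=p)
        scores = {k: c * m for k, (c, m) in edges.items()}
        thr = np.quantile(list(scores.values()), p)
        expected = {k: bool(s >= thr and s > 0) for k, s in scores.items()}
        assert {k: e.bottleneck for k, e in pmap.edges.items()} == expected


def test_bottleneck_percentile_validated():
    with pytest.raises(ValueError, match="percentile"):
        score_bottlenecks(_toy_map({("a", "b"): (1, 1.0)}), percentile=1.5)


# -- semantic annotation ----------------------------------------------------

def test_attrition_and_stepup_markers():
    pmap = _toy_map({("step3_waitlist", "discharged"): (5, 20.0),
                     ("step2_treatment", "step3_waitlist"): (3, 1.0),
                     ("assessment", "step2_waitlist"): (8, 0.5)})
    annotate_semantics(pmap, DEFAULT_STAGE_ROLES)
    assert pmap.edges[("step3_waitlist", "discharged")].attrition
    assert pmap.edges[("step2_treatment", "step3_waitlist")].step_up
    e = pmap.edges[("assessment", "step2_waitlist")]
    assert not e.attrition and not e.step_up


def test_unknown_stage_role_raises():
    pmap = _toy_map({("mystery", "discharged"): (1, 1.0)})
    with pytest.raises(KeyError, match="mystery"):
        annotate_semantics(pmap, DEFAULT_STAGE_ROLES)


def test_attrition_counts_match_ground_truth(site5000):
    lb, _ = apply_abstraction(site5000, level_b_spec(), 1.0)
    pmap = annotate_semantics(mine_dfg(lb), DEFAULT_STAGE_ROLES)
    mined = sum(e.n_cases for e in pmap.edges.values() if e.attrition)
    routes = site5000.ground_truth["cases"]["true_route"]
    expected = sum(1 for r in routes
                   if r.split("|")[-2].endswith("waitlist"))
    assert mined == expected


# -- DOT export -------------------------------------------------------------

def test_dot_output_is_deterministic_and_parseable():
    pmap = _toy_map({("b", "a"): (5, 2.0), ("a", "c"): (9, 1.0)})
    score_bottlenecks(pmap, percentile=0.6)
    dot1, dot2 = export_dot(pmap), export_dot(pmap)
    assert dot1 == dot2
    assert dot1.startswith("digraph process_map {")
    assert dot1.rstrip().endswith("}")
    edge_lines = [l for l in dot1.splitlines() if "->" in l]
    assert len(edge_lines) == 2
    for line in edge_lines:
        assert re.match(r'\s*"[^"]+" -> "[^"]+" \[.*\];$', line)


def test_dot_empty_map():
    dot = export_dot(ProcessMap())
    assert "->" not in dot


def test_dot_marks_bottleneck_and_semantics():
    pmap = _toy_map({("step3_waitlist", "discharged"): (50, 30.0),
                     ("assessment", "step3_waitlist"): (60, 0.5)})
    annotate_semantics(pmap, DEFAULT_STAGE_ROLES)
    score_bottlenecks(pmap, percentile=0.5)
    dot = export_dot(pmap)
    assert "[attrition]" in dot
    assert 'color="red"' in dot
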