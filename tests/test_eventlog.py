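"""Event-log I/O, order-violation detection, and LOCF timestamp repair."""

import numpy as np
import pandas as pd
import pytest

from careflow.dists import DistSpec
from careflow.eventlog import (
    SchemaError,
    detect_order_violations,
    filter_cases,
    impute_timestamps,
    read_log,
    to_xes,
    write_log,
)
from careflow.synthlog import corrupt_timestamps, generate_log

from conftest import make_log, make_profile


# -- order violations -------------------------------------------------------

def test_increasing_timestamps_have_no_violations():
    log = make_log({"c1": [("a", 0), ("b", 1), ("c", 2)]})
    assert len(detect_order_violations(log)) == 0


def test_backdated_event_is_flagged():
    log = make_log({"c1": [("a", 1), ("b", 5), ("c", 3), ("d", 9)]})
    viol = detect_order_violations(log)
    assert len(viol) == 1
    assert viol.iloc[0]["activity"] == "c"


def test_violations_compared_to_running_max_not_just_predecessor():
    # day 4 is after day 2 but before the running max (day 7)
    log = make_log({"c1": [("a", 0), ("b", 7), ("c", 2), ("d", 4)]})
    viol = detect_order_violations(log)
    assert set(viol["activity"]) == {"c", "d"}


def test_detection_covers_truly_corrupted_events():
    """Flagged events ⊇ corrupted events whose offset exceeded the gap."""
    log = generate_log(make_profile(n_cases=300, seed=21))
    out = corrupt_timestamps(log, 0.15, DistSpec("lognormal", {"median": 2.0, "sigma": 1.0}), seed=5)
    truth = out.ground_truth["events"]
    merged = out.events.merge(truth, on=["case_id", "source_order"])
    merged = merged.sort_values(["case_id", "source_order"])
    prev_true_max = merged.groupby("case_id")["true_timestamp"].transform(
        lambda s: s.cummax().shift(1))
    # earlier corruption lowers the recorded running max, which can mask a
    # violation; the guaranteed-flag set is corruption with a clean prefix
    earlier_corrupted = merged.groupby("case_id")["corrupted"].transform(
        lambda s: s.shift(fill_value=False).cumsum() > 0)
    must_flag = merged[merged["corrupted"] & ~earlier_corrupted
                       & (merged["timestamp"] < prev_true_max)]
    flagged = detect_order_violations(out)
    keys = set(zip(flagged["case_id"], flagged["source_order"]))
    assert set(zip(must_flag["case_id"], must_flag["source_order"])) <= keys


# -- LOCF repair ------------------------------------------------------------

def test_locf_repairs_to_running_max():
    log = make_log({"c1": [("a", 1), ("b", 5), ("c", 3), ("d", 9)]})
    repaired, report = impute_timestamps(log)
    days = (repaired.events["timestamp"] - pd.Timestamp("2020-01-01")).dt.days.tolist()
    assert days == [1, 5, 5, 9]
    row = repaired.events.iloc[2]
    assert bool(row["imputed"])
    assert row["original_timestamp"] == pd.Timestamp("2020-01-04")
    assert report.n_events_adjusted == 1
    sizes = report.adjustment_sizes_weeks
    assert sizes[sizes > 0].tolist() == pytest.approx([2 / 7])


def test_clean_log_is_unchanged_and_report_zero():
    log = make_log({"c1": [("a", 0), ("b", 3)], "c2": [("a", 1), ("b", 2)]})
    repaired, report = impute_timestamps(log)
    pd.testing.assert_frame_equal(repaired.events, log.events)
    assert report.n_events_adjusted == 0
    summary = report.summary()
    assert summary.loc["size_per_event_all_events", "median"] == 0.0
    assert summary.loc["size_per_event_adjusted_events", "n"] == 0


def test_repair_removes_all_violations_and_is_idempotent():
    log = generate_log(make_profile(n_cases=400, seed=8))
    dirty = corrupt_timestamps(log, 0.2, DistSpec("lognormal", {"median": 3.0, "sigma": 1.0}), seed=1)
    repaired, report = impute_timestamps(dirty)
    assert len(detect_order_violations(repaired)) == 0
    again, report2 = impute_timestamps(repaired)
    pd.testing.assert_frame_equal(again.events, repaired.events)
    assert report2.n_events_adjusted == 0
    assert report.n_events_adjusted > 0


def test_report_conservation():
    """Per-case counts sum to the adjusted-event count; sizes likewise."""
    log = generate_log(make_profile(n_cases=400, seed=8))
    dirty = corrupt_timestamps(log, 0.2, DistSpec("lognormal", {"median": 3.0, "sigma": 1.0}), seed=1)
    _, report = impute_timestamps(dirty)
    assert report.per_case_counts.sum() == report.n_events_adjusted
    assert report.per_case_totals_weeks.sum() == pytest.approx(
        report.adjustment_sizes_weeks.sum())
    assert report.n_cases_adjusted == int((report.per_case_counts > 0).sum())


def test_median_adjustment_over_all_events_is_zero_for_minority_adjustment():
    """With <50% of events adjusted the all-events median adjustment is 0."""
    log = generate_log(make_profile(n_cases=400, seed=8))
    dirty = corrupt_timestamps(log, 0.1, DistSpec("fixed", {"value": 100.0}), seed=2)
    _, report = impute_timestamps(dirty)
    assert 0 < report.n_events_adjusted < 0.5 * report.n_events_total
    assert report.summary().loc["size_per_event_all_events", "median"] == 0.0


def test_repair_restores_order_relative_to_clean_predecessors():
    """Repaired timestamps reach at least the latest uncorrupted predecessor.

    LOCF carries the recorded running max forward, so every repaired
    timestamp is >= the true timestamp of the most recent *uncorrupted*
    earlier event (exact recovery is not claimed).
    """
    log = generate_log(make_profile(n_cases=200, seed=15))
    dirty = corrupt_timestamps(log, 0.25, DistSpec("fixed", {"value": 1e4}), seed=3)
    repaired, _ = impute_timestamps(dirty)
    truth = dirty.ground_truth["events"]
    merged = repaired.events.merge(truth, on=["case_id", "source_order"])
    merged = merged.sort_values(["case_id", "source_order"])
    clean_true = merged["true_timestamp"].where(~merged["corrupted"])
    prev_clean_max = merged.assign(ct=clean_true).groupby("case_id")["ct"].transform(
        lambda s: s.shift(1).cummax())
    mask = prev_clean_max.notna() & merged["corrupted"]
    assert (merged.loc[mask, "timestamp"] >= prev_clean_max[mask]).all()


def test_unknown_strategy_rejected():
    log = make_log({"c1": [("a", 0)]})
    with pytest.raises(ValueError, match="strategy"):
        impute_timestamps(log, strategy="interpolate")


# -- I/O --------------------------------------------------------------------

def test_round_trip_is_lossless(tmp_path):
    log = generate_log(make_profile(n_cases=60, seed=19, corruption_rate=0.2))
    repaired, _ = impute_timestamps(log)  # includes imputed events w/ both stamps
    write_log(repaired, tmp_path)
    back = read_log(tmp_path)
    pd.testing.assert_frame_equal(back.events, repaired.events)
    pd.testing.assert_frame_equal(back.cases, repaired.cases, check_dtype=False)
    pd.testing.assert_frame_equal(back.appointments, repaired.appointments)
    pd.testing.assert_frame_equal(back.outcomes, repaired.outcomes)
    assert back.load_report.n_rejected == 0


def test_empty_log_round_trip(tmp_path):
    from careflow.eventlog import EventLog, _empty_events
    write_log(EventLog(events=_empty_events()), tmp_path)
    assert (tmp_path / "movements.csv").read_text().startswith("case_id,")
    back = read_log(tmp_path)
    assert back.n_events == 0


def test_reader_rejects_blank_case_and_bad_timestamp(tmp_path):
    (tmp_path / "movements.csv").write_text(
        "case_id,activity,timestamp\n"
        "c1,a,2020-01-01T00:00:00\n"
        ",a,2020-01-02T00:00:00\n"
        "c1,b,not-a-date\n"
        "c2,a,2020-01-03T00:00:00\n")
    log = read_log(tmp_path)
    assert log.n_events == 2
    assert log.load_report.n_rejected_missing_case_id == 1
    assert log.load_report.n_rejected_bad_timestamp == 1


def test_reader_requires_columns(tmp_path):
    (tmp_path / "movements.csv").write_text("case_id,activity,when\nc1,a,2020-01-01\n")
    with pytest.raises(SchemaError, match="timestamp"):
        read_log(tmp_path)


def test_xes_export_is_wellformed_xml():
    import xml.etree.ElementTree as ET
    log = make_log({"c1": [("a", 0), ("b", 1)], "c2": [("a", 2)]})
    root = ET.fromstring(to_xes(log))
    ns = "{http://www.xes-standard.org/}"
    assert len(root.findall(f"{ns}trace")) == 2


# -- case filtering ---------------------------------------------------------

def test_filter_cases_predicate_matches_bruteforce():
    log = generate_log(make_profile(n_cases=300, seed=23))
    kept = filter_cases(log, "age >= 30")
    expected = set(log.cases.loc[log.cases["age"] >= 30, "case_id"])
    assert set(kept.cases["case_id"]) == expected
    assert set(kept.events["case_id"]) <= expected


def test_filter_cases_true_predicate_is_identity():
    log = generate_log(make_profile(n_cases=50, seed=2))
    kept = filter_cases(log, lambda df: pd.Series(True, index=df.index))
    pd.testing.assert_frame_equal(kept.events, log.events)


def test_filter_cases_referral_window():
    log = generate_log(make_profile(n_cases=200, seed=3))
    first = log.events.sort_values(["case_id", "source_order"]).groupby("case_id")["timestamp"].first()
    cutoff = pd.Timestamp("2020-06-01")
    in_window = set(first[first < cutoff].index)
    kept = filter_cases(log, lambda df: df["case_id"].map(lambda c: first[c] < cutoff))
    assert set(kept.cases["case_id"]) == in_window
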