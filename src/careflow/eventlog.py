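"""Event-log data model, delimited-text I/O, validation, and timestamp repair.

An :class:`EventLog` bundles four pandas tables keyed by ``case_id``:

``events``
    one row per pathway *movement* — the referral entering a stage —
    with columns ``case_id, activity, timestamp, source_order, imputed,
    original_timestamp``.  ``source_order`` is the recorded entry order
    within the case and is the authoritative event sequence; timestamps
    are repaired *to* that order, never the other way round.
``cases``
    per-referral attributes (age, gender, presenting problem, referral
    source, deprivation decile, prior-referral count).
``appointments``
    scheduled appointments with ``attended`` (nullable boolean) and
    ``is_treatment`` flags.
``outcomes``
    session-order outcome-measure scores with an above-caseness flag.

Manually entered movement timestamps do not always respect the true event
sequence; :func:`impute_timestamps` repairs out-of-order timestamps by
last observation carried forward (LOCF) and returns an
:class:`ImputationReport` summarising the adjustments (sizes in weeks and
counts, per event and per case, over all and over adjusted ones only).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

WEEK = pd.Timedelta(days=7)

EVENT_COLUMNS = ["case_id", "activity", "timestamp", "source_order", "imputed", "original_timestamp"]
CASE_COLUMNS = [
    "case_id", "age", "gender", "presenting_problem", "referral_source",
    "imd_decile", "prior_referrals",
]
APPOINTMENT_COLUMNS = ["case_id", "datetime", "attended", "is_treatment"]
OUTCOME_COLUMNS = ["case_id", "session_index", "score", "above_caseness"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame({
        "case_id": pd.Series(dtype="object"),
        "activity": pd.Series(dtype="object"),
        "timestamp": pd.Series(dtype="datetime64[ns]"),
        "source_order": pd.Series(dtype="int64"),
        "imputed": pd.Series(dtype="bool"),
        "original_timestamp": pd.Series(dtype="datetime64[ns]"),
    })


def _empty_cases() -> pd.DataFrame:
    return pd.DataFrame({
        "case_id": pd.Series(dtype="object"),
        "age": pd.Series(dtype="float64"),
        "gender": pd.Series(dtype="object"),
        "presenting_problem": pd.Series(dtype="object"),
        "referral_source": pd.Series(dtype="object"),
        "imd_decile": pd.Series(dtype="float64"),
        "prior_referrals": pd.Series(dtype="int64"),
    })


def _empty_appointments() -> pd.DataFrame:
    return pd.DataFrame({
        "case_id": pd.Series(dtype="object"),
        "datetime": pd.Series(dtype="datetime64[ns]"),
        "attended": pd.Series(dtype="boolean"),
        "is_treatment": pd.Series(dtype="bool"),
    })


def _empty_outcomes() -> pd.DataFrame:
    return pd.DataFrame({
        "case_id": pd.Series(dtype="object"),
        "session_index": pd.Series(dtype="int64"),
        "score": pd.Series(dtype="float64"),
        "above_caseness": pd.Series(dtype="bool"),
    })


@dataclass
class LoadReport:
    n_rows_read: int = 0
    n_rejected_missing_case_id: int = 0
    n_rejected_bad_timestamp: int = 0

    @property
    def n_rejected(self) -> int:
        return self.n_rejected_missing_case_id + self.n_rejected_bad_timestamp


@dataclass
class EventLog:
    """Container for one site's event log and its linked tables."""

    events: pd.DataFrame
    cases: pd.DataFrame = field(default_factory=_empty_cases)
    appointments: pd.DataFrame = field(default_factory=_empty_appointments)
    outcomes: pd.DataFrame = field(default_factory=_empty_outcomes)
    #: generator ground truth (not serialised); dict with "cases"/"events" frames
    ground_truth: dict | None = None
    load_report: LoadReport | None = None

    # -- basic accessors ---------------------------------------------------
    @property
    def n_cases(self) -> int:
        return int(self.cases["case_id"].nunique())

    @property
    def n_events(self) -> int:
        return len(self.events)

    def case_ids(self) -> list[str]:
        return sorted(self.cases["case_id"].unique())

    def case_routes(self) -> pd.Series:
        """Map case_id -> tuple of activities in source order."""
        ev = self.events.sort_values(["case_id", "source_order"])
        return ev.groupby("case_id", sort=True)["activity"].agg(tuple)

    def copy(self) -> "EventLog":
        return EventLog(
            events=self.events.copy(),
            cases=self.cases.copy(),
            appointments=self.appointments.copy(),
            outcomes=self.outcomes.copy(),
            ground_truth=None if self.ground_truth is None else {
                k: v.copy() for k, v in self.ground_truth.items()
            },
            load_report=self.load_report,
        )

    def restrict(self, case_ids: Iterable[str]) -> "EventLog":
        """Return the sub-log containing exactly the given cases."""
        keep = set(case_ids)

        def _f(df: pd.DataFrame) -> pd.DataFrame:
            return df[df["case_id"].isin(keep)].reset_index(drop=True)

        gt = None
        if self.ground_truth is not None:
            gt = {k: _f(v) for k, v in self.ground_truth.items()}
        return EventLog(
            events=_f(self.events), cases=_f(self.cases),
            appointments=_f(self.appointments), outcomes=_f(self.outcomes),
            ground_truth=gt,
        )

    def validate(self) -> None:
        """Raise ValueError on violated structural invariants."""
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise SchemaError(f"events table missing columns {missing}")
        ev_cases = set(self.events["case_id"])
        known = set(self.cases["case_id"])
        orphans = ev_cases - known
        if orphans:
            raise ValueError(f"{len(orphans)} event case_ids absent from cases table")
        grp = self.events.sort_values(["case_id", "source_order"]).groupby("case_id")
        orders = grp["source_order"].agg(list)
        for cid, seq in orders.items():
            if seq != list(range(len(seq))):
                raise ValueError(f"source_order not contiguous from 0 for case {cid}")


def _normalise(events: pd.DataFrame) -> pd.DataFrame:
    ev = events.sort_values(["case_id", "source_order"], kind="mergesort").reset_index(drop=True)
    return ev


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_FILES = {
    "movements": "movements.csv",
    "cases": "cases.csv",
    "appointments": "appointments.csv",
    "outcomes": "outcomes.csv",
}


def _parse_bool(col: pd.Series, nullable: bool = False) -> pd.Series:
    mapping = {"True": True, "False": False, "true": True, "false": False,
               "1": True, "0": False, "": pd.NA}
    out = col.astype("object").where(col.notna(), "").astype(str).map(mapping)
    if nullable:
        return out.astype("boolean")
    return out.where(out.notna(), False).astype(bool)


def read_log(directory: str | os.PathLike, schema: Mapping[str, str] | None = None) -> EventLog:
    """Read an event log from a directory of CSV tables.

    ``movements.csv`` is required (columns ``case_id, activity, timestamp``
    at minimum); ``cases.csv``, ``appointments.csv`` and ``outcomes.csv``
    are optional.  ``schema`` maps file column names onto the canonical
    names, for logs exported with different headers.  Rows with a blank
    ``case_id`` or an unparseable timestamp are rejected and counted in
    the returned log's :attr:`EventLog.load_report`.
    """
    directory = os.fspath(directory)
    mov_path = os.path.join(directory, _FILES["movements"])
    if not os.path.exists(mov_path):
        raise FileNotFoundError(mov_path)
    raw = pd.read_csv(mov_path, dtype="object", keep_default_na=False)
    if schema:
        raw = raw.rename(columns=dict(schema))
    for col in ("case_id", "activity", "timestamp"):
        if col not in raw.columns:
            raise SchemaError(f"movements.csv missing required column {col!r}")

    report = LoadReport(n_rows_read=len(raw))
    blank = raw["case_id"].astype(str).str.strip() == ""
    report.n_rejected_missing_case_id = int(blank.sum())
    raw = raw[~blank]
    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    bad = ts.isna()
    report.n_rejected_bad_timestamp = int(bad.sum())
    raw = raw[~bad]
    ts = ts[~bad]

    events = pd.DataFrame({
        "case_id": raw["case_id"].astype(str).values,
        "activity": raw["activity"].astype(str).values,
        "timestamp": ts.values,
    })
    if "source_order" in raw.columns:
        events["source_order"] = raw["source_order"].astype(int).values
    else:
        events["source_order"] = events.groupby("case_id").cumcount()
    if "imputed" in raw.columns:
        events["imputed"] = _parse_bool(raw["imputed"]).values
        events["original_timestamp"] = pd.to_datetime(
            raw["original_timestamp"].replace("", pd.NaT), errors="coerce", format="ISO8601"
        ).values
    else:
        events["imputed"] = False
        events["original_timestamp"] = pd.NaT
    events = _normalise(events)

    def _read_optional(name: str) -> pd.DataFrame | None:
        path = os.path.join(directory, _FILES[name])
        return pd.read_csv(path, dtype="object", keep_default_na=False) if os.path.exists(path) else None

    cases_raw = _read_optional("cases")
    if cases_raw is not None and len(cases_raw):
        cases = pd.DataFrame({
            "case_id": cases_raw["case_id"].astype(str),
            "age": pd.to_numeric(cases_raw.get("age"), errors="coerce"),
            "gender": cases_raw.get("gender", ""),
            "presenting_problem": cases_raw.get("presenting_problem", ""),
            "referral_source": cases_raw.get("referral_source", ""),
            "imd_decile": pd.to_numeric(cases_raw.get("imd_decile"), errors="coerce"),
            "prior_referrals": pd.to_numeric(cases_raw.get("prior_referrals"), errors="coerce").fillna(0).astype(int),
        })
    else:
        # synthesise a minimal cases table from the events
        cases = _empty_cases()
        ids = sorted(events["case_id"].unique())
        cases = pd.DataFrame({"case_id": ids})
        for col in CASE_COLUMNS[1:]:
            cases[col] = np.nan
        cases["prior_referrals"] = 0
        cases["gender"] = ""
        cases["presenting_problem"] = ""
        cases["referral_source"] = ""

    appt_raw = _read_optional("appointments")
    if appt_raw is not None and len(appt_raw):
        appointments = pd.DataFrame({
            "case_id": appt_raw["case_id"].astype(str),
            "datetime": pd.to_datetime(appt_raw["datetime"], format="ISO8601"),
            "attended": _parse_bool(appt_raw["attended"], nullable=True),
            "is_treatment": _parse_bool(appt_raw["is_treatment"]),
        })
    else:
        appointments = _empty_appointments()

    out_raw = _read_optional("outcomes")
    if out_raw is not None and len(out_raw):
        outcomes = pd.DataFrame({
            "case_id": out_raw["case_id"].astype(str),
            "session_index": out_raw["session_index"].astype(int),
            "score": out_raw["score"].astype(float),
            "above_caseness": _parse_bool(out_raw["above_caseness"]),
        })
    else:
        outcomes = _empty_outcomes()

    log = EventLog(events=events, cases=cases.reset_index(drop=True),
                   appointments=appointments.reset_index(drop=True),
                   outcomes=outcomes.reset_index(drop=True))
    log.load_report = report
    return log


def write_log(log: EventLog, directory: str | os.PathLike) -> dict[str, str]:
    """Write the log as four CSV files; returns the paths written.

    The round trip ``read_log(write_log(log))`` is lossless, including the
    imputation flags and both timestamps of repaired events.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    paths = {}

    ev = log.events.copy()
    ev["timestamp"] = ev["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    ev["original_timestamp"] = ev["original_timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S").fillna("")
    paths["movements"] = os.path.join(directory, _FILES["movements"])
    ev.to_csv(paths["movements"], index=False)

    paths["cases"] = os.path.join(directory, _FILES["cases"])
    log.cases.to_csv(paths["cases"], index=False)

    ap = log.appointments.copy()
    if len(ap):
        ap["datetime"] = ap["datetime"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    ap["attended"] = ap["attended"].astype("object").where(ap["attended"].notna(), "")
    paths["appointments"] = os.path.join(directory, _FILES["appointments"])
    ap.to_csv(paths["appointments"], index=False)

    paths["outcomes"] = os.path.join(directory, _FILES["outcomes"])
    log.outcomes.to_csv(paths["outcomes"], index=False)
    return paths


def to_xes(log: EventLog) -> str:
    """Minimal XES-compatible XML export (concept:name + time:timestamp)."""
    buf = io.StringIO()
    buf.write('<?xml version="1.0" encoding="UTF-8"?>\n')
    buf.write('<log xes.version="1.0" xmlns="http://www.xes-standard.org/">\n')
    ev = log.events.sort_values(["case_id", "source_order"])
    for cid, grp in ev.groupby("case_id", sort=True):
        buf.write('  <trace>\n')
        buf.write(f'    <string key="concept:name" value="{cid}"/>\n')
        for _, row in grp.iterrows():
            buf.write('    <event>\n')
            buf.write(f'      <string key="concept:name" value="{row.activity}"/>\n')
            stamp = pd.Timestamp(row.timestamp).strftime("%Y-%m-%dT%H:%M:%S")
            buf.write(f'      <date key="time:timestamp" value="{stamp}"/>\n')
            buf.write('    </event>\n')
        buf.write('  </trace>\n')
    buf.write('</log>\n')
    return buf.getvalue()


# ---------------------------------------------------------------------------
# order violations and LOCF repair
# ---------------------------------------------------------------------------

def detect_order_violations(log: EventLog) -> pd.DataFrame:
    """Events whose timestamp precedes the running maximum of earlier events.

    "Earlier" is by ``source_order`` within the case (the recorded
    sequence); returns the violating rows of ``log.events``.
    """
    ev = _normalise(log.events)
    prev_max = ev.groupby("case_id")["timestamp"].transform(lambda s: s.cummax().shift(1))
    mask = ev["timestamp"] < prev_max
    return ev[mask]


@dataclass
class ImputationReport:
    """Adjustment-size and adjustment-count summaries of a LOCF repair.

    Sizes are absolute |repaired − recorded| in weeks.  Each statistics
    family is reported both over *all* units (events or cases, zeros
    included for unadjusted ones) and over *adjusted* units only.
    """

    adjustment_sizes_weeks: pd.Series     # per event, over ALL events (0 if unadjusted)
    event_case_ids: pd.Series             # case_id aligned with adjustment_sizes_weeks
    all_case_ids: list[str]               # every case in the log

    @property
    def n_events_total(self) -> int:
        return len(self.adjustment_sizes_weeks)

    @property
    def n_events_adjusted(self) -> int:
        return int((self.adjustment_sizes_weeks > 0).sum())

    @property
    def n_cases_total(self) -> int:
        return len(self.all_case_ids)

    @property
    def per_case_totals_weeks(self) -> pd.Series:
        totals = self.adjustment_sizes_weeks.groupby(self.event_case_ids.values).sum()
        return totals.reindex(self.all_case_ids, fill_value=0.0)

    @property
    def per_case_counts(self) -> pd.Series:
        counts = (self.adjustment_sizes_weeks > 0).groupby(self.event_case_ids.values).sum()
        return counts.reindex(self.all_case_ids, fill_value=0).astype(int)

    @property
    def n_cases_adjusted(self) -> int:
        return int((self.per_case_counts > 0).sum())

    @staticmethod
    def _stats(values: np.ndarray) -> dict:
        if len(values) == 0:
            return {"n": 0, "mean": np.nan, "sd": np.nan, "median": np.nan,
                    "q1": np.nan, "q3": np.nan}
        return {
            "n": int(len(values)),
            "mean": float(np.mean(values)),
            "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
            "median": float(np.median(values)),
            "q1": float(np.percentile(values, 25)),
            "q3": float(np.percentile(values, 75)),
        }

    def summary(self) -> pd.DataFrame:
        sizes = self.adjustment_sizes_weeks.to_numpy(float)
        totals = self.per_case_totals_weeks.to_numpy(float)
        counts = self.per_case_counts.to_numpy(float)
        adjusted_cases = counts > 0
        rows = {
            "size_per_case_all_cases": self._stats(totals),
            "size_per_case_adjusted_cases": self._stats(totals[adjusted_cases]),
            "size_per_event_all_events": self._stats(sizes),
            "size_per_event_adjusted_events": self._stats(sizes[sizes > 0]),
            "count_per_case_all_cases": self._stats(counts),
            "count_per_case_adjusted_cases": self._stats(counts[adjusted_cases]),
        }
        return pd.DataFrame(rows).T[["n", "mean", "sd", "median", "q1", "q3"]]


def impute_timestamps(log: EventLog, strategy: str = "locf") -> tuple[EventLog, ImputationReport]:
    """Repair out-of-order timestamps by last observation carried forward.

    Every event whose timestamp precedes the running maximum of earlier
    timestamps in its case is replaced by that running maximum; the
    repaired log has non-decreasing per-case timestamps in source order
    and the repair is idempotent.  Repaired events carry ``imputed=True``
    and keep their recorded value in ``original_timestamp``.
    """
    if strategy != "locf":
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    ev = _normalise(log.events).copy()
    # LOCF repaired value = max(own ts, cummax of earlier recorded ts):
    # the repaired running max equals the recorded running max.
    prev_max = ev.groupby("case_id")["timestamp"].transform(lambda s: s.cummax().shift(1))
    repaired = ev["timestamp"].where(~(ev["timestamp"] < prev_max), prev_max)
    adjusted = repaired != ev["timestamp"]
    sizes_weeks = (repaired - ev["timestamp"]).dt.total_seconds().abs() / WEEK.total_seconds()

    new_ev = ev.copy()
    new_ev.loc[adjusted, "original_timestamp"] = ev.loc[adjusted, "timestamp"]
    new_ev.loc[adjusted, "imputed"] = True
    new_ev["timestamp"] = repaired

    out = EventLog(events=new_ev, cases=log.cases, appointments=log.appointments,
                   outcomes=log.outcomes, ground_truth=log.ground_truth)
    report = ImputationReport(
        adjustment_sizes_weeks=sizes_weeks.rename("adjustment_weeks"),
        event_case_ids=ev["case_id"],
        all_case_ids=sorted(log.cases["case_id"].unique()),
    )
    return out, report


def filter_cases(log: EventLog, predicate: str | Callable[[pd.DataFrame], pd.Series]) -> EventLog:
    """Retain exactly the cases satisfying a predicate over case attributes.

    ``predicate`` is either a pandas ``query`` string evaluated on the
    cases table (e.g. ``"age >= 18"``) or a callable mapping the cases
    table to a boolean mask.
    """
    if callable(predicate):
        mask = predicate(log.cases)
    else:
        mask = log.cases.eval(predicate)
    mask = pd.Series(mask, index=log.cases.index).astype(bool)
    keep = log.cases.loc[mask, "case_id"]
    return log.restrict(keep)
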