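"""Cohort-level service metrics: completion, recovery, attendance, flows.

Every calculator returns its numerator and denominator alongside the
rate, so each published-style percentage can be reproduced and audited.
Percentages are rounded half-even to 2 decimal places (1 dp for the
timestamp-imputation rate), week durations to 1 dp — the precision the
field's service reports print.

Definitions:

- *treatment completion*: a referral with at least two attended treatment
  appointments (assessment appointments do not count);
- *recovery*: above the caseness threshold at the first recorded outcome
  score and below it at the last, among completers with outcome data who
  started above threshold;
- *missed-appointment rate*: not-attended over all scheduled appointments,
  after removing rows with a missing attendance flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN

import numpy as np
import pandas as pd

from .dfg import ProcessMap
from .eventlog import EventLog, ImputationReport, WEEK
from .stages import DEFAULT_STAGE_ROLES


@dataclass(frozen=True)
class RateResult:
    """A rate with its exact integer numerator and denominator."""

    numerator: int
    denominator: int

    @property
    def rate(self) -> float:
        if self.denominator == 0:
            return float("nan")
        return self.numerator / self.denominator

    def pct(self, dp: int = 2) -> float:
        """Percentage rounded half-even to ``dp`` decimals (exact decimal arithmetic)."""
        if self.denominator == 0:
            raise ZeroDivisionError("rate denominator is zero")
        q = Decimal(self.numerator) * 100 / Decimal(self.denominator)
        return float(q.quantize(Decimal(f"1e-{dp}"), ROUND_HALF_EVEN))

    def __str__(self) -> str:
        return f"{self.numerator}/{self.denominator} ({self.pct()})"


def completer_ids(appointments: pd.DataFrame) -> pd.Index:
    """Cases with >= 2 attended treatment appointments (missing flags dropped)."""
    ap = appointments[appointments["attended"].notna()]
    ap = ap[(ap["is_treatment"]) & (ap["attended"] == True)]  # noqa: E712
    counts = ap.groupby("case_id").size()
    return counts[counts >= 2].index


def completion_rate(appointments: pd.DataFrame, cases: pd.DataFrame) -> RateResult:
    """Treatment-completion rate over all referrals."""
    n_cases = int(cases["case_id"].nunique())
    if n_cases == 0:
        raise ZeroDivisionError("no cases")
    return RateResult(len(completer_ids(appointments)), n_cases)


@dataclass(frozen=True)
class RecoveryResult:
    recovery: RateResult              # recovered / completers-with-data above caseness at start
    data_completeness: RateResult     # completers with outcome data / completers
    n_not_at_caseness: int            # completers with data who started below threshold

    @property
    def defined(self) -> bool:
        return self.recovery.denominator > 0


def recovery_rate(outcomes: pd.DataFrame, completers: pd.Index | set) -> RecoveryResult:
    """Recovery among completers, caseness convention.

    The denominator excludes completers without outcome data and those
    below the caseness threshold at the start; both groups are reported
    separately.  An empty denominator yields ``defined == False`` rather
    than an error.
    """
    completers = pd.Index(sorted(set(completers)))
    oc = outcomes[outcomes["case_id"].isin(completers)].sort_values(["case_id", "session_index"])
    firsts = oc.groupby("case_id")["above_caseness"].first()
    lasts = oc.groupby("case_id")["above_caseness"].last()
    with_data = firsts.index
    started_above = firsts[firsts].index
    recovered = int((~lasts.loc[started_above]).sum())
    return RecoveryResult(
        recovery=RateResult(recovered, len(started_above)),
        data_completeness=RateResult(len(with_data), len(completers)),
        n_not_at_caseness=int(len(with_data) - len(started_above)),
    )


def missed_appointment_rate(appointments: pd.DataFrame) -> RateResult:
    """Not-attended over all scheduled appointments (missing flags removed)."""
    ap = appointments[appointments["attended"].notna()]
    if len(ap) == 0:
        raise ZeroDivisionError("no scheduled appointments with attendance data")
    return RateResult(int((ap["attended"] == False).sum()), len(ap))  # noqa: E712


def coverage_fraction(retained: int, total: int) -> float:
    """Percentage of referrals retained by a coverage filter, 2 dp."""
    if total == 0:
        raise ZeroDivisionError("total is zero")
    if retained > total:
        raise ValueError("retained exceeds total")
    return RateResult(retained, total).pct(2)


def imputation_rate(report: ImputationReport) -> float:
    """Percentage of events whose timestamp was adjusted, 1 dp."""
    if report.n_events_total == 0:
        raise ZeroDivisionError("report covers zero events")
    return RateResult(report.n_events_adjusted, report.n_events_total).pct(1)


def flow_breakdown(pmap: ProcessMap,
                   stage_roles: dict[str, frozenset[str]] = DEFAULT_STAGE_ROLES) -> pd.DataFrame:
    """Discharge-flow breakdown of an annotated, waitlist-retaining map.

    Rows (each with numerator, denominator, pct at 2 dp):

    - ``immediate_discharge``: cases discharged before assessment (straight
      from referral or off the assessment waiting list), over all cases;
    - ``post_assessment_discharge``: assessment→discharge, over assessed
      cases and over all cases;
    - ``pretreatment_attrition``: discharge off a step-2/step-3 waiting
      list, over triaged cases, over all cases, and per step.

    Stages missing from the map simply contribute zero; a missing
    assessment stage is noted.
    """
    def role_nodes(*needed: str) -> set[str]:
        return {s for s in pmap.nodes
                if set(needed) <= set(stage_roles.get(s, frozenset()))}

    def cases_on_edges(sources: set[str], targets: set[str]) -> int:
        return sum(e.n_cases for (a, b), e in pmap.edges.items()
                   if a in sources and b in targets)

    discharge = role_nodes("discharge")
    referral = role_nodes("referral")
    assessment = role_nodes("assessment")
    assess_wl = {s for s in role_nodes("waitlist")
                 if not ({"step2", "step3"} & set(stage_roles[s]))}
    step2_wl = role_nodes("waitlist", "step2")
    step3_wl = role_nodes("waitlist", "step3")

    total = pmap.total_cases
    n_assessed = sum(pmap.nodes[s].n_cases for s in assessment)
    n_triaged = sum(pmap.nodes[s].n_cases for s in step2_wl | step3_wl)
    n_step2 = sum(pmap.nodes[s].n_cases for s in step2_wl)
    n_step3 = sum(pmap.nodes[s].n_cases for s in step3_wl)

    imm = cases_on_edges(referral, discharge) + cases_on_edges(assess_wl, discharge)
    post_assess = cases_on_edges(assessment, discharge)
    attr2 = cases_on_edges(step2_wl, discharge)
    attr3 = cases_on_edges(step3_wl, discharge)

    def row(name, num, den, note=""):
        pct = RateResult(num, den).pct(2) if den else float("nan")
        return {"quantity": name, "numerator": num, "denominator": den,
                "pct": pct, "note": note}

    rows = [
        row("immediate_discharge_of_all", imm, total),
        row("post_assessment_discharge_of_assessed", post_assess, n_assessed,
            "" if assessment else "no assessment stage in map"),
        row("post_assessment_discharge_of_all", post_assess, total),
        row("pretreatment_attrition_of_triaged", attr2 + attr3, n_triaged),
        row("pretreatment_attrition_of_all", attr2 + attr3, total),
        row("pretreatment_attrition_step2", attr2, n_step2),
        row("pretreatment_attrition_step3", attr3, n_step3),
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort summary (data-description table)
# ---------------------------------------------------------------------------

def _dist_stats(values: np.ndarray) -> dict[str, float]:
    if len(values) == 0:
        return {"mean": np.nan, "sd": np.nan, "median": np.nan, "q1": np.nan, "q3": np.nan}
    return {
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        "median": float(np.percentile(values, 50)),
        "q1": float(np.percentile(values, 25)),
        "q3": float(np.percentile(values, 75)),
    }


@dataclass
class CohortSummary:
    n_referrals: int
    completion: RateResult
    recovery: RecoveryResult
    missed_appointments: RateResult
    imd_decile_proportions: dict[int, float]
    referral_duration_weeks: dict[str, float]
    total_waiting_weeks: dict[str, float]
    sessions_all: dict[str, float]
    sessions_completers: dict[str, float]
    demographics: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"quantity": "referrals", "value": self.n_referrals},
            {"quantity": "completion_pct", "value": self.completion.pct()},
            {"quantity": "recovery_pct",
             "value": self.recovery.recovery.pct() if self.recovery.defined else np.nan},
            {"quantity": "recovery_data_completeness_pct",
             "value": self.recovery.data_completeness.pct()
             if self.recovery.data_completeness.denominator else np.nan},
            {"quantity": "missed_appointment_pct", "value": self.missed_appointments.pct()},
        ]
        for name, stats in (("referral_duration_weeks", self.referral_duration_weeks),
                            ("total_waiting_weeks", self.total_waiting_weeks),
                            ("sessions_all", self.sessions_all),
                            ("sessions_completers", self.sessions_completers)):
            for k, v in stats.items():
                rows.append({"quantity": f"{name}_{k}", "value": v})
        for decile, p in sorted(self.imd_decile_proportions.items()):
            rows.append({"quantity": f"imd_decile_{decile}_pct", "value": p})
        return pd.DataFrame(rows)


def summarize_cohort(log: EventLog,
                     stage_roles: dict[str, frozenset[str]] = DEFAULT_STAGE_ROLES) -> CohortSummary:
    """Data-description summary of one site log (rates, waits, demographics).

    ``total waiting time`` sums each case's durations in waiting-list-role
    stages, so the log should retain waitlist events (raw or level B).
    """
    completers = completer_ids(log.appointments)
    ev = log.events.sort_values(["case_id", "source_order"])
    span = ev.groupby("case_id")["timestamp"].agg(["first", "last"])
    referral_weeks = ((span["last"] - span["first"]) / WEEK).to_numpy(float)

    next_ts = ev.groupby("case_id")["timestamp"].shift(-1)
    dur_weeks = ((next_ts - ev["timestamp"]) / WEEK).fillna(0.0)
    is_wait = ev["activity"].map(lambda a: "waitlist" in stage_roles.get(a, frozenset()))
    waits = dur_weeks.where(is_wait, 0.0).groupby(ev["case_id"].values).sum()

    ap = log.appointments[log.appointments["attended"].notna()]
    ap = ap[(ap["is_treatment"]) & (ap["attended"] == True)]  # noqa: E712
    per_case_sessions = ap.groupby("case_id").size()
    all_sessions = per_case_sessions.reindex(log.cases["case_id"], fill_value=0).to_numpy(float)
    completer_sessions = per_case_sessions.reindex(completers).to_numpy(float)

    imd = log.cases["imd_decile"].dropna().astype(int)
    imd_props = {d: RateResult(int((imd == d).sum()), len(imd)).pct(2) if len(imd) else np.nan
                 for d in range(1, 11)}

    demographics = {}
    for col in ("gender", "presenting_problem", "referral_source"):
        counts = log.cases[col].value_counts()
        demographics[col] = {k: RateResult(int(v), len(log.cases)).pct(2)
                             for k, v in counts.items()}

    return CohortSummary(
        n_referrals=int(log.cases["case_id"].nunique()),
        completion=completion_rate(log.appointments, log.cases),
        recovery=recovery_rate(log.outcomes, completers),
        missed_appointments=missed_appointment_rate(log.appointments),
        imd_decile_proportions=imd_props,
        referral_duration_weeks=_dist_stats(referral_weeks),
        total_waiting_weeks=_dist_stats(waits.to_numpy(float)),
        sessions_all=_dist_stats(all_sessions),
        sessions_completers=_dist_stats(completer_sessions),
        demographics=demographics,
    )
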