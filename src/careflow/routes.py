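"""Route (trace/variant) analysis of stepped-care event logs.

A *route* is one unique stage sequence shared by one or more cases.
This module enumerates routes on a waitlist-retaining (level-B style)
log, ranks them by frequency, computes per-route timing (per-stage median
durations and the median over cases of the summed waiting-stage
durations) and referral-outcome proportions, classifies each route
(no-treatment, step-2 only, step-3 only, stepped care, or waiting-list
attrition at each list), and produces the top-N + pooled-"other" summary
used for stacked-timeline visualisations.

Referral outcomes per case form a partition: ``not_completed`` (fewer
than two attended treatment sessions), and for completers ``recovered`` /
``not_recovered`` (above the caseness threshold at the start and
below/above at the end), ``not_at_caseness`` (started below threshold),
or ``unknown`` (no outcome data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN

import numpy as np
import pandas as pd

from .eventlog import EventLog, WEEK
from .stages import DEFAULT_STAGE_ROLES

OUTCOME_BINS = ("not_completed", "recovered", "not_recovered", "not_at_caseness", "unknown")

ROUTE_CLASSES = (
    "no_treatment", "step2_only", "step3_only", "stepped_care",
    "attrition_step2_wl", "attrition_step3_wl", "attrition_assessment_wl", "other",
)


def _round(x: float, dp: int) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal(f"1e-{dp}"), ROUND_HALF_EVEN))


@dataclass
class RouteSummary:
    route: tuple[str, ...]
    n_cases: int
    pct_of_all: float
    stage_median_weeks: tuple[float, ...]
    total_wait_median_weeks: float
    outcome_counts: dict[str, int]
    outcome_rates: dict[str, float]
    route_class: str
    #: per-case summed waiting-stage durations (kept for exact pooling)
    case_total_waits: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)

    @property
    def label(self) -> str:
        return " > ".join(self.route)


def classify_route(route: tuple[str, ...],
                   stage_roles: dict[str, frozenset[str]] = DEFAULT_STAGE_ROLES) -> str:
    """Assign a route to exactly one pathway class.

    Treatment routes are classified by the steps treated (stepped care
    requires step-2 treatment followed later by step-3 treatment);
    non-treatment routes ending with a discharge straight off a waiting
    list are attrition at that list; anything else without treatment is
    ``no_treatment``.
    """
    roles = [stage_roles.get(s, frozenset()) for s in route]
    s2t = [i for i, r in enumerate(roles) if "treatment" in r and "step2" in r]
    s3t = [i for i, r in enumerate(roles) if "treatment" in r and "step3" in r]
    if s2t and s3t:
        return "stepped_care" if min(s2t) < max(s3t) else "other"
    if s3t:
        return "step3_only"
    if s2t:
        return "step2_only"
    if len(route) >= 2 and "discharge" in roles[-1] and "waitlist" in roles[-2]:
        prev = roles[-2]
        if "step3" in prev:
            return "attrition_step3_wl"
        if "step2" in prev:
            return "attrition_step2_wl"
        return "attrition_assessment_wl"
    return "no_treatment" if route else "other"


def case_outcomes(log: EventLog) -> pd.Series:
    """Map every case to its referral-outcome bin (see module docstring)."""
    ap = log.appointments
    if len(ap):
        attended = ap[(ap["is_treatment"]) & (ap["attended"] == True)]  # noqa: E712
        n_attended = attended.groupby("case_id").size()
    else:
        n_attended = pd.Series(dtype=int)
    out = pd.Series("not_completed", index=log.cases["case_id"].values, dtype=object)
    completers = n_attended[n_attended >= 2].index
    out.loc[out.index.intersection(completers)] = "unknown"
    oc = log.outcomes
    if len(oc):
        oc = oc.sort_values(["case_id", "session_index"])
        firsts = oc.groupby("case_id").first()
        lasts = oc.groupby("case_id").last()
        with_data = firsts.index.intersection(completers)
        for cid in with_data:
            if not firsts.loc[cid, "above_caseness"]:
                out.loc[cid] = "not_at_caseness"
            elif lasts.loc[cid, "above_caseness"]:
                out.loc[cid] = "not_recovered"
            else:
                out.loc[cid] = "recovered"
    return out


def _stage_durations(grp_times: list, n: int) -> np.ndarray:
    """Durations (weeks) per stage position; the last stage contributes 0."""
    arr = np.zeros(n)
    for i in range(n - 1):
        arr[i] = (grp_times[i + 1] - grp_times[i]) / WEEK
    return arr


def enumerate_routes(log: EventLog,
                     stage_roles: dict[str, frozenset[str]] = DEFAULT_STAGE_ROLES
                     ) -> list[RouteSummary]:
    """One summary per distinct route, ranked by descending case count.

    Ties are broken lexicographically by route.  Per-stage medians are
    computed over the cases on the route; the total-wait median is the
    median over cases of each case's *summed* waiting-stage durations
    (median of sums, not sum of medians).
    """
    routes = log.case_routes()
    total = len(routes)
    if total == 0:
        return []
    outcome_by_case = case_outcomes(log)
    ev = log.events.sort_values(["case_id", "source_order"])
    times_by_case = ev.groupby("case_id")["timestamp"].agg(list)

    summaries = []
    by_route: dict[tuple, list[str]] = {}
    for cid, route in routes.items():
        by_route.setdefault(route, []).append(cid)

    for route, cids in by_route.items():
        n = len(route)
        durs = np.array([_stage_durations(times_by_case[cid], n) for cid in cids])
        wait_pos = [i for i, s in enumerate(route) if "waitlist" in stage_roles.get(s, frozenset())]
        total_waits = durs[:, wait_pos].sum(axis=1) if wait_pos else np.zeros(len(cids))
        counts = {b: 0 for b in OUTCOME_BINS}
        for cid in cids:
            counts[outcome_by_case.loc[cid]] += 1
        rates = {b: counts[b] / len(cids) for b in OUTCOME_BINS}
        summaries.append(RouteSummary(
            route=route,
            n_cases=len(cids),
            pct_of_all=100.0 * len(cids) / total,
            stage_median_weeks=tuple(float(np.percentile(durs[:, i], 50)) for i in range(n)),
            total_wait_median_weeks=float(np.percentile(total_waits, 50)),
            outcome_counts=counts,
            outcome_rates=rates,
            route_class=classify_route(route, stage_roles),
            case_total_waits=total_waits,
        ))
    summaries.sort(key=lambda s: (-s.n_cases, s.route))
    return summaries


def top_n_with_other(summaries: list[RouteSummary], n: int = 10
                     ) -> tuple[list[RouteSummary], RouteSummary]:
    """Split ranked summaries into the top n plus one pooled aggregate.

    The aggregate pools the remaining cases: outcome rates are recomputed
    from pooled counts and the total-wait median is taken over the pooled
    cases.  With fewer than n routes the aggregate is empty (0 cases).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    top, rest = summaries[:n], summaries[n:]
    pooled_counts = {b: sum(s.outcome_counts[b] for s in rest) for b in OUTCOME_BINS}
    pooled_n = sum(s.n_cases for s in rest)
    pooled_waits = (np.concatenate([s.case_total_waits for s in rest])
                    if rest else np.array([]))
    total = pooled_n + sum(s.n_cases for s in top)
    other = RouteSummary(
        route=("other",),
        n_cases=pooled_n,
        pct_of_all=100.0 * pooled_n / total if total else 0.0,
        stage_median_weeks=(float(np.percentile(pooled_waits, 50)) if pooled_n else float("nan"),),
        total_wait_median_weeks=float(np.percentile(pooled_waits, 50)) if pooled_n else float("nan"),
        outcome_counts=pooled_counts,
        outcome_rates={b: (pooled_counts[b] / pooled_n if pooled_n else 0.0) for b in OUTCOME_BINS},
        route_class="other",
        case_total_waits=pooled_waits,
    )
    return top, other


@dataclass
class SteppedCareBreakdown:
    n_common: int         # stepped-care cases on top-N routes
    n_uncommon: int       # stepped-care cases on less common routes
    total_cases: int

    @property
    def n_stepped(self) -> int:
        return self.n_common + self.n_uncommon

    @property
    def pct(self) -> float:
        if self.total_cases == 0:
            raise ZeroDivisionError("total_cases is zero")
        return float((Decimal(self.n_stepped) * 100 / Decimal(self.total_cases))
                     .quantize(Decimal("0.01"), ROUND_HALF_EVEN))


def stepped_care_rate(summaries: list[RouteSummary], total_cases: int,
                      top_n: int = 10) -> SteppedCareBreakdown:
    """Count stepped-care cases on common (top-N) vs less common routes."""
    common = sum(s.n_cases for s in summaries[:top_n] if s.route_class == "stepped_care")
    uncommon = sum(s.n_cases for s in summaries[top_n:] if s.route_class == "stepped_care")
    return SteppedCareBreakdown(n_common=common, n_uncommon=uncommon, total_cases=total_cases)


def wait_comparison(summaries: list[RouteSummary]) -> pd.DataFrame:
    """Treated-vs-attrition total-wait comparison per step, plus step ratio.

    For each step level the most common treated route's total-wait median
    is paired with its waiting-list-attrition counterpart; the difference
    is reported to 1 dp.  A final row gives the step3/step2 treated-route
    ratio (1 dp).  Missing counterparts are omitted with a note.
    """
    def best(cls: str) -> RouteSummary | None:
        cands = [s for s in summaries if s.route_class == cls]
        return cands[0] if cands else None

    rows = []
    for step, treated_cls, attr_cls in (("step2", "step2_only", "attrition_step2_wl"),
                                        ("step3", "step3_only", "attrition_step3_wl")):
        t, a = best(treated_cls), best(attr_cls)
        if t is None or a is None:
            rows.append({"comparison": f"{step}_treated_vs_attrition", "treated_median_weeks": np.nan,
                         "attrition_median_weeks": np.nan, "difference_weeks": np.nan,
                         "note": "missing counterpart route"})
            continue
        rows.append({
            "comparison": f"{step}_treated_vs_attrition",
            "treated_median_weeks": t.total_wait_median_weeks,
            "attrition_median_weeks": a.total_wait_median_weeks,
            "difference_weeks": _round(a.total_wait_median_weeks - t.total_wait_median_weeks, 1),
            "note": "",
        })
    t2, t3 = best("step2_only"), best("step3_only")
    if t2 is not None and t3 is not None and t2.total_wait_median_weeks > 0:
        rows.append({
            "comparison": "step3_vs_step2_treated_ratio",
            "treated_median_weeks": t3.total_wait_median_weeks,
            "attrition_median_weeks": t2.total_wait_median_weeks,
            "difference_weeks": _round(t3.total_wait_median_weeks / t2.total_wait_median_weeks, 1),
            "note": "difference column holds the ratio",
        })
    return pd.DataFrame(rows)


def export_route_plot_data(top: list[RouteSummary],
                           other: RouteSummary | None = None) -> pd.DataFrame:
    """Tabular spec for a stacked-timeline chart of the top routes.

    One row per route × stage with the stage's start offset (cumulative
    preceding stage medians), its width (the stage median), and the
    route's outcome rates; deterministic ordering by rank then stage.
    """
    rows = []
    entries = list(enumerate(top, start=1))
    if other is not None and other.n_cases > 0:
        entries.append((len(top) + 1, other))
    for rank, s in entries:
        offset = 0.0
        for i, stage in enumerate(s.route):
            width = s.stage_median_weeks[i]
            row = {
                "rank": rank, "route": s.label, "route_class": s.route_class,
                "n_cases": s.n_cases, "pct_of_all": _round(s.pct_of_all, 2),
                "stage_index": i, "stage": stage,
                "offset_weeks": _round(offset, 3), "width_weeks": _round(width, 3),
                "total_wait_median_weeks": _round(s.total_wait_median_weeks, 1),
            }
            for b in OUTCOME_BINS:
                row[f"rate_{b}"] = _round(s.outcome_rates[b], 4)
            rows.append(row)
            offset += width
    return pd.DataFrame(rows)


def plot_routes(plot_data: pd.DataFrame, path: str) -> None:
    """Render the stacked-timeline route chart to PNG/SVG via matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stages_present = sorted(plot_data["stage"].unique())
    cmap = plt.get_cmap("tab20")
    colors = {s: cmap(i % 20) for i, s in enumerate(stages_present)}
    ranks = sorted(plot_data["rank"].unique())
    fig, ax = plt.subplots(figsize=(10, 0.5 * len(ranks) + 2))
    for rank in ranks:
        sub = plot_data[plot_data["rank"] == rank]
        for _, row in sub.iterrows():
            ax.barh(-rank, row["width_weeks"], left=row["offset_weeks"],
                    color=colors[row["stage"]], edgecolor="white", height=0.8)
    ax.set_yticks([-r for r in ranks])
    labels = plot_data.drop_duplicates("rank").set_index("rank")
    ax.set_yticklabels([f"#{r} (n={labels.loc[r, 'n_cases']})" for r in ranks])
    ax.set_xlabel("median duration (weeks)")
    handles = [plt.Rectangle((0, 0), 1, 1, color=colors[s]) for s in stages_present]
    ax.legend(handles, stages_present, loc="lower right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
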