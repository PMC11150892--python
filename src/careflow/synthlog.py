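"""Seeded synthetic stepped-care event-log generator.

Emulates the movement records a stepped-care psychological-therapies
service accumulates in its care-record system: each referral is received,
joins the assessment waiting list, is assessed and triaged to the step-2
(low-intensity) or step-3 (high-intensity) waiting list, may be stepped
up from step 2 to step 3, and is eventually discharged — with attrition
branches from every waiting list.  Alongside the movements it generates
appointment records (with attendance), per-session outcome-measure scores
with a caseness threshold, and case attributes, and can back-date a
controlled fraction of timestamps to mimic manual data entry that breaks
the true event order.

The generator keeps per-case ground truth (true route, true timestamps,
completion/recovery status) on the returned log so every downstream stage
can be tested against known parameters.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import yaml

from . import stages as st
from .dists import DistSpec
from .eventlog import EventLog, _empty_appointments, _empty_outcomes

_DECISION_POINTS = (
    "post_referral", "assessment_waitlist", "post_assessment",
    "step2_waitlist", "step2_treatment", "step3_waitlist", "step3_treatment",
)

#: raw (pre-abstraction) stage-name variants, exercised by the rename maps
RAW_NAMES = {
    st.REFERRAL: ["Referral received"],
    st.ASSESS_WL: ["Assessment waiting list", "Waiting list (assessment)"],
    st.ASSESSMENT: ["Assessment", "Initial assessment (v1)"],
    st.STEP2_WL: ["Step 2 waiting list"],
    st.STEP2_GSH: ["Guided self-help", "Guided self-help (old)"],
    st.STEP2_CCBT: ["Computerised CBT"],
    st.STEP3_WL: ["Step 3 waiting list"],
    st.STEP3_CBT: ["CBT", "CBT (v1)"],
    st.STEP3_COUNSELLING: ["Counselling"],
    st.STEP3_EMDR: ["EMDR"],
    st.STEP_CHANGE: ["Step change"],
    st.DISCHARGE_PLANNING: ["Discharge planning"],
    st.DISCHARGED: ["Discharged"],
}


class ProfileError(ValueError):
    """A site profile field failed validation."""


_REQUIRED_WAITS = (
    "referral_to_discharge", "referral_to_assessment_wl",
    "assessment_wl_to_discharge", "assessment_wl_to_assessment",
    "assessment_to_discharge", "assessment_to_step2_wl", "assessment_to_step3_wl",
    "step2_wl_to_discharge", "step2_wl_to_treatment",
    "step3_wl_to_discharge", "step3_wl_to_treatment",
    "stepup_to_step3_wl", "treatment_to_discharge_planning",
    "discharge_planning_to_discharge",
)


@dataclass
class OutcomeModel:
    pre_score_mean: float = 16.0
    pre_score_sd: float = 5.0
    caseness_threshold: float = 10.0
    completeness: float = 0.95
    #: probability of recovery given completion and above-caseness start,
    #: keyed by treatment kind ("step2", "step3", "stepped")
    recovery_prob: dict[str, float] = field(
        default_factory=lambda: {"step2": 0.50, "step3": 0.46, "stepped": 0.48})


@dataclass
class SessionModel:
    step2: DistSpec = field(default_factory=lambda: DistSpec("poisson_shifted", {"lam": 5.0, "shift": 1}))
    step3: DistSpec = field(default_factory=lambda: DistSpec("poisson_shifted", {"lam": 7.0, "shift": 1}))
    before_stepup: DistSpec = field(default_factory=lambda: DistSpec("poisson_shifted", {"lam": 2.0, "shift": 1}))
    gap_weeks: DistSpec = field(default_factory=lambda: DistSpec("lognormal", {"median": 1.0, "sigma": 0.3}))


@dataclass
class SiteProfile:
    """Ground-truth parameters for one synthetic service site.

    ``routing`` maps each decision point to a categorical distribution
    over its outcomes (``proceed`` / ``discharge`` / ``step_up`` / step
    labels at triage); ``wait_dists`` gives the waiting-time distribution
    (weeks) of each pathway transition.
    """

    site_name: str
    n_cases: int
    routing: dict[str, dict[str, float]]
    wait_dists: dict[str, DistSpec]
    sessions: SessionModel = field(default_factory=SessionModel)
    attendance_prob: float = 0.895
    attendance_missing_rate: float = 0.004
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    corruption_rate: float = 0.0
    corruption_magnitude: DistSpec = field(
        default_factory=lambda: DistSpec("lognormal", {"median": 2.0, "sigma": 1.0}))
    seed: int = 0
    window_start: datetime = datetime(2019, 6, 1)
    window_end: datetime = datetime(2021, 6, 1)
    attributes: dict = field(default_factory=dict)
    #: probability of emitting the alternative raw name for a stage
    name_variant_prob: float = 0.2
    #: probability a discharge is preceded by a discharge-planning event
    discharge_planning_prob: float = 0.7

    def __post_init__(self) -> None:
        if self.n_cases <= 0:
            raise ProfileError("n_cases must be a positive integer")
        if not 0.0 <= self.corruption_rate <= 1.0:
            raise ProfileError("corruption_rate must lie in [0, 1]")
        if not 0.0 <= self.attendance_prob <= 1.0:
            raise ProfileError("attendance_prob must lie in [0, 1]")
        for point in _DECISION_POINTS:
            if point not in self.routing:
                raise ProfileError(f"routing missing decision point {point!r}")
            probs = self.routing[point]
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ProfileError(
                    f"routing[{point!r}] probabilities sum to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ProfileError(f"routing[{point!r}] has a negative probability")
        for key in _REQUIRED_WAITS:
            if key not in self.wait_dists:
                raise ProfileError(f"wait_dists missing transition {key!r}")
        for name, dist in self.wait_dists.items():
            if dist.family == "lognormal" and dist.params["median"] <= 0:
                raise ProfileError(f"wait_dists[{name!r}] scale must be positive")

    # -- serialisation -----------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "SiteProfile":
        d = dict(d)
        d["wait_dists"] = {k: DistSpec.from_dict(v) for k, v in d["wait_dists"].items()}
        if "sessions" in d:
            d["sessions"] = SessionModel(**{k: DistSpec.from_dict(v) for k, v in d["sessions"].items()})
        if "outcome_model" in d:
            d["outcome_model"] = OutcomeModel(**d["outcome_model"])
        if "corruption" in d:
            corr = d.pop("corruption")
            d["corruption_rate"] = float(corr["rate"])
            d["corruption_magnitude"] = DistSpec.from_dict(corr["magnitude"])
        if "window" in d:
            w = d.pop("window")
            d["window_start"] = _as_datetime(w["start"])
            d["window_end"] = _as_datetime(w["end"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SiteProfile":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _as_datetime(v) -> datetime:
    if isinstance(v, datetime):
        return v
    if hasattr(v, "year") and not isinstance(v, datetime):  # datetime.date
        return datetime(v.year, v.month, v.day)
    return datetime.fromisoformat(str(v))


def load_profile(name_or_path: str, **overrides) -> SiteProfile:
    """Load a packaged profile ("site_a", "site_b") or a YAML file path.

    Keyword overrides replace top-level profile fields (e.g.
    ``n_cases=500, seed=3``).
    """
    if name_or_path in ("site_a", "site_b"):
        ref = importlib.resources.files("careflow.data") / f"{name_or_path}.yaml"
        data = yaml.safe_load(ref.read_text())
    else:
        with open(name_or_path) as fh:
            data = yaml.safe_load(fh)
    data.update(overrides)
    return SiteProfile.from_dict(data)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _choice(rng: np.random.Generator, probs: dict[str, float]) -> str:
    labels = sorted(probs)
    p = np.array([probs[k] for k in labels], dtype=float)
    return labels[rng.choice(len(labels), p=p / p.sum())]


def _raw_name(rng: np.random.Generator, canonical: str, variant_prob: float) -> str:
    names = RAW_NAMES[canonical]
    if len(names) > 1 and rng.random() < variant_prob:
        return names[1]
    return names[0]


def _simulate_case(rng: np.random.Generator, profile: SiteProfile, cid: str, t0: datetime):
    """Simulate one referral; returns (events, appointments, outcomes, truth)."""
    wd = profile.wait_dists
    route: list[str] = [st.REFERRAL]
    times: list[datetime] = [t0]
    appts: list[tuple] = []
    scores: list[tuple] = []

    def advance(stage: str, wait_key: str) -> None:
        wait_weeks = max(float(wd[wait_key].sample(rng)), 1.0 / (7 * 24 * 60))
        times.append(times[-1] + timedelta(days=7 * wait_weeks))
        route.append(stage)

    def sessions_block(stage: str, n_sessions: int, is_treatment: bool = True) -> datetime:
        """Schedule sessions from the current stage-entry time; returns last session time."""
        t = times[-1]
        last = t
        for k in range(n_sessions):
            if k > 0:
                gap = max(float(profile.sessions.gap_weeks.sample(rng)), 0.05)
                t = t + timedelta(days=7 * gap)
            attended: object
            if rng.random() < profile.attendance_missing_rate:
                attended = None
            else:
                attended = bool(rng.random() < profile.attendance_prob)
            appts.append((cid, t, attended, is_treatment))
            last = t
        return last

    kind = "no_treatment"          # treatment kind for outcome realisation
    stepped_up = False

    def treat(step: str) -> None:
        """Run a treatment episode (possibly stepping up), then discharge."""
        nonlocal kind, stepped_up
        if step == "step2":
            choice = _choice(rng, profile.routing["step2_treatment"])
            stage = st.STEP2_GSH if rng.random() < 0.7 else st.STEP2_CCBT
            advance(stage, "step2_wl_to_treatment")
            if choice == "step_up":
                stepped_up = True
                n = int(profile.sessions.before_stepup.sample(rng))
                last = sessions_block(stage, n)
                times.append(last + timedelta(days=1))
                route.append(st.STEP_CHANGE)
                advance(st.STEP3_WL, "stepup_to_step3_wl")
                wl_choice = _choice(rng, profile.routing["step3_waitlist"])
                if wl_choice == "discharge":
                    kind = "step2"  # treated at step 2 only, then WL attrition
                    advance_discharge("step3_wl_to_discharge")
                    return
                kind = "stepped"
                stage3 = _choice(rng, {st.STEP3_CBT: 0.6, st.STEP3_COUNSELLING: 0.3, st.STEP3_EMDR: 0.1})
                advance(stage3, "step3_wl_to_treatment")
                n3 = int(profile.sessions.step3.sample(rng))
                last = sessions_block(stage3, n3)
                finish(last)
                return
            kind = "step2"
            n = int(profile.sessions.step2.sample(rng))
            last = sessions_block(stage, n)
            finish(last)
        else:
            kind = "step3"
            stage3 = _choice(rng, {st.STEP3_CBT: 0.6, st.STEP3_COUNSELLING: 0.3, st.STEP3_EMDR: 0.1})
            advance(stage3, "step3_wl_to_treatment")
            n3 = int(profile.sessions.step3.sample(rng))
            last = sessions_block(stage3, n3)
            finish(last)

    def finish(last_session: datetime) -> None:
        gap = max(float(wd["treatment_to_discharge_planning"].sample(rng)), 0.01)
        t = max(last_session, times[-1]) + timedelta(days=7 * gap)
        if rng.random() < profile.discharge_planning_prob:
            times.append(t)
            route.append(st.DISCHARGE_PLANNING)
            advance(st.DISCHARGED, "discharge_planning_to_discharge")
        else:
            times.append(t)
            route.append(st.DISCHARGED)

    def advance_discharge(wait_key: str) -> None:
        advance(st.DISCHARGED, wait_key)

    # decision tree -------------------------------------------------------
    if _choice(rng, profile.routing["post_referral"]) == "discharge":
        advance_discharge("referral_to_discharge")
    else:
        advance(st.ASSESS_WL, "referral_to_assessment_wl")
        if _choice(rng, profile.routing["assessment_waitlist"]) == "discharge":
            advance_discharge("assessment_wl_to_discharge")
        else:
            advance(st.ASSESSMENT, "assessment_wl_to_assessment")
            # the assessment itself is a non-treatment appointment; a missed
            # first slot is rebooked, so the stage movement still occurs
            if rng.random() < profile.attendance_missing_rate:
                a_attended: object = None
            else:
                a_attended = bool(rng.random() < profile.attendance_prob)
            appts.append((cid, times[-1], a_attended, False))
            triage = _choice(rng, profile.routing["post_assessment"])
            if triage == "discharge":
                advance_discharge("assessment_to_discharge")
            elif triage == "step2":
                advance(st.STEP2_WL, "assessment_to_step2_wl")
                if _choice(rng, profile.routing["step2_waitlist"]) == "discharge":
                    advance_discharge("step2_wl_to_discharge")
                else:
                    treat("step2")
            else:
                advance(st.STEP3_WL, "assessment_to_step3_wl")
                if _choice(rng, profile.routing["step3_waitlist"]) == "discharge":
                    advance_discharge("step3_wl_to_discharge")
                else:
                    treat("step3")

    # outcome scores ------------------------------------------------------
    om = profile.outcome_model
    n_attended = sum(1 for a in appts if a[3] and a[2] is True)
    completed = n_attended >= 2
    recovered: bool | None = None
    has_outcome_data = False
    started_above = None
    if completed and rng.random() < om.completeness:
        has_outcome_data = True
        pre = max(0.0, rng.normal(om.pre_score_mean, om.pre_score_sd))
        started_above = pre >= om.caseness_threshold
        if started_above:
            recovered = bool(rng.random() < om.recovery_prob.get(kind, 0.45))
            post = (rng.uniform(1.0, om.caseness_threshold - 0.5) if recovered
                    else rng.uniform(om.caseness_threshold, om.caseness_threshold + 8.0))
        else:
            post = rng.uniform(0.0, om.caseness_threshold - 0.5)
        n_scores = max(2, n_attended)
        levels = np.linspace(pre, post, n_scores)
        for i, level in enumerate(levels):
            noisy = level if i in (0, n_scores - 1) else max(0.0, level + rng.normal(0, 1.5))
            scores.append((cid, i, float(noisy), bool(noisy >= om.caseness_threshold)))

    # enforce strictly increasing true timestamps (same-day moves get a
    # one-minute separation so the recorded order is recoverable)
    for i in range(1, len(times)):
        if times[i] <= times[i - 1]:
            times[i] = times[i - 1] + timedelta(minutes=1)

    raw_activities = [_raw_name(rng, c, profile.name_variant_prob) for c in route]
    events = [(cid, raw_activities[i], times[i], i) for i in range(len(route))]
    truth = {
        "case_id": cid,
        "true_route": "|".join(route),
        "kind": kind,
        "stepped_up": stepped_up,
        "completed": completed,
        "has_outcome_data": has_outcome_data,
        "started_above_caseness": started_above,
        "recovered": recovered,
        "n_attended_treatment": n_attended,
    }
    return events, appts, scores, truth


def _sample_attributes(rng: np.random.Generator, n: int, attrs: dict) -> pd.DataFrame:
    """Draw case attributes from the profile's categorical tables."""
    def cat(table: dict[str, float]) -> np.ndarray:
        labels = list(table)
        p = np.array([table[k] for k in labels], dtype=float)
        return np.array(labels, dtype=object)[rng.choice(len(labels), size=n, p=p / p.sum())]

    age_spec = attrs.get("age", {"median": 31.0, "sigma": 0.45})
    age = 18 + np.floor(rng.lognormal(np.log(age_spec["median"] - 18), age_spec["sigma"], n))
    gender = cat(attrs.get("gender", {"female": 0.66, "male": 0.33, "nonbinary": 0.005, "unspecified": 0.005}))
    problem = cat(attrs.get("presenting_problem", {"anxiety": 0.32, "depression": 0.27, "unspecified": 0.41}))
    source = cat(attrs.get("referral_source", {"self": 0.9, "gp": 0.05, "other": 0.05}))
    prior = cat(attrs.get("prior_referrals", {"0": 0.85, "1": 0.11, "2": 0.04})).astype(int)
    deciles = attrs.get("imd_deciles", [0.1] * 10)
    p = np.array(deciles, dtype=float)
    imd = rng.choice(np.arange(1, 11), size=n, p=p / p.sum()).astype(float)
    missing = rng.random(n) < attrs.get("imd_missing_rate", 0.005)
    imd[missing] = np.nan
    return pd.DataFrame({
        "age": age, "gender": gender, "presenting_problem": problem,
        "referral_source": source, "imd_decile": imd, "prior_referrals": prior,
    })


def generate_log(profile: SiteProfile) -> EventLog:
    """Generate a synthetic site log from a validated :class:`SiteProfile`.

    Deterministic for a fixed profile (including its seed).  Ground truth
    (true route, pre-corruption timestamps, completion/recovery status)
    is attached at ``log.ground_truth``.
    """
    rng = np.random.default_rng(profile.seed)
    window_days = (profile.window_end - profile.window_start).total_seconds() / 86400.0
    width = len(str(profile.n_cases))

    all_events, all_appts, all_scores, truths = [], [], [], []
    for i in range(profile.n_cases):
        cid = f"{profile.site_name}-{i:0{width}d}"
        t0 = profile.window_start + timedelta(days=float(rng.uniform(0, window_days)))
        t0 = t0.replace(microsecond=0)
        ev, ap, sc, truth = _simulate_case(rng, profile, cid, t0)
        all_events.extend(ev)
        all_appts.extend(ap)
        all_scores.extend(sc)
        truths.append(truth)

    events = pd.DataFrame(all_events, columns=["case_id", "activity", "timestamp", "source_order"])
    events["timestamp"] = pd.to_datetime(events["timestamp"]).dt.floor("s")
    events["imputed"] = False
    events["original_timestamp"] = pd.NaT
    events = events.sort_values(["case_id", "source_order"]).reset_index(drop=True)

    cases = _sample_attributes(rng, profile.n_cases, profile.attributes)
    cases.insert(0, "case_id", [t["case_id"] for t in truths])
    cases = cases.sort_values("case_id").reset_index(drop=True)

    if all_appts:
        appointments = pd.DataFrame(all_appts, columns=["case_id", "datetime", "attended", "is_treatment"])
        appointments["datetime"] = pd.to_datetime(appointments["datetime"]).dt.floor("s")
        appointments["attended"] = appointments["attended"].astype("boolean")
        appointments["is_treatment"] = appointments["is_treatment"].astype(bool)
        appointments = appointments.sort_values(["case_id", "datetime"]).reset_index(drop=True)
    else:
        appointments = _empty_appointments()

    if all_scores:
        outcomes = pd.DataFrame(all_scores, columns=["case_id", "session_index", "score", "above_caseness"])
        outcomes = outcomes.sort_values(["case_id", "session_index"]).reset_index(drop=True)
    else:
        outcomes = _empty_outcomes()

    truth_cases = pd.DataFrame(truths).sort_values("case_id").reset_index(drop=True)
    truth_events = events[["case_id", "source_order", "timestamp"]].copy()
    truth_events = truth_events.rename(columns={"timestamp": "true_timestamp"})
    truth_events["corrupted"] = False

    log = EventLog(events=events, cases=cases, appointments=appointments, outcomes=outcomes,
                   ground_truth={"cases": truth_cases, "events": truth_events})
    if profile.corruption_rate > 0:
        log = corrupt_timestamps(log, profile.corruption_rate, profile.corruption_magnitude,
                                 seed=(profile.seed + 1) % (2 ** 31))
    return log


def corrupt_timestamps(log: EventLog, rate: float, magnitude_dist: DistSpec, seed: int) -> EventLog:
    """Back-date a random fraction of non-first events.

    Each non-first event (by source order) is independently selected with
    probability ``rate``; selected events have their timestamp reduced by
    a draw (weeks) from ``magnitude_dist``, producing an order violation
    whenever the draw exceeds the gap to the preceding event.  Original
    timestamps are kept in the log's ground truth.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"corruption rate must lie in [0, 1], got {rate}")
    out = log.copy()
    ev = out.events
    rng = np.random.default_rng(seed)
    non_first = (ev["source_order"] > 0).to_numpy()
    selected = non_first & (rng.random(len(ev)) < rate)
    offsets_weeks = magnitude_dist.sample(rng, int(selected.sum()))
    offsets = pd.to_timedelta(np.asarray(offsets_weeks, dtype=float) * 7.0, unit="D")

    truth_events = (out.ground_truth or {}).get("events")
    if truth_events is None:
        truth_events = ev[["case_id", "source_order", "timestamp"]].rename(
            columns={"timestamp": "true_timestamp"})
        truth_events["corrupted"] = False
    truth_events = truth_events.copy()
    truth_events.loc[ev.index[selected], "corrupted"] = True

    ev = ev.copy()
    ev.loc[ev.index[selected], "timestamp"] = (
        ev.loc[ev.index[selected], "timestamp"] - offsets.floor("s")
    )
    out.events = ev
    out.ground_truth = dict(out.ground_truth or {})
    out.ground_truth["events"] = truth_events
    return out
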