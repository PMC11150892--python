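"""Shared fixtures: toy event-log builder and small synthetic site logs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from careflow.dists import DistSpec
from careflow.eventlog import EventLog
from careflow.synthlog import SiteProfile, generate_log

BASE = pd.Timestamp("2020-01-01")


def make_log(traces: dict[str, list[tuple[str, float]]],
             appointments: pd.DataFrame | None = None,
             outcomes: pd.DataFrame | None = None,
             cases: pd.DataFrame | None = None) -> EventLog:
    """Build an EventLog from {case_id: [(activity, day_offset), ...]}."""
    rows = []
    for cid, seq in traces.items():
        for i, (activity, day) in enumerate(seq):
            rows.append({"case_id": cid, "activity": activity,
                         "timestamp": BASE + pd.Timedelta(days=day),
                         "source_order": i, "imputed": False,
                         "original_timestamp": pd.NaT})
    events = pd.DataFrame(rows).sort_values(["case_id", "source_order"]).reset_index(drop=True)
    events["original_timestamp"] = pd.to_datetime(events["original_timestamp"])
    if cases is None:
        cases = pd.DataFrame({"case_id": sorted(traces)})
        for col in ("age", "imd_decile"):
            cases[col] = np.nan
        for col in ("gender", "presenting_problem", "referral_source"):
            cases[col] = ""
        cases["prior_referrals"] = 0
    log = EventLog(events=events, cases=cases)
    if appointments is not None:
        appointments = appointments.copy()
        appointments["attended"] = appointments["attended"].astype("boolean")
        appointments["is_treatment"] = appointments["is_treatment"].astype(bool)
        log.appointments = appointments
    if outcomes is not None:
        log.outcomes = outcomes
    return log


def lognorm(median: float, sigma: float = 0.5) -> DistSpec:
    return DistSpec("lognormal", {"median": median, "sigma": sigma})


def make_profile(n_cases: int = 200, seed: int = 0, **overrides) -> SiteProfile:
    """Compact fully-specified test profile; override any top-level field."""
    kwargs = dict(
        site_name="test",
        n_cases=n_cases,
        seed=seed,
        routing={
            "post_referral": {"proceed": 0.8, "discharge": 0.2},
            "assessment_waitlist": {"proceed": 0.9, "discharge": 0.1},
            "post_assessment": {"step2": 0.5, "step3": 0.3, "discharge": 0.2},
            "step2_waitlist": {"proceed": 0.8, "discharge": 0.2},
            "step2_treatment": {"proceed": 0.85, "step_up": 0.15},
            "step3_waitlist": {"proceed": 0.75, "discharge": 0.25},
            "step3_treatment": {"proceed": 1.0},
        },
        wait_dists={
            "referral_to_discharge": lognorm(1.0),
            "referral_to_assessment_wl": lognorm(0.2),
            "assessment_wl_to_assessment": lognorm(4.0),
            "assessment_wl_to_discharge": lognorm(6.0),
            "assessment_to_discharge": lognorm(1.0),
            "assessment_to_step2_wl": lognorm(0.3),
            "assessment_to_step3_wl": lognorm(0.3),
            "step2_wl_to_treatment": lognorm(6.0),
            "step2_wl_to_discharge": lognorm(10.0),
            "step3_wl_to_treatment": lognorm(15.0),
            "step3_wl_to_discharge": lognorm(20.0),
            "stepup_to_step3_wl": lognorm(0.3),
            "treatment_to_discharge_planning": lognorm(1.0),
            "discharge_planning_to_discharge": lognorm(0.3),
        },
    )
    kwargs.update(overrides)
    return SiteProfile(**kwargs)


@pytest.fixture(scope="session")
def site_small() -> EventLog:
    """Small packaged-profile-shaped synthetic log (with corruption)."""
    from careflow.synthlog import load_profile
    return generate_log(load_profile("site_a", n_cases=1500, seed=7))


@pytest.fixture(scope="session")
def site5000() -> EventLog:
    """Clean (uncorrupted) synthetic log at parameter-recovery scale."""
    return generate_log(make_profile(n_cases=5000, seed=11))
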