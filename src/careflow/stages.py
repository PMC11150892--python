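"""Canonical stage vocabulary and stage-role map for stepped-care pathways.

Stage labels (after renaming) describe the journey of one referral through a
stepped-care psychological-therapies service: referral receipt, the
assessment waiting list, assessment and triage, the step-2 (low-intensity)
and step-3 (high-intensity) waiting lists and treatments, and discharge.

Roles drive semantic annotation of process-map edges (waiting-list attrition,
step-up) and route classification; a stage can hold several roles
(``step2_waitlist`` is both a ``waitlist`` and a ``step2`` stage).
"""

from __future__ import annotations

# canonical (post-rename) labels
REFERRAL = "referral_received"
ASSESS_WL = "assessment_waitlist"
ASSESSMENT = "assessment"
STEP2_WL = "step2_waitlist"
STEP2_GSH = "step2_gsh"          # guided self-help
STEP2_CCBT = "step2_ccbt"        # computerised CBT
STEP3_WL = "step3_waitlist"
STEP3_CBT = "step3_cbt"
STEP3_COUNSELLING = "step3_counselling"
STEP3_EMDR = "step3_emdr"
STEP_CHANGE = "step_change"      # administrative step-intensity move
DISCHARGE_PLANNING = "discharge_planning"
DISCHARGED = "discharged"

# subprocess labels introduced by abstraction level B
STEP2_TREATMENT = "step2_treatment"
STEP3_TREATMENT = "step3_treatment"

STEP2_TREATMENTS = frozenset({STEP2_GSH, STEP2_CCBT})
STEP3_TREATMENTS = frozenset({STEP3_CBT, STEP3_COUNSELLING, STEP3_EMDR})

#: role vocabulary: referral, assessment, waitlist, treatment, discharge,
#: step2, step3, admin
DEFAULT_STAGE_ROLES: dict[str, frozenset[str]] = {
    REFERRAL: frozenset({"referral"}),
    ASSESS_WL: frozenset({"waitlist"}),
    ASSESSMENT: frozenset({"assessment"}),
    STEP2_WL: frozenset({"waitlist", "step2"}),
    STEP2_GSH: frozenset({"treatment", "step2"}),
    STEP2_CCBT: frozenset({"treatment", "step2"}),
    STEP2_TREATMENT: frozenset({"treatment", "step2"}),
    STEP3_WL: frozenset({"waitlist", "step3"}),
    STEP3_CBT: frozenset({"treatment", "step3"}),
    STEP3_COUNSELLING: frozenset({"treatment", "step3"}),
    STEP3_EMDR: frozenset({"treatment", "step3"}),
    STEP3_TREATMENT: frozenset({"treatment", "step3"}),
    STEP_CHANGE: frozenset({"admin"}),
    DISCHARGE_PLANNING: frozenset({"admin"}),
    DISCHARGED: frozenset({"discharge"}),
}
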