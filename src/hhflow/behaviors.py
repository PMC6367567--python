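"""Classification of the four WHO hygiene behaviors and the nine sequences.

Before an aseptic delivery flow the WHO guidelines prescribe, in order:

1. rub hands with alcohol-based rub or wash with soap and water;
2. avoid recontaminating the hands until gloves are donned (or until the
   procedure if no gloves are worn);
3. don at least one (new) glove;
4. avoid recontaminating the gloves before the flow starts.

Behaviors 2 and 4 are contingent: Behavior 2 is applicable only when
Behavior 1 was performed, Behavior 4 only when Behavior 3 was. The 3 x 3
contingent combinations give exactly nine mutually exclusive behavior
sequences, Sequence 1 being full compliance and Sequence 9 none of the four.

Interval anchoring: when several washes or dons occur in a window the LAST
event of each kind anchors the recontamination intervals — the most favorable
reading of "avoid recontamination after rubbing/washing". Behavior 2's
interval ends at the FIRST glove don after the last wash, because gloves
shield the hands from then on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .events import Disposition, HandAction, SurfaceCategory
from .segmentation import GloveState, Opportunity, OpportunityStatus


class Verdict(str, Enum):
    PERFORMED = "performed"
    NOT_PERFORMED = "not_performed"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class BehaviorProfile:
    """Verdicts for the four contingent hygiene behaviors of one opportunity."""

    b1_rub_wash: Verdict
    b2_avoid_hand_recontam: Verdict
    b3_don_glove: Verdict
    b4_avoid_glove_recontam: Verdict

    def __post_init__(self) -> None:
        if (self.b2_avoid_hand_recontam is Verdict.NOT_APPLICABLE) != (
            self.b1_rub_wash is not Verdict.PERFORMED
        ):
            raise ValueError("Behavior 2 applicable iff Behavior 1 performed")
        if (self.b4_avoid_glove_recontam is Verdict.NOT_APPLICABLE) != (
            self.b3_don_glove is not Verdict.PERFORMED
        ):
            raise ValueError("Behavior 4 applicable iff Behavior 3 performed")


P, N, NA = Verdict.PERFORMED, Verdict.NOT_PERFORMED, Verdict.NOT_APPLICABLE

# The nine behavior sequences: Sequence 1 is the WHO recommendation, Sequence 9
# is none of the four behaviors.
SEQUENCE_DEFINITIONS: dict[int, BehaviorProfile] = {
    1: BehaviorProfile(P, P, P, P),
    2: BehaviorProfile(P, P, P, N),
    3: BehaviorProfile(P, P, N, NA),
    4: BehaviorProfile(P, N, P, P),
    5: BehaviorProfile(P, N, P, N),
    6: BehaviorProfile(P, N, N, NA),
    7: BehaviorProfile(N, NA, P, P),
    8: BehaviorProfile(N, NA, P, N),
    9: BehaviorProfile(N, NA, N, NA),
}
_PROFILE_TO_SEQUENCE = {v: k for k, v in SEQUENCE_DEFINITIONS.items()}


@dataclass(frozen=True)
class SequenceID:
    id: int

    @property
    def definition(self) -> BehaviorProfile:
        return SEQUENCE_DEFINITIONS[self.id]


class GloveUsePattern(str, Enum):
    """Suboptimal glove behavior practiced when no new glove was donned."""

    REUSED_GLOVES_PREVIOUS_FLOW = "reused_gloves_previous_flow"
    BARE_HANDS = "bare_hands"
    GLOVES_REMOVED_NOT_REPLACED = "gloves_removed_not_replaced"
    OTHER = "other"


@dataclass(frozen=True)
class RubWashQuality:
    technique_adequate: bool | None
    duration_s: float
    duration_ok: bool


MIN_RUB_WASH_DURATION_S = 10.0  # Zanzibar infection-prevention guideline


def _window_rub_washes(o: Opportunity) -> list[HandAction]:
    return [a for a in o.window if a.counts_as_rub_wash()]


def _window_new_dons(o: Opportunity) -> list[HandAction]:
    return [
        a for a in o.window if a.action.code == "glove_don" and a.glove_new is True
    ]


def _window_dons(o: Opportunity) -> list[HandAction]:
    return [a for a in o.window if a.action.code == "glove_don"]


def _touches_between(
    window: Sequence[HandAction], lo_idx: int, hi_idx: int | None
) -> list[HandAction]:
    """Recontaminating touches strictly between two window positions."""
    hi = len(window) if hi_idx is None else hi_idx
    return [
        a
        for a in window[lo_idx + 1 : hi]
        if a.disposition is Disposition.RECONTAMINATING_TOUCH
    ]


def hand_recontamination_touches(o: Opportunity) -> list[HandAction]:
    """Touches between the last rub/wash and the first subsequent glove don
    (or the flow start when no don follows)."""
    washes = _window_rub_washes(o)
    if not washes:
        return []
    wash_idx = max(i for i, a in enumerate(o.window) if a is washes[-1])
    don_idx = None
    for i in range(wash_idx + 1, len(o.window)):
        if o.window[i].action.code == "glove_don":
            don_idx = i
            break
    return _touches_between(o.window, wash_idx, don_idx)


def glove_recontamination_touches(o: Opportunity) -> list[HandAction]:
    """Touches between the last glove don and the flow start."""
    dons = _window_dons(o)
    if not dons:
        return []
    don_idx = max(i for i, a in enumerate(o.window) if a is dons[-1])
    return _touches_between(o.window, don_idx, None)


def evaluate_behaviors(opportunity: Opportunity) -> BehaviorProfile:
    """Evaluate Behaviors 1-4 on an analyzable opportunity's window."""
    if opportunity.status is not OpportunityStatus.ANALYZABLE:
        raise ValueError(
            f"behaviors are evaluated on analyzable opportunities only, "
            f"got status {opportunity.status.value!r}"
        )
    b1 = P if _window_rub_washes(opportunity) else N
    if b1 is P:
        b2 = N if hand_recontamination_touches(opportunity) else P
    else:
        b2 = NA
    b3 = P if _window_new_dons(opportunity) else N
    if b3 is P:
        b4 = N if glove_recontamination_touches(opportunity) else P
    else:
        b4 = NA
    return BehaviorProfile(b1, b2, b3, b4)


def assign_sequence(profile: BehaviorProfile) -> SequenceID:
    """Map a contingent behavior profile to its sequence class (1-9)."""
    try:
        return SequenceID(_PROFILE_TO_SEQUENCE[profile])
    except KeyError:
        raise ValueError(f"profile violates the contingency rules: {profile}")


def classify_glove_pattern(
    opportunity: Opportunity, profile: BehaviorProfile
) -> GloveUsePattern:
    """Describe the suboptimal glove behavior when no new glove was donned."""
    if profile.b3_don_glove is P:
        raise ValueError("glove pattern applies only when Behavior 3 not performed")
    window = opportunity.window
    removes = [a for a in window if a.action.code == "glove_remove"]
    dons = _window_dons(opportunity)
    state = opportunity.glove_state_at_window_start
    if state is GloveState.GLOVED_USED and not removes:
        return GloveUsePattern.REUSED_GLOVES_PREVIOUS_FLOW
    if state is GloveState.BARE and not removes and not dons:
        return GloveUsePattern.BARE_HANDS
    if removes:
        last_remove_idx = max(
            i for i, a in enumerate(window) if a.action.code == "glove_remove"
        )
        new_don_after = any(
            a.action.code == "glove_don" and a.glove_new is True
            for a in window[last_remove_idx + 1 :]
        )
        if not new_don_after:
            return GloveUsePattern.GLOVES_REMOVED_NOT_REPLACED
    return GloveUsePattern.OTHER


def score_rub_wash(
    opportunity: Opportunity, session_end_t: float | None = None
) -> RubWashQuality:
    """Technique and duration quality of the (last) rub/wash in the window.

    The instrument logs action start times only, so duration is the gap from
    the rub/wash to the next recorded action (end of session if none).
    """
    washes = _window_rub_washes(opportunity)
    if not washes:
        raise ValueError("no rub/wash action in window")
    last = washes[-1]
    later_ts = [a.t for a in opportunity.window if a.t > last.t]
    later_ts.append(opportunity.flow.start_t)
    next_t = min(later_ts)
    if next_t <= last.t and session_end_t is not None:
        next_t = session_end_t
    duration = max(0.0, next_t - last.t)
    return RubWashQuality(
        technique_adequate=last.technique_adequate,
        duration_s=duration,
        duration_ok=duration >= MIN_RUB_WASH_DURATION_S,
    )


class TallyPhase(str, Enum):
    AFTER_RUB_WASH = "after_rub_wash"
    AFTER_GLOVE_DON = "after_glove_don"


@dataclass
class SurfaceTally:
    """Recontaminating-touch counts by surface for one phase.

    ``n_failed_opportunities`` counts opportunities where the relevant
    avoidance behavior was not performed; every touch in the phase interval of
    those opportunities is attributed to its surface category.
    """

    phase: TallyPhase
    counts: dict[SurfaceCategory, int]
    n_failed_opportunities: int
    n_touches: int
    mean_touches: float | None
    sd_touches: float | None
    min_touches: int | None
    max_touches: int | None

    def surface_percent(self, surface: SurfaceCategory) -> float | None:
        if self.n_touches == 0:
            return None
        return 100.0 * self.counts.get(surface, 0) / self.n_touches


def tally_recontamination(
    classified: Iterable[tuple[Opportunity, BehaviorProfile]],
    phase: TallyPhase,
) -> SurfaceTally:
    """Tally recontaminating touches over the failures of one phase."""
    if not isinstance(phase, TallyPhase):
        raise ValueError(f"unknown tally phase {phase!r}")
    counts: dict[SurfaceCategory, int] = {}
    per_opp: list[int] = []
    for opp, profile in classified:
        if phase is TallyPhase.AFTER_RUB_WASH:
            if profile.b2_avoid_hand_recontam is not N:
                continue
            touches = hand_recontamination_touches(opp)
        else:
            if profile.b4_avoid_glove_recontam is not N:
                continue
            touches = glove_recontamination_touches(opp)
        per_opp.append(len(touches))
        for t in touches:
            surf = t.action.surface_category
            counts[surf] = counts.get(surf, 0) + 1
    n_failed = len(per_opp)
    n_touches = sum(per_opp)
    if n_failed == 0:
        return SurfaceTally(phase, counts, 0, 0, None, None, None, None)
    mean = n_touches / n_failed
    if n_failed > 1:
        sd = math.sqrt(sum((x - mean) ** 2 for x in per_opp) / (n_failed - 1))
    else:
        sd = None
    return SurfaceTally(
        phase=phase,
        counts=counts,
        n_failed_opportunities=n_failed,
        n_touches=n_touches,
        mean_touches=mean,
        sd_touches=sd,
        min_touches=min(per_opp),
        max_touches=max(per_opp),
    )


def classify_opportunities(
    opportunities: Iterable[Opportunity],
) -> list[tuple[Opportunity, BehaviorProfile, SequenceID]]:
    """Evaluate and sequence-classify every analyzable opportunity."""
    out = []
    for o in opportunities:
        if o.status is not OpportunityStatus.ANALYZABLE:
            continue
        profile = evaluate_behaviors(o)
        out.append((o, profile, assign_sequence(profile)))
    return out
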