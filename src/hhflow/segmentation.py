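"""Segmentation of action streams into delivery flows and HH opportunities.

A *delivery flow* is a maximal run of aseptic procedures interleaved only
with actions exclusive to the patient zone (and, once the flow has started,
glove changes and rinsing with water, which guidelines permit mid-flow). Each
flow constitutes exactly one hand-hygiene opportunity: the *window* of actions
between the previous boundary and the flow's first procedure is where the four
hygiene behaviors are evaluated.

Boundaries and rules, in the order the state machine applies them:

* A ``BREAKING`` action (deliberate activity outside the workflow) terminates
  any open flow and resets the window: hygiene performed before it does not
  carry over to the next opportunity.
* A ``RECONTAMINATING_TOUCH`` before any procedure stays in the window (it
  feeds Behaviors 2 and 4); once a flow has started it terminates the flow and
  becomes the first action of the next window.
* ``FLOW_NEUTRAL`` actions never break a flow.
* ``glove_don`` / ``glove_remove`` / ``hand_rinse_water`` are window actions
  before the first procedure and permitted interleaved actions after it.
  A hand rub/wash once a flow has started closes the flow and opens the next
  window (washing entails leaving the patient zone), with the wash credited
  to the new window.

The first opportunity of a session can be *censored* when its window is
truncated by the start of observation, and any opportunity with contradictory
duplicate hygiene records is flagged *inconsistent*; both are excluded from
analysis denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import yaml

from .events import (
    Disposition,
    HandAction,
    ObservationSession,
    SoapSeen,
)


class OpportunityStatus(str, Enum):
    ANALYZABLE = "analyzable"
    CENSORED = "censored"
    INCONSISTENT = "inconsistent"


class GloveState(str, Enum):
    """Glove state of the attendant's hands at a window start."""

    BARE = "bare"
    GLOVED_USED = "gloved_used"
    UNKNOWN = "unknown"


@dataclass
class SegmentationConfig:
    """Tunables for segmentation and censoring.

    min_lead_seconds: minimum observed lead time before the first flow of a
        session for its opportunity to be analyzable (the study never
        quantifies "too close to the start"; 60 s is the default and is
        echoed in output metadata).
    strict_taxonomy: reject unknown action codes when reading logs.
    """

    min_lead_seconds: float = 60.0
    strict_taxonomy: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "SegmentationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class DeliveryFlow:
    """A maximal unbroken run of aseptic procedures (one HH opportunity)."""

    procedures: list[HandAction]
    interleaved: list[HandAction] = field(default_factory=list)

    @property
    def start_t(self) -> float:
        return self.procedures[0].t

    @property
    def end_t(self) -> float:
        return self.procedures[-1].t


@dataclass
class Opportunity:
    """A pre-flow window plus the delivery flow it precedes."""

    session_id: str
    attendant_id: str
    facility_id: str
    index_in_session: int
    window: list[HandAction]
    flow: DeliveryFlow
    window_start_t: float
    glove_state_at_window_start: GloveState = GloveState.UNKNOWN
    status: OpportunityStatus = OpportunityStatus.ANALYZABLE

    @property
    def is_first_of_session(self) -> bool:
        return self.index_in_session == 0

    @property
    def window_duration(self) -> float:
        return self.flow.start_t - self.window_start_t

    def window_has_hygiene(self) -> bool:
        return any(a.disposition is Disposition.HYGIENE for a in self.window)


_MIDFLOW_ALLOWED_HYGIENE = {"glove_don", "glove_remove", "hand_rinse_water"}


def segment_session(
    session: ObservationSession, config: SegmentationConfig | None = None
) -> list[Opportunity]:
    """Partition one session's stream into HH opportunities.

    Requires tie-break-resolved, time-ordered actions (as produced by
    ``read_event_log``); raises ``ValueError`` otherwise. Censoring and
    inconsistency flags are applied before returning.
    """
    config = config or SegmentationConfig()
    actions = session.actions
    for a, b in zip(actions, actions[1:]):
        if b.t < a.t:
            raise ValueError(
                f"session {session.session_id}: actions not time-ordered"
            )

    opportunities: list[Opportunity] = []
    window: list[HandAction] = []
    window_start = session.start_t
    window_glove_state = _initial_glove_state(actions)
    glove_state = window_glove_state
    flow: DeliveryFlow | None = None

    def close_flow() -> None:
        nonlocal flow
        flow = None

    def open_window(start_t: float, first: HandAction | None = None) -> None:
        nonlocal window, window_start, window_glove_state
        window = [] if first is None else [first]
        window_start = start_t
        window_glove_state = glove_state

    for a in actions:
        disp = a.disposition
        if disp is Disposition.SESSION_MARKER:
            continue  # metadata; consumed by _initial_glove_state
        if flow is None:
            if disp is Disposition.FLOW_PROCEDURE:
                flow = DeliveryFlow(procedures=[a])
                opportunities.append(
                    Opportunity(
                        session_id=session.session_id,
                        attendant_id=session.attendant_id,
                        facility_id=session.facility_id,
                        index_in_session=len(opportunities),
                        window=window,
                        flow=flow,
                        window_start_t=window_start,
                        glove_state_at_window_start=window_glove_state,
                    )
                )
            elif disp is Disposition.BREAKING:
                open_window(a.t)
            else:
                window.append(a)
        else:
            if disp is Disposition.FLOW_PROCEDURE:
                flow.procedures.append(a)
            elif disp is Disposition.FLOW_NEUTRAL or (
                disp is Disposition.HYGIENE
                and a.action.code in _MIDFLOW_ALLOWED_HYGIENE
            ):
                flow.interleaved.append(a)
            elif disp is Disposition.RECONTAMINATING_TOUCH:
                end_t = flow.end_t
                close_flow()
                open_window(end_t, first=a)
            elif disp is Disposition.HYGIENE:  # rub/wash mid-flow
                end_t = flow.end_t
                close_flow()
                open_window(end_t, first=a)
            else:  # BREAKING
                close_flow()
                open_window(a.t)
        glove_state = _update_glove_state(glove_state, a)

    return [
        flag_inconsistent(apply_censoring(o, config)) for o in opportunities
    ]


def _initial_glove_state(actions: Sequence[HandAction]) -> GloveState:
    """Glove state at session start, from an observer marker if present."""
    for a in actions:
        if a.disposition is Disposition.SESSION_MARKER:
            if a.action.code == "session_start_gloved":
                return GloveState.GLOVED_USED
            if a.action.code == "session_start_bare":
                return GloveState.BARE
        else:
            break
    return GloveState.UNKNOWN


def _update_glove_state(state: GloveState, a: HandAction) -> GloveState:
    if a.action.code == "glove_don":
        return GloveState.GLOVED_USED
    if a.action.code == "glove_remove":
        return GloveState.BARE
    return state


def apply_censoring(
    opportunity: Opportunity, config: SegmentationConfig | None = None
) -> Opportunity:
    """Censor a first-of-session opportunity with a truncated window.

    Only the first opportunity of a session, whose window begins at the start
    of observation (no prior out-of-workflow boundary), can be censored: when
    the observed lead time is shorter than ``min_lead_seconds``, or when the
    glove state is unknown and no hygiene action was seen, the hygiene
    behaviors cannot be determined.
    """
    config = config or SegmentationConfig()
    if opportunity.status is not OpportunityStatus.ANALYZABLE:
        return opportunity
    if not opportunity.is_first_of_session:
        return opportunity
    short = opportunity.window_duration < config.min_lead_seconds
    uninformative = (
        opportunity.glove_state_at_window_start is GloveState.UNKNOWN
        and not opportunity.window_has_hygiene()
    )
    if short or uninformative:
        return replace(opportunity, status=OpportunityStatus.CENSORED)
    return opportunity


def flag_inconsistent(opportunity: Opportunity) -> Opportunity:
    """Flag opportunities whose window holds contradictory hygiene records.

    The observers' tool can emit duplicate records for one action; when two
    rub/wash records at the same instant disagree on soap use or technique,
    the information is contradictory and the opportunity is excluded from all
    downstream denominators.
    """
    if opportunity.status is not OpportunityStatus.ANALYZABLE:
        return opportunity
    washes = [
        a
        for a in opportunity.window
        if a.action.code in ("hand_rub", "hand_wash")
    ]
    by_t: dict[tuple[float, str], list[HandAction]] = {}
    for w in washes:
        by_t.setdefault((w.t, w.action.code), []).append(w)
    for group in by_t.values():
        if len(group) < 2:
            continue
        soaps = {w.soap_seen for w in group if w.soap_seen is not None}
        techs = {w.technique_adequate for w in group if w.technique_adequate is not None}
        if len(soaps) > 1 or len(techs) > 1:
            return replace(opportunity, status=OpportunityStatus.INCONSISTENT)
    return opportunity


def segment_sessions(
    sessions: Sequence[ObservationSession],
    config: SegmentationConfig | None = None,
) -> list[Opportunity]:
    """Segment every session; concatenated in session order."""
    out: list[Opportunity] = []
    for s in sessions:
        out.extend(segment_session(s, config))
    return out


def opportunities_table(opportunities: Sequence[Opportunity]):
    """One row per opportunity (ids, status, window/flow boundaries)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "session_id": [o.session_id for o in opportunities],
            "attendant_id": [o.attendant_id for o in opportunities],
            "facility_id": [o.facility_id for o in opportunities],
            "index_in_session": [o.index_in_session for o in opportunities],
            "status": [o.status.value for o in opportunities],
            "window_start_t": [o.window_start_t for o in opportunities],
            "flow_start_t": [o.flow.start_t for o in opportunities],
            "flow_end_t": [o.flow.end_t for o in opportunities],
            "n_window_actions": [len(o.window) for o in opportunities],
            "n_procedures": [len(o.flow.procedures) for o in opportunities],
            "glove_state_at_window_start": [
                o.glove_state_at_window_start.value for o in opportunities
            ],
        }
    )
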