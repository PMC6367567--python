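from __future__ import annotations

import numpy as np
import pytest

import hhflow as h
from hhflow.events import HandAction, SoapSeen, default_taxonomy

TAX = default_taxonomy()


def make_action(code, t, rec, session="S1", **attrs):
    """Convenience constructor for a HandAction with the default taxonomy."""
    return HandAction(
        session_id=session,
        attendant_id="A1",
        facility_id="F1",
        observer_id="O1",
        t=float(t),
        action=TAX[code],
        record_index=rec,
        **attrs,
    )


def make_session(codes_and_attrs, session_id="S1", start_t=0.0):
    """Build a session from (code, t) or (code, t, attrs) tuples."""
    actions = []
    for rec, item in enumerate(codes_and_attrs):
        code, t, *rest = item
        attrs = rest[0] if rest else {}
        actions.append(make_action(code, t, rec, session=session_id, **attrs))
    s = h.ObservationSession(
        session_id=session_id,
        attendant_id="A1",
        facility_id="F1",
        observer_id="O1",
        shift="morning",
        actions=h.resolve_simultaneous(actions),
        start_t=start_t,
    )
    return s


# Code pool for random stream generation, weighted toward the interesting
# interactions (procedures, hygiene, touches).
STREAM_POOL = [
    "vaginal_exam",
    "catch_baby",
    "cord_cut_clamp",
    "touch_patient_zone",
    "carry_placenta",
    "touch_patient_bed",
    "touch_glove_pack",
    "touch_other_unclean",
    "leave_room",
    "blood_pressure",
    "hand_wash",
    "hand_rub",
    "glove_don",
    "glove_remove",
    "hand_rinse_water",
]


def random_stream(rng: np.random.Generator, max_len: int = 30):
    """A random tie-resolved action stream exercising every rule."""
    n = int(rng.integers(0, max_len + 1))
    actions = []
    t = 0.0
    for rec in range(n):
        code = STREAM_POOL[int(rng.integers(len(STREAM_POOL)))]
        t += float(rng.choice([0.0, 1.0, 5.0, 30.0, 120.0]))
        attrs = {}
        if code == "hand_wash":
            attrs["soap_seen"] = [
                SoapSeen.SEEN,
                SoapSeen.NOT_SEEN,
                SoapSeen.PRESUMED,
                None,
            ][int(rng.integers(4))]
        if code in ("hand_wash", "hand_rub"):
            attrs["technique_adequate"] = [True, False, None][int(rng.integers(3))]
        if code == "glove_don":
            attrs["glove_new"] = [True, False, None][int(rng.integers(3))]
        actions.append(make_action(code, t, rec, **attrs))
    if rng.random() < 0.3:
        marker = "session_start_gloved" if rng.random() < 0.5 else "session_start_bare"
        actions.insert(0, make_action(marker, 0.0, n))
    return h.resolve_simultaneous(actions)


@pytest.fixture(scope="session")
def fixture_sessions():
    return h.build_canonical_fixture()


@pytest.fixture(scope="session")
def fixture_report(fixture_sessions):
    return h.analyze_sessions(
        fixture_sessions, h.PipelineConfig(compute_icc=False)
    )


@pytest.fixture(scope="session")
def fixture_classified(fixture_sessions):
    return h.classify_opportunities(h.segment_sessions(fixture_sessions))
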