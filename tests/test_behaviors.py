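"""Behavior evaluation, sequence assignment, glove patterns, tallies."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import hhflow as h
from hhflow.behaviors import (
    NA,
    N,
    P,
    SEQUENCE_DEFINITIONS,
    TallyPhase,
)
from hhflow.segmentation import (
    DeliveryFlow,
    GloveState,
    Opportunity,
    OpportunityStatus,
)

from .conftest import make_action
from .oracles import oracle_behaviors


def make_opportunity(window_items, glove_state=GloveState.BARE, status=None):
    """Build an Opportunity directly from (code, t, attrs) window items."""
    actions = []
    for rec, item in enumerate(window_items):
        code, t, *rest = item
        attrs = rest[0] if rest else {}
        actions.append(make_action(code, t, rec, **attrs))
    flow_t = (actions[-1].t + 15) if actions else 100.0
    flow = DeliveryFlow(procedures=[make_action("vaginal_exam", flow_t, 900)])
    return Opportunity(
        session_id="S1",
        attendant_id="A1",
        facility_id="F1",
        index_in_session=1,
        window=actions,
        flow=flow,
        window_start_t=0.0,
        glove_state_at_window_start=glove_state,
        status=status or OpportunityStatus.ANALYZABLE,
    )


WASH = ("hand_wash", None, {"soap_seen": h.SoapSeen.SEEN})
TOUCH = ("touch_glove_pack", None)
DON = ("glove_don", None, {"glove_new": True})


def timed(items, start=100, gap=15):
    return [
        (code, start + i * gap, *rest) for i, (code, _, *rest) in enumerate(items)
    ]


class TestEvaluateBehaviors:
    def test_touch_between_wash_and_don_fails_b2(self):
        o = make_opportunity(timed([WASH, TOUCH, DON]))
        p = h.evaluate_behaviors(o)
        assert (p.b1_rub_wash, p.b2_avoid_hand_recontam) == (P, N)
        assert (p.b3_don_glove, p.b4_avoid_glove_recontam) == (P, P)

    def test_don_only_window(self):
        p = h.evaluate_behaviors(make_opportunity(timed([DON])))
        assert (p.b1_rub_wash, p.b2_avoid_hand_recontam) == (N, NA)
        assert (p.b3_don_glove, p.b4_avoid_glove_recontam) == (P, P)

    def test_empty_window_with_carried_gloves(self):
        o = make_opportunity([], glove_state=GloveState.GLOVED_USED)
        p = h.evaluate_behaviors(o)
        assert p == h.BehaviorProfile(N, NA, N, NA)

    def test_touch_after_don_fails_b4_not_b2(self):
        p = h.evaluate_behaviors(make_opportunity(timed([WASH, DON, TOUCH])))
        assert p == h.BehaviorProfile(P, P, P, N)

    def test_used_glove_don_does_not_count_for_b3(self):
        o = make_opportunity(
            timed([("glove_don", None, {"glove_new": False})])
        )
        p = h.evaluate_behaviors(o)
        assert p.b3_don_glove is N

    def test_soap_not_seen_wash_does_not_count_for_b1(self):
        o = make_opportunity(
            timed([("hand_wash", None, {"soap_seen": h.SoapSeen.NOT_SEEN})])
        )
        assert h.evaluate_behaviors(o).b1_rub_wash is N

    def test_last_wash_anchors_the_interval(self):
        # touch between two washes is forgiven; the last wash restores
        # clean hands
        o = make_opportunity(timed([WASH, TOUCH, WASH, DON]))
        assert h.evaluate_behaviors(o) == h.BehaviorProfile(P, P, P, P)

    def test_rejects_non_analyzable_opportunity(self):
        o = make_opportunity([], status=OpportunityStatus.CENSORED)
        with pytest.raises(ValueError, match="analyzable"):
            h.evaluate_behaviors(o)

    def test_all_wash_touch_don_words_match_brute_force_oracle(self):
        """Exhaustive check: every ordering of {wash, touch, don} of length
        <= 4 agrees with an oracle that scans every inter-event interval."""
        symbols = {"w": WASH, "t": TOUCH, "d": DON}
        n_checked = 0
        for length in range(5):
            for word in itertools.product("wtd", repeat=length):
                o = make_opportunity(timed([symbols[c] for c in word]))
                got = h.evaluate_behaviors(o)
                want = oracle_behaviors(o.window)
                mark = {P: "P", N: "N", NA: "-"}
                assert (
                    mark[got.b1_rub_wash],
                    mark[got.b2_avoid_hand_recontam],
                    mark[got.b3_don_glove],
                    mark[got.b4_avoid_glove_recontam],
                ) == want, word
                n_checked += 1
        assert n_checked == 121

    def test_contingency_invariant_on_random_windows(self):
        rng = np.random.default_rng(17)
        pool = [WASH, TOUCH, DON, ("glove_remove", None),
                ("hand_rub", None), ("touch_patient_bed", None),
                ("glove_don", None, {"glove_new": False})]
        for _ in range(500):
            items = [pool[i] for i in rng.integers(len(pool), size=rng.integers(0, 6))]
            p = h.evaluate_behaviors(make_opportunity(timed(items)))
            assert (p.b2_avoid_hand_recontam is NA) == (p.b1_rub_wash is not P)
            assert (p.b4_avoid_glove_recontam is NA) == (p.b3_don_glove is not P)
            h.assign_sequence(p)  # every emitted profile maps to a sequence

    def test_adding_touch_after_don_only_degrades_b4(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(0, 4))
            items = [[WASH, DON][int(rng.integers(2))] for _ in range(n)] + [DON]
            base = make_opportunity(timed(items))
            aug = make_opportunity(timed(items + [TOUCH]))
            p0, p1 = h.evaluate_behaviors(base), h.evaluate_behaviors(aug)
            if p0.b4_avoid_glove_recontam is P:
                assert p1.b4_avoid_glove_recontam is N
            assert not (
                p0.b4_avoid_glove_recontam is N and p1.b4_avoid_glove_recontam is P
            )


class TestAssignSequence:
    def test_who_sequence_is_one_and_nothing_is_nine(self):
        assert h.assign_sequence(h.BehaviorProfile(P, P, P, P)).id == 1
        assert h.assign_sequence(h.BehaviorProfile(N, NA, N, NA)).id == 9

    def test_nine_valid_profiles_give_nine_distinct_ids(self):
        ids = {h.assign_sequence(p).id for p in SEQUENCE_DEFINITIONS.values()}
        assert ids == set(range(1, 10))

    def test_contingency_violation_rejected(self):
        with pytest.raises(ValueError):
            h.BehaviorProfile(N, P, P, P)


class TestGlovePattern:
    def test_reused_gloves(self):
        o = make_opportunity([], glove_state=GloveState.GLOVED_USED)
        p = h.evaluate_behaviors(o)
        assert h.classify_glove_pattern(o, p) is h.GloveUsePattern.REUSED_GLOVES_PREVIOUS_FLOW

    def test_bare_hands(self):
        o = make_opportunity([], glove_state=GloveState.BARE)
        p = h.evaluate_behaviors(o)
        assert h.classify_glove_pattern(o, p) is h.GloveUsePattern.BARE_HANDS

    def test_removed_not_replaced(self):
        o = make_opportunity(
            timed([("glove_remove", None)]), glove_state=GloveState.GLOVED_USED
        )
        p = h.evaluate_behaviors(o)
        assert (
            h.classify_glove_pattern(o, p)
            is h.GloveUsePattern.GLOVES_REMOVED_NOT_REPLACED
        )

    def test_decision_table(self):
        """Enumerate (state, remove?, used-don?) combinations against the
        written decision rules."""
        for state in GloveState:
            for has_remove in (False, True):
                for has_used_don in (False, True):
                    items = []
                    if has_remove:
                        items.append(("glove_remove", None))
                    if has_used_don:
                        items.append(("glove_don", None, {"glove_new": False}))
                    o = make_opportunity(timed(items), glove_state=state)
                    p = h.evaluate_behaviors(o)
                    got = h.classify_glove_pattern(o, p)
                    if state is GloveState.GLOVED_USED and not has_remove:
                        want = h.GloveUsePattern.REUSED_GLOVES_PREVIOUS_FLOW
                    elif (
                        state is GloveState.BARE
                        and not has_remove
                        and not has_used_don
                    ):
                        want = h.GloveUsePattern.BARE_HANDS
                    elif has_remove:
                        want = h.GloveUsePattern.GLOVES_REMOVED_NOT_REPLACED
                    else:
                        want = h.GloveUsePattern.OTHER
                    assert got is want, (state, has_remove, has_used_don)

    def test_rejects_when_b3_performed(self):
        o = make_opportunity(timed([DON]))
        p = h.evaluate_behaviors(o)
        with pytest.raises(ValueError):
            h.classify_glove_pattern(o, p)


class TestScoreRubWash:
    def test_duration_from_gap_to_next_action(self):
        o = make_opportunity([("hand_wash", 100, WASH[2]),
                              ("glove_don", 112, {"glove_new": True})])
        q = h.score_rub_wash(o)
        assert q.duration_s == 12 and q.duration_ok

    def test_short_gap_fails_duration(self):
        o = make_opportunity([("hand_wash", 100, WASH[2]),
                              ("glove_don", 105, {"glove_new": True})])
        q = h.score_rub_wash(o)
        assert q.duration_s == 5 and not q.duration_ok

    def test_wash_alone_measures_to_flow_start(self):
        o = make_opportunity([("hand_wash", 100, WASH[2])])
        assert h.score_rub_wash(o).duration_s == 15.0

    def test_technique_taken_from_last_wash(self):
        o = make_opportunity(
            [
                ("hand_wash", 100, {"soap_seen": h.SoapSeen.SEEN, "technique_adequate": False}),
                ("hand_wash", 120, {"soap_seen": h.SoapSeen.SEEN, "technique_adequate": True}),
            ]
        )
        assert h.score_rub_wash(o).technique_adequate is True

    def test_no_wash_rejected(self):
        with pytest.raises(ValueError):
            h.score_rub_wash(make_opportunity([]))

    def test_fixture_technique_marginal(self, fixture_classified):
        sess_opps = [
            (o, p) for o, p, _ in fixture_classified if p.b1_rub_wash is P
        ]
        adequate = sum(
            1 for o, _ in sess_opps if h.score_rub_wash(o).technique_adequate
        )
        assert (adequate, len(sess_opps)) == (59, 192)


class TestTally:
    def test_no_failures_gives_empty_tally(self):
        o = make_opportunity(timed([WASH, DON]))
        p = h.evaluate_behaviors(o)
        tally = h.tally_recontamination([(o, p)], TallyPhase.AFTER_RUB_WASH)
        assert tally.n_failed_opportunities == 0
        assert tally.n_touches == 0
        assert tally.mean_touches is None

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError):
            h.tally_recontamination([], "sideways")

    def test_counts_conserved(self):
        rng = np.random.default_rng(3)
        pool = [WASH, TOUCH, DON, ("touch_patient_bed", None)]
        pairs = []
        for _ in range(200):
            items = [pool[i] for i in rng.integers(len(pool), size=rng.integers(0, 6))]
            o = make_opportunity(timed(items))
            pairs.append((o, h.evaluate_behaviors(o)))
        for phase in TallyPhase:
            tally = h.tally_recontamination(pairs, phase)
            assert sum(tally.counts.values()) == tally.n_touches

    def test_fixture_tallies(self, fixture_classified):
        pairs = [(o, p) for o, p, _ in fixture_classified]
        wash = h.tally_recontamination(pairs, TallyPhase.AFTER_RUB_WASH)
        assert (wash.n_touches, wash.n_failed_opportunities) == (78, 60)
        assert wash.counts[h.SurfaceCategory.GLOVE_PACK] == 37
        don = h.tally_recontamination(pairs, TallyPhase.AFTER_GLOVE_DON)
        assert (don.n_touches, don.n_failed_opportunities) == (275, 188)
        assert don.counts[h.SurfaceCategory.PATIENT_OUTSIDE_ZONE] == 154
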