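"""Independent reference implementations used only as test oracles.

These are deliberately written in a different style from the package code
(index scanning and brute-force interval enumeration rather than a streaming
state machine) so that agreement is informative.
"""

from __future__ import annotations

import math
from fractions import Fraction

from hhflow.events import Disposition, HandAction
from hhflow.segmentation import GloveState

_MIDFLOW_OK = {"glove_don", "glove_remove", "hand_rinse_water"}


def _is_ignorable_inside_flow(a: HandAction) -> bool:
    d = a.disposition
    return (
        d is Disposition.FLOW_NEUTRAL
        or d is Disposition.SESSION_MARKER
        or (d is Disposition.HYGIENE and a.action.code in _MIDFLOW_OK)
    )


def oracle_segment(actions, session_start_t=0.0):
    """Exhaustive index-scanning segmentation oracle.

    Returns a list of dicts with window/flow record indices, window start
    time and glove state at window start, for a tie-resolved action list.
    """
    idx = list(range(len(actions)))
    proc_idx = [
        i for i in idx if actions[i].disposition is Disposition.FLOW_PROCEDURE
    ]
    # Group procedures into flows: consecutive procedures stay in one flow
    # iff everything strictly between them is ignorable inside a flow.
    flows: list[list[int]] = []
    for i in proc_idx:
        if flows:
            prev = flows[-1][-1]
            between = actions[prev + 1 : i]
            if all(_is_ignorable_inside_flow(a) for a in between):
                flows[-1].append(i)
                continue
        flows.append([i])

    # Initial glove state from a leading observer marker.
    init_state = GloveState.UNKNOWN
    for a in actions:
        if a.disposition is Disposition.SESSION_MARKER:
            if a.action.code == "session_start_gloved":
                init_state = GloveState.GLOVED_USED
            elif a.action.code == "session_start_bare":
                init_state = GloveState.BARE
        else:
            break

    def state_before(index: int) -> GloveState:
        state = init_state
        for a in actions[:index]:
            if a.action.code == "glove_don":
                state = GloveState.GLOVED_USED
            elif a.action.code == "glove_remove":
                state = GloveState.BARE
        return state

    out = []
    for f_no, flow in enumerate(flows):
        start = flow[0]
        prev_flow_end = flows[f_no - 1][-1] if f_no else -1
        # Actions between the previous flow's last procedure and the action
        # that terminated it belong to that flow; the next window begins at
        # the terminator itself (a touch or mid-flow rub/wash) — unless a
        # later BREAKING action resets the window.
        if f_no == 0:
            term = 0  # no previous flow: the window opens at session start
        else:
            term = start
            for j in range(prev_flow_end + 1, start):
                if not _is_ignorable_inside_flow(actions[j]):
                    term = j
                    break
        last_breaking = None
        for j in range(term, start):
            if actions[j].disposition is Disposition.BREAKING:
                last_breaking = j
        if last_breaking is not None:
            boundary_t = actions[last_breaking].t
            content_from = last_breaking + 1
        else:
            boundary_t = (
                actions[prev_flow_end].t if prev_flow_end >= 0 else session_start_t
            )
            content_from = term
        window = [
            j
            for j in range(content_from, start)
            if actions[j].disposition is not Disposition.SESSION_MARKER
        ]
        first_content = window[0] if window else start
        out.append(
            {
                "window": [actions[i].record_index for i in window],
                "procedures": [actions[i].record_index for i in flow],
                "window_start_t": boundary_t,
                "glove_state": state_before(first_content),
            }
        )
    return out


def oracle_behaviors(window, flow_has_started_at=None):
    """Brute-force behavior evaluation by scanning every inter-event interval.

    ``window`` is a list of HandAction; returns (b1, b2, b3, b4) as strings
    'P'/'N'/'-'. Independent of the package's interval-anchoring code.
    """
    def is_wash(a):
        return a.counts_as_rub_wash()

    def is_don_new(a):
        return a.action.code == "glove_don" and a.glove_new is True

    def is_don(a):
        return a.action.code == "glove_don"

    def is_touch(a):
        return a.disposition is Disposition.RECONTAMINATING_TOUCH

    b1 = any(is_wash(a) for a in window)
    b3 = any(is_don_new(a) for a in window)
    b2 = "-"
    if b1:
        last_wash = max(i for i, a in enumerate(window) if is_wash(a))
        end = len(window)
        for i in range(last_wash + 1, len(window)):
            if is_don(window[i]):
                end = i
                break
        bad = any(
            is_touch(window[i]) for i in range(last_wash + 1, end)
        )
        b2 = "N" if bad else "P"
    b4 = "-"
    if b3:
        last_don = max(i for i, a in enumerate(window) if is_don(a))
        bad = any(is_touch(window[i]) for i in range(last_don + 1, len(window)))
        b4 = "N" if bad else "P"
    return ("P" if b1 else "N", b2, "P" if b3 else "N", b4)


def oracle_clopper_pearson(k: int, n: int, alpha: float = 0.05):
    """Exact binomial interval by bisecting the binomial tail sums."""

    def upper_tail(p: float) -> float:  # P(X >= k)
        return sum(
            math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)
        )

    def lower_tail(p: float) -> float:  # P(X <= k)
        return sum(
            math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(0, k + 1)
        )

    def bisect(f, target, lo, hi, increasing):
        for _ in range(100):
            mid = (lo + hi) / 2
            if (f(mid) < target) == increasing:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    lo = 0.0 if k == 0 else bisect(upper_tail, alpha / 2, 0.0, 1.0, True)
    hi = 1.0 if k == n else bisect(lower_tail, alpha / 2, 0.0, 1.0, False)
    return lo, hi
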