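"""Synthetic event-stream generation.

Two generators share one low-level session builder:

* :func:`simulate_event_log` draws attendant random intercepts on the
  log-odds scale for each of the four behaviors and emits raw action streams
  realizing the sampled behavior profiles — the statistical structure the
  analysis pipeline assumes, with known ground truth for parameter-recovery
  tests.

* :func:`build_canonical_fixture` deterministically emits a raw event log
  that, run through the full pipeline, reproduces the marginal counts of the
  Zanzibar study: 914 candidate opportunities (127 censored, 6 inconsistent,
  781 analyzable), sequence counts (75, 52, 5, 35, 21, 4, 194, 115, 280),
  154 reused-glove opportunities within Sequence 9, 78 post-wash touches over
  60 failures and 275 post-don touches over 188 failures with the published
  per-surface splits, 59/192 adequate-technique and 12/192 hand-rub
  opportunities, spread over 104 attendants, 10 facilities and 336 sessions
  with 65 attendants contributing >= 5 analyzable opportunities.

  The per-sequence allocation is a feasible reconstruction: it is derived
  from the published marginals (which pin it down essentially uniquely), not
  from the unreleased opportunity-level dataset. Timestamps are schematic
  (fixed gaps); only ordering and gap thresholds matter downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

from .events import (
    ActionCode,
    HandAction,
    ObservationSession,
    SoapSeen,
    SurfaceCategory,
    default_taxonomy,
)

_TAX = default_taxonomy()

_SURFACE_TO_CODE = {
    SurfaceCategory.GLOVE_PACK: "touch_glove_pack",
    SurfaceCategory.UNCLEAN_DRYING_MATERIAL: "touch_drying_material",
    SurfaceCategory.PATIENT_OUTSIDE_ZONE: "touch_patient_outside_zone",
    SurfaceCategory.PERSONAL_BAG: "touch_personal_bag",
    SurfaceCategory.UNCLEAN_DELIVERY_SURFACE: "touch_unclean_delivery_surface",
    SurfaceCategory.PATIENT_BED: "touch_patient_bed",
    SurfaceCategory.WASTE_BIN: "touch_waste_bin",
    SurfaceCategory.TROLLEY: "touch_trolley",
    SurfaceCategory.HH_OBJECT: "touch_hh_object",
    SurfaceCategory.OTHER_UNCLEAN: "touch_other_unclean",
}

# Within-block gap between consecutive actions (s) and stride between
# opportunity blocks (s). Schematic values: large enough that rub/wash
# duration (gap to next action) exceeds the 10 s guideline and the first
# window exceeds the default 60 s censoring lead.
_GAP = 15.0
_STRIDE = 500.0
_FIRST_BLOCK_T = 100.0


@dataclass
class _OppSpec:
    """What one emitted opportunity should classify as."""

    kind: str  # s1..s8, s9_reused, s9_bare, censored, inconsistent
    rub: bool = False  # hand_rub instead of hand_wash
    technique_adequate: bool = False
    postwash_touches: list[SurfaceCategory] = field(default_factory=list)
    postdon_touches: list[SurfaceCategory] = field(default_factory=list)


_HAS_WASH = {"s1", "s2", "s3", "s4", "s5", "s6"}
_HAS_DON = {"s1", "s2", "s4", "s5", "s7", "s8"}
# Per-session emission order: gloved contexts first so reused-glove
# opportunities find gloves on the attendant's hands.
_KIND_RANK = {
    **{k: 0 for k in _HAS_DON},
    "s9_reused": 1,
    "s3": 2,
    "s6": 2,
    "s9_bare": 2,
    "inconsistent": 3,
}


class _SessionBuilder:
    """Emits schematic raw actions for a sequence of opportunity specs."""

    def __init__(
        self,
        session_id: str,
        attendant_id: str,
        facility_id: str,
        observer_id: str,
        shift: str,
    ):
        self.session = ObservationSession(
            session_id=session_id,
            attendant_id=attendant_id,
            facility_id=facility_id,
            observer_id=observer_id,
            shift=shift,
        )
        self._rec = 0
        self._gloved = False

    def _emit(self, t: float, code: str, **attrs) -> None:
        self.session.actions.append(
            HandAction(
                session_id=self.session.session_id,
                attendant_id=self.session.attendant_id,
                facility_id=self.session.facility_id,
                observer_id=self.session.observer_id,
                t=t,
                action=_TAX[code],
                record_index=self._rec,
                **attrs,
            )
        )
        self._rec += 1
        if code == "glove_don":
            self._gloved = True
        elif code == "glove_remove":
            self._gloved = False

    def build(self, specs: Sequence[_OppSpec], leading_censored: bool) -> None:
        specs = sorted(specs, key=lambda s: _KIND_RANK[s.kind])
        marker = (
            "session_start_gloved"
            if specs and specs[0].kind == "s9_reused"
            else "session_start_bare"
        )
        self._emit(0.0, marker)
        self._gloved = marker == "session_start_gloved"
        block = 0
        if leading_censored:
            # Procedure almost immediately after observation starts: the
            # pre-flow window is truncated and the opportunity is censored.
            self._emit(5.0, "vaginal_exam")
            self._emit(40.0, "leave_room")
        for i, spec in enumerate(specs):
            t = _FIRST_BLOCK_T + _STRIDE * block
            if block > 0 or leading_censored:
                self._emit(t - 50.0, "leave_room")
            t = self._emit_window(t, spec)
            self._emit(t, "vaginal_exam")
            block += 1
        # Trailing out-of-workflow activity so the session has a realistic
        # observed duration.
        last_t = self.session.actions[-1].t
        self._emit(last_t + 800.0, "leave_room")
        self.session.end_t = self.session.actions[-1].t

    def _emit_window(self, t: float, spec: _OppSpec) -> float:
        """Emit window actions starting at t; returns the flow start time."""
        kind = spec.kind
        if kind == "inconsistent":
            # Duplicate wash records at one instant disagreeing on soap use.
            self._emit(t, "hand_wash", soap_seen=SoapSeen.SEEN)
            self._emit(t, "hand_wash", soap_seen=SoapSeen.NOT_SEEN)
            return t + _GAP
        if kind == "s9_reused":
            return t  # empty window; gloves carried in from previous flow
        if kind == "s9_bare":
            if self._gloved:
                self._emit(t, "glove_remove")
                t += _GAP
            return t
        if kind in _HAS_WASH:
            if spec.rub:
                self._emit(t, "hand_rub", technique_adequate=spec.technique_adequate)
            else:
                self._emit(
                    t,
                    "hand_wash",
                    soap_seen=SoapSeen.SEEN,
                    technique_adequate=spec.technique_adequate,
                )
            t += _GAP
        for surf in spec.postwash_touches:
            self._emit(t, _SURFACE_TO_CODE[surf])
            t += _GAP
        if kind in _HAS_DON:
            self._emit(t, "glove_don", glove_new=True)
            t += _GAP
        for surf in spec.postdon_touches:
            self._emit(t, _SURFACE_TO_CODE[surf])
            t += _GAP
        return t


# ---------------------------------------------------------------------------
# Canonical fixture
# ---------------------------------------------------------------------------

#: Published marginal counts the fixture must reproduce.
FIXTURE_SPEC = {
    "n_candidates": 914,
    "n_censored": 127,
    "n_inconsistent": 6,
    "n_analyzable": 781,
    "sequence_counts": {1: 75, 2: 52, 3: 5, 4: 35, 5: 21, 6: 4, 7: 194, 8: 115, 9: 280},
    "s9_reused_gloves": 154,
    "n_rub_wash": 192,
    "n_hand_rub": 12,
    "n_technique_adequate": 59,
    "n_glove_don": 492,
    "b2_performed": 132,
    "b4_performed": 304,
    "postwash_failures": 60,
    "postwash_touches": 78,
    "postdon_failures": 188,
    "postdon_touches": 275,
    "postwash_surfaces": {
        SurfaceCategory.GLOVE_PACK: 37,
        SurfaceCategory.UNCLEAN_DRYING_MATERIAL: 16,
        SurfaceCategory.OTHER_UNCLEAN: 13,
        SurfaceCategory.PATIENT_OUTSIDE_ZONE: 7,
        SurfaceCategory.PERSONAL_BAG: 4,
        SurfaceCategory.UNCLEAN_DELIVERY_SURFACE: 1,
    },
    "postdon_surfaces": {
        SurfaceCategory.OTHER_UNCLEAN: 45,
        SurfaceCategory.PATIENT_OUTSIDE_ZONE: 154,
        SurfaceCategory.PERSONAL_BAG: 6,
        SurfaceCategory.UNCLEAN_DELIVERY_SURFACE: 55,
        SurfaceCategory.PATIENT_BED: 14,
        SurfaceCategory.WASTE_BIN: 1,
    },
    "n_attendants": 104,
    "n_facilities": 10,
    "n_sessions": 336,
    "attendants_with_5plus": 65,
}

_FACILITY_SIZES = [4, 6, 8, 10, 10, 11, 12, 12, 13, 18]  # 104 attendants


def verify_fixture_marginals(spec: dict = FIXTURE_SPEC) -> None:
    """Integer-constraint check: the derived allocation satisfies every
    published marginal simultaneously. Raises AssertionError otherwise."""
    sc = spec["sequence_counts"]
    assert sum(sc.values()) == spec["n_analyzable"] == 781
    assert spec["n_candidates"] == (
        spec["n_analyzable"] + spec["n_censored"] + spec["n_inconsistent"]
    )
    b1 = sc[1] + sc[2] + sc[3] + sc[4] + sc[5] + sc[6]
    b3 = sc[1] + sc[2] + sc[4] + sc[5] + sc[7] + sc[8]
    assert b1 == spec["n_rub_wash"] == 192
    assert b3 == spec["n_glove_don"] == 492
    both = sc[1] + sc[2] + sc[4] + sc[5]
    assert both == b1 + b3 - (spec["n_analyzable"] - sc[9])  # union = 501
    assert sc[1] + sc[2] + sc[3] == spec["b2_performed"] == 132
    assert sc[4] + sc[5] + sc[6] == spec["postwash_failures"] == 60
    assert sc[1] + sc[4] + sc[7] == spec["b4_performed"] == 304
    assert sc[2] + sc[5] + sc[8] == spec["postdon_failures"] == 188
    # recontamination-risk union among opportunities with behavior 1 or 3:
    risk = spec["postwash_failures"] + spec["postdon_failures"] - sc[5]
    assert risk == 227
    assert sum(spec["postwash_surfaces"].values()) == spec["postwash_touches"] == 78
    assert sum(spec["postdon_surfaces"].values()) == spec["postdon_touches"] == 275
    assert spec["s9_reused_gloves"] == 154 and sc[9] == 280
    assert sum(_FACILITY_SIZES) == spec["n_attendants"] == 104


def _fixture_opp_specs() -> list[_OppSpec]:
    """The 781 analyzable opportunity specs in canonical global order."""
    sc = FIXTURE_SPEC["sequence_counts"]
    kinds: list[str] = []
    for s in range(1, 9):
        kinds += [f"s{s}"] * sc[s]
    kinds += ["s9_reused"] * FIXTURE_SPEC["s9_reused_gloves"]
    kinds += ["s9_bare"] * (sc[9] - FIXTURE_SPEC["s9_reused_gloves"])
    specs = [_OppSpec(kind=k) for k in kinds]

    wash_ops = [s for s in specs if s.kind in _HAS_WASH]
    for s in wash_ops[: FIXTURE_SPEC["n_hand_rub"]]:
        s.rub = True
    for s in wash_ops[: FIXTURE_SPEC["n_technique_adequate"]]:
        s.technique_adequate = True

    # Post-wash touches over the behavior-2 failures (sequences 4, 5, 6):
    # distribute the 78 touches as evenly as the totals allow.
    b2_fail = [s for s in specs if s.kind in ("s4", "s5", "s6")]
    _allocate_touches(
        b2_fail,
        FIXTURE_SPEC["postwash_surfaces"],
        FIXTURE_SPEC["postwash_touches"],
        "postwash_touches",
    )
    # Post-don touches over the behavior-4 failures (sequences 2, 5, 8).
    b4_fail = [s for s in specs if s.kind in ("s2", "s5", "s8")]
    _allocate_touches(
        b4_fail,
        FIXTURE_SPEC["postdon_surfaces"],
        FIXTURE_SPEC["postdon_touches"],
        "postdon_touches",
    )
    return specs


def _allocate_touches(
    failures: list[_OppSpec],
    surfaces: dict[SurfaceCategory, int],
    n_touches: int,
    attr: str,
) -> None:
    n_fail = len(failures)
    extra = n_touches - n_fail  # opportunities receiving a second touch
    flat: list[SurfaceCategory] = []
    for surf, cnt in surfaces.items():
        flat += [surf] * cnt
    pos = 0
    for i, spec in enumerate(failures):
        take = 2 if i < extra else 1
        getattr(spec, attr).extend(flat[pos : pos + take])
        pos += take
    assert pos == n_touches


def _fixture_attendant_quotas() -> list[tuple[str, str, int, int]]:
    """(attendant_id, facility_id, n_analyzable, n_sessions) for 104 attendants.

    65 attendants contribute >= 5 analyzable opportunities (40 with 10 and 25
    with 9), 39 contribute 4; session counts total 336 with every attendant
    observed 1-9 times.
    """
    facilities: list[str] = []
    for f, size in enumerate(_FACILITY_SIZES, start=1):
        facilities += [f"F{f:02d}"] * size
    quotas = []
    for i in range(104):
        if i < 40:
            n_opp = 10
        elif i < 65:
            n_opp = 9
        else:
            n_opp = 4
        if i < 63:
            n_sess = 4
        elif i < 65:
            n_sess = 3
        else:
            n_sess = 2
        quotas.append((f"A{i + 1:03d}", facilities[i], n_opp, n_sess))
    assert sum(q[3] for q in quotas) == FIXTURE_SPEC["n_sessions"]
    assert sum(q[2] for q in quotas) == FIXTURE_SPEC["n_analyzable"]
    return quotas


def build_canonical_fixture() -> list[ObservationSession]:
    """Deterministically build the canonical raw event log (no randomness)."""
    verify_fixture_marginals()
    specs = _fixture_opp_specs()
    # Deterministic interleaving so each attendant receives a mix of
    # sequence kinds (37 is coprime to 781).
    order = sorted(range(781), key=lambda i: (i * 37) % 781)
    dealt = [specs[i] for i in order]

    quotas = _fixture_attendant_quotas()
    sessions: list[ObservationSession] = []
    pos = 0
    session_no = 0
    shifts = ["morning", "evening", "night"]
    per_session_specs: list[tuple[tuple[str, str, str, str], list[_OppSpec]]] = []
    for att_id, fac_id, n_opp, n_sess in quotas:
        mine = dealt[pos : pos + n_opp]
        pos += n_opp
        # Split across sessions as evenly as possible.
        base, rem = divmod(n_opp, n_sess)
        sizes = [base + 1] * rem + [base] * (n_sess - rem)
        j = 0
        for size in sizes:
            session_no += 1
            key = (
                f"S{session_no:03d}",
                att_id,
                fac_id,
                f"O{(session_no - 1) % 3 + 1}",
            )
            per_session_specs.append((key, mine[j : j + size]))
            j += size
    assert pos == 781 and session_no == 336

    n_censored = FIXTURE_SPEC["n_censored"]
    n_inconsistent = FIXTURE_SPEC["n_inconsistent"]
    for idx, ((sid, att, fac, obs), opp_specs) in enumerate(per_session_specs):
        opp_specs = list(opp_specs)
        if idx >= len(per_session_specs) - n_inconsistent:
            opp_specs.append(_OppSpec(kind="inconsistent"))
        builder = _SessionBuilder(sid, att, fac, obs, shifts[idx % 3])
        builder.build(opp_specs, leading_censored=idx < n_censored)
        sessions.append(builder.session)
    return sessions


# ---------------------------------------------------------------------------
# Stochastic simulator
# ---------------------------------------------------------------------------

#: Default surface mixes, proportional to the published tally columns.
_POSTWASH_SURFACE_PROBS = {
    SurfaceCategory.GLOVE_PACK: 37 / 78,
    SurfaceCategory.UNCLEAN_DRYING_MATERIAL: 16 / 78,
    SurfaceCategory.OTHER_UNCLEAN: 13 / 78,
    SurfaceCategory.PATIENT_OUTSIDE_ZONE: 7 / 78,
    SurfaceCategory.PERSONAL_BAG: 4 / 78,
    SurfaceCategory.UNCLEAN_DELIVERY_SURFACE: 1 / 78,
}
_POSTDON_SURFACE_PROBS = {
    SurfaceCategory.OTHER_UNCLEAN: 45 / 275,
    SurfaceCategory.PATIENT_OUTSIDE_ZONE: 154 / 275,
    SurfaceCategory.PERSONAL_BAG: 6 / 275,
    SurfaceCategory.UNCLEAN_DELIVERY_SURFACE: 55 / 275,
    SurfaceCategory.PATIENT_BED: 14 / 275,
    SurfaceCategory.WASTE_BIN: 1 / 275,
}


@dataclass
class SimulationParams:
    """Generator settings emulating the study's structure.

    Baseline log-odds default to the logits of the observed marginal
    compliance rates (b1 24.6%, b2 68.8% of applicable, b3 63.0%, b4 61.8%
    of applicable); random-intercept SDs default to values implying the
    published between-attendant ICCs (0.28, 0.10, 0.04, 0.08) under the
    latent-threshold model. Touch counts are zero-truncated Poisson with
    rates matching the published means of 1.3 and 1.5 touches per failure.
    """

    seed: int
    n_facilities: int = 10
    attendants_per_facility: int = 10
    sessions_per_attendant: tuple[int, int] = (1, 6)
    flows_per_session_mean: float = 2.7
    flows_per_session_exact: int | None = None
    beta0_b1: float = -1.120
    beta0_b2: float = 0.788
    beta0_b3: float = 0.532
    beta0_b4: float = 0.481
    sigma_b1: float = 1.131
    sigma_b2: float = 0.605
    sigma_b3: float = 0.370
    sigma_b4: float = 0.535
    touch_rate_postwash: float = 0.55
    touch_rate_postdon: float = 0.88
    postwash_surface_probs: dict = field(
        default_factory=lambda: dict(_POSTWASH_SURFACE_PROBS)
    )
    postdon_surface_probs: dict = field(
        default_factory=lambda: dict(_POSTDON_SURFACE_PROBS)
    )
    censor_fraction: float = 0.14
    inconsistent_fraction: float = 0.007

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("an explicit seed is mandatory")
        for name in (
            "sigma_b1", "sigma_b2", "sigma_b3", "sigma_b4",
            "touch_rate_postwash", "touch_rate_postdon",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("censor_fraction", "inconsistent_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for probs in (self.postwash_surface_probs, self.postdon_surface_probs):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError("surface probabilities must sum to 1")


def _zt_poisson(rng: np.random.Generator, lam: float) -> int:
    """Zero-truncated Poisson draw (at least one touch per failure)."""
    if lam <= 0:
        return 1
    while True:
        k = int(rng.poisson(lam))
        if k > 0:
            return k


def _sample_surfaces(
    rng: np.random.Generator, probs: dict, k: int
) -> list[SurfaceCategory]:
    cats = list(probs.keys())
    p = np.array([probs[c] for c in cats])
    idx = rng.choice(len(cats), size=k, p=p / p.sum())
    return [cats[i] for i in idx]


def simulate_event_log(params: SimulationParams) -> list[ObservationSession]:
    """Simulate raw action-level sessions under the contingent logistic model.

    Per attendant, one random intercept per behavior is drawn on the log-odds
    scale; per opportunity, behaviors are sampled contingently (2 given 1,
    4 given 3) and realized as raw actions. Bit-reproducible per seed.
    """
    rng = np.random.default_rng(params.seed)
    sessions: list[ObservationSession] = []
    shifts = ["morning", "evening", "night"]
    session_no = 0
    att_no = 0
    for f in range(params.n_facilities):
        fac_id = f"F{f + 1:02d}"
        for _ in range(params.attendants_per_facility):
            att_no += 1
            att_id = f"A{att_no:03d}"
            u = {
                b: rng.normal(0.0, getattr(params, f"sigma_{b}"))
                for b in ("b1", "b2", "b3", "b4")
            }
            lo, hi = params.sessions_per_attendant
            n_sess = int(rng.integers(lo, hi + 1))
            for _ in range(n_sess):
                session_no += 1
                if params.flows_per_session_exact is not None:
                    n_flows = params.flows_per_session_exact
                else:
                    n_flows = max(1, int(rng.poisson(params.flows_per_session_mean)))
                specs = [
                    _sample_opp_spec(rng, params, u) for _ in range(n_flows)
                ]
                censored = rng.random() < params.censor_fraction
                builder = _SessionBuilder(
                    f"S{session_no:04d}",
                    att_id,
                    fac_id,
                    f"O{(session_no - 1) % 3 + 1}",
                    shifts[(session_no - 1) % 3],
                )
                builder.build(specs, leading_censored=censored)
                sessions.append(builder.session)
    return sessions


def _sample_opp_spec(
    rng: np.random.Generator, params: SimulationParams, u: dict
) -> _OppSpec:
    if rng.random() < params.inconsistent_fraction:
        return _OppSpec(kind="inconsistent")
    b1 = rng.random() < expit(params.beta0_b1 + u["b1"])
    b3 = rng.random() < expit(params.beta0_b3 + u["b3"])
    b2 = b1 and (rng.random() < expit(params.beta0_b2 + u["b2"]))
    b4 = b3 and (rng.random() < expit(params.beta0_b4 + u["b4"]))
    if b1:
        kind = {True: {True: "s1", False: "s2"}, False: {True: "s4", False: "s5"}}[
            b2
        ][b4] if b3 else ("s3" if b2 else "s6")
    else:
        kind = ("s7" if b4 else "s8") if b3 else "s9_bare"
    spec = _OppSpec(kind=kind)
    if b1:
        spec.rub = rng.random() < 12 / 192
        spec.technique_adequate = rng.random() < 59 / 192
        if not b2:
            k = _zt_poisson(rng, params.touch_rate_postwash)
            spec.postwash_touches = _sample_surfaces(
                rng, params.postwash_surface_probs, k
            )
    if b3 and not b4:
        k = _zt_poisson(rng, params.touch_rate_postdon)
        spec.postdon_touches = _sample_surfaces(rng, params.postdon_surface_probs, k)
    return spec
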