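"""Event data model and I/O for hand-action observation logs.

An observation session is a time-ordered stream of hand actions recorded by a
trained observer shadowing one birth attendant. Each action carries a taxonomy
code that fixes how the segmentation rules treat it:

* ``FLOW_PROCEDURE`` — one of the 12 aseptic procedures of a delivery flow
  (vaginal examination, catching the baby, cord cutting, ...).
* ``FLOW_NEUTRAL`` — hand actions exclusive to the patient zone; they never
  open a new hand-hygiene opportunity.
* ``RECONTAMINATING_TOUCH`` — a touch on a potentially contaminated surface
  (glove pack, bed, trolley, unclean drying material, ...); carries a surface
  category used by the recontamination tally.
* ``BREAKING`` — a deliberate activity outside the workflow (leaving the room,
  measuring blood pressure); it terminates a delivery flow and opens a new
  opportunity.
* ``HYGIENE`` — hand rub/wash, glove donning/removal, rinsing with water.
* ``SESSION_MARKER`` — observer metadata (e.g. glove state at session start).

The on-disk format is UTF-8 delimited text (comma by default, tab accepted)
with columns: session_id, attendant_id, facility_id, observer_id, shift,
t_seconds, action_code, surface_category, soap_seen, technique_adequate,
glove_new, record_index. Empty string means "not applicable". Timestamps are
seconds from session start; only gaps and ordering matter downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("hhflow")

EVENT_LOG_COLUMNS = [
    "session_id",
    "attendant_id",
    "facility_id",
    "observer_id",
    "shift",
    "t_seconds",
    "action_code",
    "surface_category",
    "soap_seen",
    "technique_adequate",
    "glove_new",
    "record_index",
]


class Disposition(str, Enum):
    """How the segmentation rules treat an action code."""

    FLOW_PROCEDURE = "FLOW_PROCEDURE"
    FLOW_NEUTRAL = "FLOW_NEUTRAL"
    RECONTAMINATING_TOUCH = "RECONTAMINATING_TOUCH"
    BREAKING = "BREAKING"
    HYGIENE = "HYGIENE"
    SESSION_MARKER = "SESSION_MARKER"


class SurfaceCategory(str, Enum):
    """Surface classes for recontaminating touches (superset of the tally rows)."""

    GLOVE_PACK = "glove_pack"
    UNCLEAN_DRYING_MATERIAL = "unclean_drying_material"
    PATIENT_OUTSIDE_ZONE = "patient_outside_zone"
    PERSONAL_BAG = "personal_bag"
    UNCLEAN_DELIVERY_SURFACE = "unclean_delivery_surface"
    PATIENT_BED = "patient_bed"
    WASTE_BIN = "waste_bin"
    TROLLEY = "trolley"
    HH_OBJECT = "hh_object"
    OTHER_UNCLEAN = "other_unclean"


class SoapSeen(str, Enum):
    """Observer's record of soap use during a hand wash.

    ``PRESUMED`` covers washes where the observer could not see the action in
    detail; soap use is presumed and the wash counts toward Behavior 1.
    ``NOT_SEEN`` records that soap was positively not used.
    """

    SEEN = "seen"
    NOT_SEEN = "not_seen"
    PRESUMED = "presumed"


# Hygiene codes with a fixed meaning in the behavior rules.
HYGIENE_CODES = frozenset(
    {"hand_rub", "hand_wash", "glove_don", "glove_remove", "hand_rinse_water"}
)
RUB_WASH_CODES = frozenset({"hand_rub", "hand_wash"})

# Tie-break priority when several actions share a timestamp: hygiene actions
# and aseptic procedures outrank touches, which outrank patient-zone actions,
# which outrank out-of-workflow activities. Markers sort first (metadata).
_TIE_RANK = {
    Disposition.SESSION_MARKER: -1,
    Disposition.HYGIENE: 0,
    Disposition.FLOW_PROCEDURE: 0,
    Disposition.RECONTAMINATING_TOUCH: 1,
    Disposition.FLOW_NEUTRAL: 2,
    Disposition.BREAKING: 3,
}


@dataclass(frozen=True)
class ActionCode:
    """A taxonomy entry: code, disposition and (for touches) surface category."""

    code: str
    disposition: Disposition
    surface_category: SurfaceCategory | None = None

    def __post_init__(self) -> None:
        if self.disposition is Disposition.RECONTAMINATING_TOUCH and (
            self.surface_category is None
        ):
            raise ValueError(
                f"recontaminating touch {self.code!r} requires a surface category"
            )


class Taxonomy:
    """The canonical action vocabulary, loadable from a plain-text TSV file."""

    def __init__(self, codes: Iterable[ActionCode]):
        self._codes: dict[str, ActionCode] = {}
        for c in codes:
            if c.code in self._codes:
                raise ValueError(f"duplicate action code {c.code!r} in taxonomy")
            self._codes[c.code] = c

    def __contains__(self, code: str) -> bool:
        return code in self._codes

    def __getitem__(self, code: str) -> ActionCode:
        return self._codes[code]

    def __iter__(self):
        return iter(self._codes.values())

    def __len__(self) -> int:
        return len(self._codes)

    def codes_with(self, disposition: Disposition) -> list[str]:
        return [c.code for c in self._codes.values() if c.disposition is disposition]

    @classmethod
    def from_file(cls, path: str | Path) -> "Taxonomy":
        return cls(_parse_taxonomy_lines(Path(path).read_text().splitlines()))

    @classmethod
    def default(cls) -> "Taxonomy":
        text = (
            resources.files("hhflow").joinpath("data/taxonomy.tsv").read_text()
        )
        return cls(_parse_taxonomy_lines(text.splitlines()))


def _parse_taxonomy_lines(lines: Iterable[str]) -> list[ActionCode]:
    out = []
    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"taxonomy line {lineno}: expected 3 tab-separated fields")
        code, disp, surf = (p.strip() for p in parts)
        out.append(
            ActionCode(
                code=code,
                disposition=Disposition(disp),
                surface_category=None if surf == "-" else SurfaceCategory(surf),
            )
        )
    return out


_DEFAULT_TAXONOMY: Taxonomy | None = None


def default_taxonomy() -> Taxonomy:
    """The shipped taxonomy, loaded once per process."""
    global _DEFAULT_TAXONOMY
    if _DEFAULT_TAXONOMY is None:
        _DEFAULT_TAXONOMY = Taxonomy.default()
    return _DEFAULT_TAXONOMY


@dataclass(frozen=True)
class HandAction:
    """One timestamped observed hand action."""

    session_id: str
    attendant_id: str
    facility_id: str
    observer_id: str
    t: float
    action: ActionCode
    soap_seen: SoapSeen | None = None
    technique_adequate: bool | None = None
    glove_new: bool | None = None
    record_index: int = 0

    def __post_init__(self) -> None:
        if not (self.t >= 0 and self.t == self.t and self.t != float("inf")):
            raise ValueError(f"timestamp must be finite and >= 0, got {self.t}")
        code = self.action.code
        if self.soap_seen is not None and code != "hand_wash":
            raise ValueError("soap_seen applies to hand_wash only")
        if self.technique_adequate is not None and code not in RUB_WASH_CODES:
            raise ValueError("technique_adequate applies to hand_rub/hand_wash only")
        if self.glove_new is not None and code != "glove_don":
            raise ValueError("glove_new applies to glove_don only")

    @property
    def disposition(self) -> Disposition:
        return self.action.disposition

    def counts_as_rub_wash(self) -> bool:
        """True when this action counts as hand rubbing/washing for Behavior 1.

        A hand wash counts when soap was seen or presumed; a wash with soap
        positively not seen is mere rinsing and does not count.
        """
        if self.action.code == "hand_rub":
            return True
        if self.action.code == "hand_wash":
            return self.soap_seen in (SoapSeen.SEEN, SoapSeen.PRESUMED, None)
        return False


@dataclass
class ObservationSession:
    """All actions recorded while shadowing one attendant, time-ordered."""

    session_id: str
    attendant_id: str
    facility_id: str
    observer_id: str
    shift: str
    actions: list[HandAction] = field(default_factory=list)
    start_t: float = 0.0
    end_t: float = 0.0

    def __post_init__(self) -> None:
        if self.actions:
            self.end_t = max(self.end_t, max(a.t for a in self.actions))

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t


class SchemaError(ValueError):
    """Event-log header or vocabulary violation."""


class IntegrityError(ValueError):
    """Duplicate record index or other within-session consistency failure."""


def resolve_simultaneous(actions: Sequence[HandAction]) -> list[HandAction]:
    """Order simultaneous actions by behavioral priority.

    Within a group of actions sharing one timestamp, hygiene actions and
    aseptic procedures come first, then recontaminating touches, then
    patient-zone actions, then out-of-workflow activities; ties within a class
    keep entry order. Nothing is dropped: lower-priority simultaneous actions
    are down-ranked, not deleted.
    """
    return sorted(
        actions, key=lambda a: (a.t, _TIE_RANK[a.disposition], a.record_index)
    )


def _parse_bool(v: str) -> bool:
    if v in ("true", "True", "1"):
        return True
    if v in ("false", "False", "0"):
        return False
    raise ValueError(f"expected boolean, got {v!r}")


def read_event_log(
    path: str | Path,
    strict: bool = True,
    taxonomy: Taxonomy | None = None,
) -> list[ObservationSession]:
    """Read a delimited event log into tie-break-resolved sessions.

    In strict mode an unknown action code raises :class:`SchemaError`; in
    non-strict mode it is logged and kept with disposition ``BREAKING`` (the
    conservative choice: an unknown activity ends the delivery flow and opens
    a new opportunity).
    """
    taxonomy = taxonomy or default_taxonomy()
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"event log {path} missing required columns: {missing}")

    sessions: dict[str, ObservationSession] = {}
    seen_indices: dict[str, set[int]] = {}
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        sid = row.session_id
        code = row.action_code
        try:
            t = float(row.t_seconds)
        except ValueError:
            raise SchemaError(
                f"row {pos}: non-numeric timestamp {row.t_seconds!r}"
            ) from None
        if code in taxonomy:
            action_code = taxonomy[code]
        elif strict:
            raise SchemaError(f"row {pos}: unknown action code {code!r}")
        else:
            logger.warning("row %d: unknown action code %r kept as BREAKING", pos, code)
            action_code = ActionCode(code=code, disposition=Disposition.BREAKING)
        try:
            rec = int(row.record_index)
        except ValueError:
            raise SchemaError(
                f"row {pos}: non-integer record_index {row.record_index!r}"
            ) from None
        if sid not in sessions:
            sessions[sid] = ObservationSession(
                session_id=sid,
                attendant_id=row.attendant_id,
                facility_id=row.facility_id,
                observer_id=row.observer_id,
                shift=row.shift,
            )
            seen_indices[sid] = set()
        if rec in seen_indices[sid]:
            raise IntegrityError(
                f"row {pos}: duplicate record_index {rec} in session {sid!r}"
            )
        seen_indices[sid].add(rec)
        sessions[sid].actions.append(
            HandAction(
                session_id=sid,
                attendant_id=row.attendant_id,
                facility_id=row.facility_id,
                observer_id=row.observer_id,
                t=t,
                action=action_code,
                soap_seen=SoapSeen(row.soap_seen) if row.soap_seen else None,
                technique_adequate=(
                    _parse_bool(row.technique_adequate)
                    if row.technique_adequate
                    else None
                ),
                glove_new=_parse_bool(row.glove_new) if row.glove_new else None,
                record_index=rec,
            )
        )
    out = []
    for s in sessions.values():
        s.actions = resolve_simultaneous(s.actions)
        s.end_t = max((a.t for a in s.actions), default=0.0)
        out.append(s)
    return out


def write_event_log(sessions: Sequence[ObservationSession], path: str | Path) -> None:
    """Write sessions back to the delimited event-log format."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    rows = []
    for s in sessions:
        for a in s.actions:
            rows.append(
                {
                    "session_id": s.session_id,
                    "attendant_id": s.attendant_id,
                    "facility_id": s.facility_id,
                    "observer_id": s.observer_id,
                    "shift": s.shift,
                    "t_seconds": a.t,
                    "action_code": a.action.code,
                    "surface_category": (
                        a.action.surface_category.value
                        if a.action.surface_category
                        else ""
                    ),
                    "soap_seen": a.soap_seen.value if a.soap_seen else "",
                    "technique_adequate": (
                        "" if a.technique_adequate is None
                        else str(a.technique_adequate).lower()
                    ),
                    "glove_new": "" if a.glove_new is None else str(a.glove_new).lower(),
                    "record_index": a.record_index,
                }
            )
    pd.DataFrame(rows, columns=EVENT_LOG_COLUMNS).to_csv(path, sep=sep, index=False)


# Observed plausibility bounds for session duration (seconds): the study's
# sessions ranged from 13 minutes to 6 h 45 min. Outside this range we warn
# but never block.
SESSION_DURATION_RANGE = (13 * 60.0, 6 * 3600.0 + 45 * 60.0)
MAX_SESSIONS_PER_ATTENDANT = 9


@dataclass
class ValidationReport:
    """Per-session warnings and errors from :func:`validate_sessions`."""

    warnings: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_sessions(sessions: Sequence[ObservationSession]) -> ValidationReport:
    """Report-only plausibility checks; warnings never block processing."""
    report = ValidationReport()
    lo, hi = SESSION_DURATION_RANGE
    per_attendant: dict[str, int] = {}
    for s in sessions:
        per_attendant[s.attendant_id] = per_attendant.get(s.attendant_id, 0) + 1
        if not lo <= s.duration <= hi:
            report.warnings.append(
                f"session {s.session_id}: duration {s.duration:.0f}s outside "
                f"observed range [{lo:.0f}, {hi:.0f}]s"
            )
        for a in s.actions:
            if a.t < 0:
                report.errors.append(
                    f"session {s.session_id}: negative timestamp {a.t}"
                )
    for att, n in per_attendant.items():
        if n > MAX_SESSIONS_PER_ATTENDANT:
            report.warnings.append(
                f"attendant {att}: observed in {n} sessions "
                f"(> {MAX_SESSIONS_PER_ATTENDANT})"
            )
    return report
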