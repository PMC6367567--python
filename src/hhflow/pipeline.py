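"""End-to-end pipeline: read -> clean -> segment -> classify -> tally ->
estimate, with a machine-readable run report.

The report mirrors the reporting style of hand-hygiene compliance studies:
attrition (candidate opportunities, censored, inconsistent, analyzable),
per-behavior compliance as "% (95% CI; k/n)", the nine-sequence table, the
suboptimal glove-pattern breakdown, recontamination surface tallies for both
phases, rub/wash quality, and latent-scale ICCs per behavior. Percentages are
printed to one decimal; exact fractions are retained in the JSON document.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from .behaviors import (
    BehaviorProfile,
    GloveUsePattern,
    SequenceID,
    SurfaceTally,
    TallyPhase,
    Verdict,
    classify_glove_pattern,
    classify_opportunities,
    score_rub_wash,
    tally_recontamination,
)
from .events import ObservationSession, read_event_log, validate_sessions
from .segmentation import (
    Opportunity,
    OpportunityStatus,
    SegmentationConfig,
    segment_sessions,
)
from .stats import IccResult, ProportionEstimate, icc_analysis, proportion_ci

logger = logging.getLogger("hhflow")

P = Verdict.PERFORMED
N = Verdict.NOT_PERFORMED


def round1(x: float) -> float:
    """Round half up to one decimal (the printed-percentage convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def percent1(k: int, n: int) -> float:
    return round1(100.0 * k / n)


@dataclass
class PipelineConfig:
    """Single plain-text (YAML) configuration for a pipeline run."""

    min_lead_seconds: float = 60.0
    strict_taxonomy: bool = True
    ci_method: str = "clopper_pearson"
    alpha: float = 0.05
    icc_min_opportunities: int = 5
    icc_bootstrap_B: int = 0  # 0 = point estimates only; >=100 adds CIs
    compute_icc: bool = True
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def segmentation(self) -> SegmentationConfig:
        return SegmentationConfig(
            min_lead_seconds=self.min_lead_seconds,
            strict_taxonomy=self.strict_taxonomy,
        )


@dataclass
class RunReport:
    """Everything one pipeline run computed, JSON-serializable."""

    dataset: dict[str, Any]
    attrition: dict[str, int]
    compliance: dict[str, ProportionEstimate | None]
    sequences: dict[int, ProportionEstimate]
    glove_patterns: dict[str, int]
    s9_reused: ProportionEstimate | None
    tallies: dict[str, SurfaceTally]
    rub_wash_quality: dict[str, Any]
    icc: dict[str, IccResult | None]
    config: dict[str, Any]
    validation_warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        def conv(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {
                    (k.value if hasattr(k, "value") else str(k)): conv(v)
                    for k, v in obj.items()
                }
            if hasattr(obj, "value") and not isinstance(obj, (int, float)):
                return obj.value
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            return obj

        return conv(
            {
                "dataset": self.dataset,
                "attrition": self.attrition,
                "compliance": self.compliance,
                "sequences": self.sequences,
                "glove_patterns": self.glove_patterns,
                "s9_reused": self.s9_reused,
                "tallies": self.tallies,
                "rub_wash_quality": self.rub_wash_quality,
                "icc": self.icc,
                "config": self.config,
                "validation_warnings": self.validation_warnings,
            }
        )

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)


def behavior_outcome_groups(
    classified: Sequence[tuple[Opportunity, BehaviorProfile, SequenceID]],
    behavior: str,
) -> dict[str, list[int]]:
    """Per-attendant binary outcomes for one behavior (applicable opps only)."""
    attr = {
        "b1": "b1_rub_wash",
        "b2": "b2_avoid_hand_recontam",
        "b3": "b3_don_glove",
        "b4": "b4_avoid_glove_recontam",
    }[behavior]
    groups: dict[str, list[int]] = {}
    for opp, profile, _seq in classified:
        verdict = getattr(profile, attr)
        if verdict is Verdict.NOT_APPLICABLE:
            continue
        groups.setdefault(opp.attendant_id, []).append(1 if verdict is P else 0)
    return groups


def analyze_sessions(
    sessions: Sequence[ObservationSession],
    config: PipelineConfig | None = None,
) -> RunReport:
    """Run the full analysis on in-memory sessions."""
    config = config or PipelineConfig()
    validation = validate_sessions(sessions)
    opportunities = segment_sessions(sessions, config.segmentation())
    n_candidates = len(opportunities)
    n_censored = sum(
        1 for o in opportunities if o.status is OpportunityStatus.CENSORED
    )
    n_inconsistent = sum(
        1 for o in opportunities if o.status is OpportunityStatus.INCONSISTENT
    )
    for o in opportunities:
        if o.status is not OpportunityStatus.ANALYZABLE:
            logger.info(
                "opportunity %s#%d excluded: %s",
                o.session_id,
                o.index_in_session,
                o.status.value,
            )
    classified = classify_opportunities(opportunities)
    n = len(classified)

    def prop(k: int, n_: int) -> ProportionEstimate | None:
        if n_ == 0:
            return None
        return proportion_ci(k, n_, method=config.ci_method, alpha=config.alpha)

    b1_k = sum(1 for _, p, _ in classified if p.b1_rub_wash is P)
    b3_k = sum(1 for _, p, _ in classified if p.b3_don_glove is P)
    b2_applicable = [p for _, p, _ in classified if p.b1_rub_wash is P]
    b4_applicable = [p for _, p, _ in classified if p.b3_don_glove is P]
    b2_k = sum(1 for p in b2_applicable if p.b2_avoid_hand_recontam is P)
    b4_k = sum(1 for p in b4_applicable if p.b4_avoid_glove_recontam is P)
    # Opportunities with rubbing/washing or donning in which the applicable
    # avoidance behavior(s) failed: the recontamination-risk share.
    union = [
        p
        for _, p, _ in classified
        if p.b1_rub_wash is P or p.b3_don_glove is P
    ]
    risk_k = sum(
        1
        for p in union
        if p.b2_avoid_hand_recontam is N or p.b4_avoid_glove_recontam is N
    )

    seq_counts = {i: 0 for i in range(1, 10)}
    for _, _, seq in classified:
        seq_counts[seq.id] += 1
    sequences = {
        i: proportion_ci(seq_counts[i], n, method=config.ci_method)
        for i in range(1, 10)
    } if n else {}

    glove_patterns = {p.value: 0 for p in GloveUsePattern}
    s9_reused_k = 0
    s9_n = 0
    for opp, profile, seq in classified:
        if profile.b3_don_glove is P:
            continue
        pattern = classify_glove_pattern(opp, profile)
        glove_patterns[pattern.value] += 1
        if seq.id == 9:
            s9_n += 1
            if pattern is GloveUsePattern.REUSED_GLOVES_PREVIOUS_FLOW:
                s9_reused_k += 1

    pairs = [(o, p) for o, p, _ in classified]
    tallies = {
        "after_rub_wash": tally_recontamination(pairs, TallyPhase.AFTER_RUB_WASH),
        "after_glove_don": tally_recontamination(pairs, TallyPhase.AFTER_GLOVE_DON),
    }

    sess_end = {s.session_id: s.end_t for s in sessions}
    rub_wash_opps = [
        (o, p) for o, p, _ in classified if p.b1_rub_wash is P
    ]
    qualities = [
        score_rub_wash(o, session_end_t=sess_end.get(o.session_id))
        for o, _ in rub_wash_opps
    ]
    n_rub = sum(
        1
        for o, _ in rub_wash_opps
        if any(a.action.code == "hand_rub" for a in o.window)
    )
    rub_wash_quality = {
        "n_rub_wash": len(qualities),
        "n_hand_rub": n_rub,
        "n_technique_adequate": sum(1 for q in qualities if q.technique_adequate),
        "n_duration_ok": sum(1 for q in qualities if q.duration_ok),
    }

    icc: dict[str, IccResult | None] = {}
    if config.compute_icc and n:
        for b in ("b1", "b2", "b3", "b4"):
            groups = behavior_outcome_groups(classified, b)
            for label, min_k in (
                (b, config.icc_min_opportunities),
                (f"{b}_all_attendants", 1),
            ):
                try:
                    icc[label] = icc_analysis(
                        groups,
                        min_opportunities=min_k,
                        bootstrap_B=config.icc_bootstrap_B,
                        seed=config.seed if config.icc_bootstrap_B else None,
                    )
                except (ValueError, RuntimeError) as exc:
                    logger.warning("ICC for %s skipped: %s", label, exc)
                    icc[label] = None

    return RunReport(
        dataset={
            "n_sessions": len(sessions),
            "n_attendants": len({s.attendant_id for s in sessions}),
            "n_facilities": len({s.facility_id for s in sessions}),
            "n_actions": sum(len(s.actions) for s in sessions),
        },
        attrition={
            "candidates": n_candidates,
            "censored": n_censored,
            "inconsistent": n_inconsistent,
            "analyzable": n,
        },
        compliance={
            "b1_rub_wash": prop(b1_k, n),
            "b2_avoid_hand_recontam": prop(b2_k, len(b2_applicable)),
            "b3_don_glove": prop(b3_k, n),
            "b4_avoid_glove_recontam": prop(b4_k, len(b4_applicable)),
            "recontamination_risk": prop(risk_k, len(union)),
            "full_sequence": prop(seq_counts[1], n) if n else None,
        },
        sequences=sequences,
        glove_patterns=glove_patterns,
        s9_reused=(
            proportion_ci(s9_reused_k, s9_n, method=config.ci_method)
            if s9_n
            else None
        ),
        tallies=tallies,
        rub_wash_quality=rub_wash_quality,
        icc=icc,
        config={
            **dataclasses.asdict(config),
            "ci_cluster_adjustment": "none (cluster-naive binomial intervals)",
        },
        validation_warnings=validation.warnings,
    )


def classification_table(
    sessions: Sequence[ObservationSession],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-opportunity classification table (the opportunity-level export)."""
    config = config or PipelineConfig()
    opportunities = segment_sessions(sessions, config.segmentation())
    rows = []
    for o in opportunities:
        row: dict[str, Any] = {
            "session_id": o.session_id,
            "attendant_id": o.attendant_id,
            "facility_id": o.facility_id,
            "index_in_session": o.index_in_session,
            "status": o.status.value,
            "b1": "",
            "b2": "",
            "b3": "",
            "b4": "",
            "sequence_id": "",
            "glove_pattern": "",
            "technique_adequate": "",
            "duration_ok": "",
        }
        if o.status is OpportunityStatus.ANALYZABLE:
            from .behaviors import assign_sequence, evaluate_behaviors

            profile = evaluate_behaviors(o)
            seq = assign_sequence(profile)
            row.update(
                b1=profile.b1_rub_wash.value,
                b2=profile.b2_avoid_hand_recontam.value,
                b3=profile.b3_don_glove.value,
                b4=profile.b4_avoid_glove_recontam.value,
                sequence_id=seq.id,
            )
            if profile.b3_don_glove is not P:
                row["glove_pattern"] = classify_glove_pattern(o, profile).value
            if profile.b1_rub_wash is P:
                q = score_rub_wash(o)
                row["technique_adequate"] = q.technique_adequate
                row["duration_ok"] = q.duration_ok
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    event_log_path: str | Path,
    config_path: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> RunReport:
    """Read an event log, run the full analysis, optionally write outputs.

    Writes (when ``out_dir`` is given): ``report.json``, ``report.txt``,
    ``opportunities.csv``. Partial outputs are removed on failure.
    """
    config = (
        PipelineConfig.from_file(config_path) if config_path else PipelineConfig()
    )
    sessions = read_event_log(event_log_path, strict=config.strict_taxonomy)
    report = analyze_sessions(sessions, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        try:
            p = out / "report.json"
            p.write_text(report.to_json())
            written.append(p)
            p = out / "report.txt"
            p.write_text(render_text_report(report))
            written.append(p)
            p = out / "opportunities.csv"
            classification_table(sessions, config).to_csv(p, index=False)
            written.append(p)
        except Exception:
            for p in written:
                p.unlink(missing_ok=True)
            raise
    return report


_SEQ_MARKS = {
    1: ("Y", "Y", "Y", "Y"),
    2: ("Y", "Y", "Y", "x"),
    3: ("Y", "Y", "x", "-"),
    4: ("Y", "x", "Y", "Y"),
    5: ("Y", "x", "Y", "x"),
    6: ("Y", "x", "x", "-"),
    7: ("x", "-", "Y", "Y"),
    8: ("x", "-", "Y", "x"),
    9: ("x", "-", "x", "-"),
}


def render_sequence_figure_table(report: RunReport) -> pd.DataFrame:
    """The nine-sequence table: behavior marks, n, percent, CI per sequence."""
    rows = []
    for i in range(1, 10):
        est = report.sequences.get(i)
        b1, b2, b3, b4 = _SEQ_MARKS[i]
        rows.append(
            {
                "sequence": i,
                "rub_wash": b1,
                "avoid_hand_recontam": b2,
                "don_gloves": b3,
                "avoid_glove_recontam": b4,
                "n": est.k if est else 0,
                "percent": round1(est.percent) if est else 0.0,
                "ci_low": round1(est.ci_low) if est else None,
                "ci_high": round1(est.ci_high) if est else None,
            }
        )
    return pd.DataFrame(rows)


def render_text_report(report: RunReport) -> str:
    """Human-readable tables mirroring the '% (95% CI; k/n)' style."""
    lines = []
    d = report.dataset
    a = report.attrition
    lines.append(
        f"Dataset: {d['n_sessions']} sessions, {d['n_attendants']} attendants, "
        f"{d['n_facilities']} facilities, {d['n_actions']} actions"
    )
    lines.append(
        f"Opportunities: {a['candidates']} candidates, {a['censored']} censored"
        + (
            f" ({percent1(a['censored'], a['candidates'])}%)"
            if a["candidates"]
            else ""
        )
        + f", {a['inconsistent']} inconsistent, {a['analyzable']} analyzable"
    )
    lines.append("")
    lines.append("Compliance:")
    labels = {
        "b1_rub_wash": "1. Rub/wash hands",
        "b2_avoid_hand_recontam": "2. Avoid hand recontamination",
        "b3_don_glove": "3. Don >=1 new glove",
        "b4_avoid_glove_recontam": "4. Avoid glove recontamination",
        "recontamination_risk": "Risked recontamination (1 or 3 done)",
        "full_sequence": "Full WHO sequence (Sequence 1)",
    }
    for key, label in labels.items():
        est = report.compliance.get(key)
        lines.append(f"  {label}: {est if est else 'n/a'}")
    lines.append("")
    lines.append("Behavior sequences:")
    table = render_sequence_figure_table(report)
    lines.append(table.to_string(index=False))
    lines.append("")
    for phase, tally in report.tallies.items():
        lines.append(
            f"Recontaminating touches {phase}: {tally.n_touches} touches over "
            f"{tally.n_failed_opportunities} opportunities"
            + (
                f" (mean {tally.mean_touches:.1f})"
                if tally.mean_touches is not None
                else ""
            )
        )
        for surf, cnt in sorted(
            tally.counts.items(), key=lambda kv: -kv[1]
        ):
            pct = tally.surface_percent(surf)
            lines.append(f"    {surf.value}: {pct:.1f}% ({cnt})")
    lines.append("")
    if report.s9_reused:
        lines.append(f"Sequence 9 with reused gloves: {report.s9_reused}")
    q = report.rub_wash_quality
    if q["n_rub_wash"]:
        lines.append(
            f"Rub/wash quality: technique adequate "
            f"{q['n_technique_adequate']}/{q['n_rub_wash']}, duration >=10 s "
            f"{q['n_duration_ok']}/{q['n_rub_wash']}, hand rub "
            f"{q['n_hand_rub']}/{q['n_rub_wash']}"
        )
    for label, res in report.icc.items():
        if res is None:
            lines.append(f"ICC {label}: not estimable")
        else:
            ci = (
                f" (95% CI, {res.ci_low:.2f}-{res.ci_high:.2f})"
                if res.ci_low is not None
                else ""
            )
            lines.append(
                f"ICC {label}: {res.icc:.2f}{ci} "
                f"[{res.n_attendants} attendants, {res.n_obs} opportunities, "
                f">={res.min_opportunities} each]"
            )
    return "\n".join(lines) + "\n"
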