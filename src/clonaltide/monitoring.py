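"""Longitudinal ctDNA monitoring against clinical timelines.

Links per-mutation dPCR detection series to a patient's clinical course
(surgery at day 0, chemotherapy epochs, imaging findings) to call molecular
relapse, measure the lead time of ctDNA over imaging, and assign the
clinical-validity categories a personalised ctDNA assay can deliver: early
relapse prediction, treatment-efficacy evaluation, non-relapse corroboration,
and the false-positive / false-negative failure modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dpcr import DetectionCall, DpcrAssay, call_detection

EVENT_KINDS = {
    "surgery",
    "chemo_start",
    "chemo_end",
    "imaging_negative",
    "imaging_relapse",
    "metastasectomy",
    "death",
}

__all__ = [
    "ClinicalEvent",
    "PatientTimeline",
    "ValidityCall",
    "NotClassifiableError",
    "molecular_relapse_day",
    "lead_time",
    "classify_validity",
    "preop_detection_rate",
    "group_detection_rates",
]


class NotClassifiableError(ValueError):
    """Raised when follow-up is too short to assign a validity category."""


@dataclass(frozen=True)
class ClinicalEvent:
    day: float
    kind: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.day < -365:
            raise ValueError("events limited to a one-year preoperative window")


@dataclass
class PatientTimeline:
    """Ordered clinical events plus per-mutation dPCR assay series.

    Day 0 is the day of primary-tumour surgery; negative days are
    preoperative.  ``assays`` maps mutation id to its time-ordered assay list.
    CEA values ride along for reporting but never enter the ctDNA logic.
    """

    patient_id: str
    events: list[ClinicalEvent]
    assays: dict[str, list[DpcrAssay]]
    cea: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        days = [e.day for e in self.events]
        if days != sorted(days):
            raise ValueError("clinical events must be ordered in time")
        for mut, series in self.assays.items():
            if [a.day for a in series] != sorted(a.day for a in series):
                raise ValueError(f"assay series for {mut!r} must be ordered in time")

    def events_of(self, kind: str) -> list[ClinicalEvent]:
        return [e for e in self.events if e.kind == kind]

    def postop_calls(self, rule: str = "lenient") -> dict[str, list[DetectionCall]]:
        """Detection calls on the post-operative (day > 0) subseries."""
        out = {}
        for mut, series in self.assays.items():
            post = [a for a in series if a.day > 0]
            out[mut] = call_detection(post, rule=rule) if post else []
        return out

    def preop_calls(self, rule: str = "lenient") -> dict[str, list[DetectionCall]]:
        out = {}
        for mut, series in self.assays.items():
            pre = [a for a in series if a.day <= 0]
            out[mut] = call_detection(pre, rule=rule) if pre else []
        return out

    @property
    def postop_days(self) -> list[float]:
        days = sorted({a.day for s in self.assays.values() for a in s if a.day > 0})
        return days

    @property
    def followup_end(self) -> float | None:
        days = self.postop_days
        return days[-1] if days else None


@dataclass
class ValidityCall:
    categories: set[str]
    lead_time_days: float | None


def molecular_relapse_day(timeline: PatientTimeline, rule: str = "lenient") -> float | None:
    """Earliest sustained post-operative ctDNA positivity, or None.

    A detected timepoint qualifies when it satisfies the two-dot rule by
    itself or the next sampled timepoint of the same mutation is also
    detected — isolated single-dot blips never call a relapse.  Unless
    positivity starts at the very first post-operative sample, at least one
    earlier post-operative sample must have been negative.
    """
    best: float | None = None
    for mut, calls in timeline.postop_calls(rule=rule).items():
        series = [a for a in timeline.assays[mut] if a.day > 0]
        for i, call in enumerate(calls):
            if not call.detected:
                continue
            standalone = series[i].fam >= 2 and series[i].vic >= 1
            sustained = standalone or (i + 1 < len(calls) and calls[i + 1].detected)
            if not sustained:
                continue
            prior_negative = any(not c.detected for c in calls[:i])
            if i > 0 and not prior_negative:
                continue
            if best is None or call.day < best:
                best = call.day
            break
    return best


def lead_time(timeline: PatientTimeline, rule: str = "lenient") -> float:
    """Days by which molecular relapse precedes imaging-confirmed relapse.

    Positive values mean ctDNA rose first; negative means imaging was first.
    """
    mol = molecular_relapse_day(timeline, rule=rule)
    imaging = timeline.events_of("imaging_relapse")
    if mol is None or not imaging:
        raise NotClassifiableError("need both molecular relapse and imaging relapse")
    return imaging[0].day - mol


def _chemo_epochs(timeline: PatientTimeline) -> list[tuple[float, float]]:
    starts = [e.day for e in timeline.events_of("chemo_start")]
    ends = [e.day for e in timeline.events_of("chemo_end")]
    return [(s, e) for s, e in zip(starts, ends) if e > s]


def _treatment_efficacy(timeline: PatientTimeline, rule: str, margin: float) -> bool:
    """True when ctDNA of some mutation falls below ``margin`` of its level
    between the first and last sample of a treatment epoch (or clears)."""
    calls_by_mut = {
        mut: {c.day: c for c in calls}
        for mut, calls in timeline.postop_calls(rule=rule).items()
    }
    # preop-positive disease cleared by surgery is efficacy of resection, not
    # chemotherapy; only within-epoch declines count here
    for start, end in _chemo_epochs(timeline):
        for mut, by_day in calls_by_mut.items():
            days = sorted(d for d in by_day if start <= d <= end)
            if len(days) < 2:
                continue
            first, last = by_day[days[0]], by_day[days[-1]]
            if not first.detected or first.vaf_pct is None or first.vaf_pct <= 0:
                continue
            end_vaf = last.vaf_pct if last.detected and last.vaf_pct else 0.0
            if end_vaf < margin * first.vaf_pct:
                return True
    return False


def classify_validity(
    timeline: PatientTimeline,
    rule: str = "lenient",
    efficacy_margin: float = 0.5,
) -> ValidityCall:
    """Assign clinical-validity categories to one monitored patient.

    Categories (not mutually exclusive except where noted):

    - ``early_relapse_prediction``: molecular relapse precedes imaging relapse.
    - ``treatment_efficacy``: ctDNA declines below ``efficacy_margin`` of its
      starting level (or clears) across a chemotherapy epoch.
    - ``non_relapse_corroboration``: no imaging relapse and every
      post-operative timepoint undetected; excludes early_relapse_prediction.
    - ``false_negative``: imaging relapse with no molecular relapse call.
    - ``false_positive``: molecular relapse with no imaging relapse by the end
      of follow-up (last sampled day).
    """
    if len(timeline.postop_days) < 2:
        raise NotClassifiableError("need at least two post-operative timepoints")
    mol = molecular_relapse_day(timeline, rule=rule)
    imaging = timeline.events_of("imaging_relapse")
    categories: set[str] = set()

    if imaging and mol is not None:
        lt = imaging[0].day - mol
        if lt > 0:
            categories.add("early_relapse_prediction")
    else:
        lt = None
    if imaging and mol is None:
        categories.add("false_negative")
    if mol is not None and not imaging:
        categories.add("false_positive")
    all_negative = all(
        not c.detected for calls in timeline.postop_calls(rule=rule).values() for c in calls
    )
    if not imaging and all_negative:
        categories.add("non_relapse_corroboration")
    if _treatment_efficacy(timeline, rule, efficacy_margin):
        categories.add("treatment_efficacy")
    return ValidityCall(categories=categories, lead_time_days=lt)


def preop_detection_rate(timelines: list[PatientTimeline], rule: str = "lenient") -> dict:
    """Share of patients with any mutation detected in preoperative plasma."""
    if not timelines:
        raise ValueError("need at least one patient")
    n_detected = 0
    for tl in timelines:
        pre = tl.preop_calls(rule=rule)
        if not any(s for s in pre.values()):
            raise ValueError(f"patient {tl.patient_id!r} has no preoperative assay")
        if any(c.detected for calls in pre.values() for c in calls):
            n_detected += 1
    n = len(timelines)
    return {"n_detected": n_detected, "n_total": n, "pct": round(100.0 * n_detected / n, 1)}


def group_detection_rates(
    detected: dict[str, bool], labels: dict[str, set[str] | list[str]]
) -> dict:
    """Detection rates per mutation label group, plus the share of detected
    ctDNA attributable to founder-or-truncal mutations.

    ``labels`` maps each mutation to the label groups it belongs to (e.g.
    {"founder", "truncal"}); every detected mutation must be labelled.
    """
    missing = [m for m in detected if m not in labels]
    if missing:
        raise ValueError(f"unlabelled mutations: {missing}")
    groups: dict[str, list[bool]] = {}
    for mut, flag in detected.items():
        for g in labels[mut]:
            groups.setdefault(g, []).append(bool(flag))
    out = {}
    for g, flags in sorted(groups.items()):
        n, d = len(flags), sum(flags)
        out[g] = {"detected": d, "total": n, "pct": round(100.0 * d / n, 1) if n else None}
    n_det = sum(bool(v) for v in detected.values())
    if n_det:
        ft = sum(
            1
            for mut, flag in detected.items()
            if flag and ({"founder", "truncal"} & set(labels[mut]))
        )
        out["founder_or_truncal_share"] = {
            "detected": ft,
            "total": n_det,
            "pct": round(100.0 * ft / n_det, 1),
        }
    return out
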