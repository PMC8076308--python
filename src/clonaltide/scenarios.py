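"""Canonical monitoring scenarios with known expected clinical validity.

Four stylised patient courses exercise the monitoring logic end to end:

- ``relapse_shedding``: ctDNA-positive before surgery, cleared by resection,
  exponential regrowth after adjuvant chemotherapy ends, imaging confirmation
  90 days after the burden re-crosses the detection floor — the early-relapse
  prediction pattern.
- ``relapse_no_shedding``: imaging-confirmed relapse with a tumour that never
  sheds detectable ctDNA — the false-negative pattern.
- ``cure``: preoperative positivity, complete resection, long event-free
  follow-up — the non-relapse corroboration pattern.
- ``blip``: as ``cure`` but with one isolated single-FAM-dot artefact, which
  the detection rule must ignore.

Each builder returns the patient timeline plus the category the monitoring
classifier is expected to assign.
"""

from __future__ import annotations

import math

import numpy as np

from .dpcr import DpcrAssay
from .monitoring import ClinicalEvent, PatientTimeline
from .simulate import TrajectoryScenario, TreatmentEpoch, simulate_trajectory

SCENARIOS = ("relapse_shedding", "relapse_no_shedding", "cure", "blip")

__all__ = ["SCENARIOS", "canonical_timeline", "floor_crossing_day"]


def floor_crossing_day(scenario: TrajectoryScenario, v0: float) -> float:
    """Analytic day the relapse regrowth re-crosses the detection floor
    (valid for scenarios whose treatment epochs end before the relapse)."""
    if scenario.relapse_day is None or scenario.growth_per_day <= 0:
        raise ValueError("scenario has no regrowth phase")
    log_b = math.log(scenario.residual_factor)
    for e in scenario.epochs:
        log_b -= e.decay_per_day * (e.end - e.start)
    needed = math.log(scenario.detection_floor / v0) - log_b
    return scenario.relapse_day + needed / scenario.growth_per_day


def _timeline_from_trajectory(
    patient_id: str,
    scenario: TrajectoryScenario,
    shed: dict[str, float],
    events: list[ClinicalEvent],
    droplet_total: int,
    rng: np.random.Generator,
) -> PatientTimeline:
    traj = simulate_trajectory(scenario, shed)
    assays: dict[str, list[DpcrAssay]] = {m: [] for m in shed}
    for _, row in traj.iterrows():
        fam = int(rng.binomial(droplet_total, row["vaf"]))
        assays[row["mutation_id"]].append(
            DpcrAssay(
                mutation_id=row["mutation_id"],
                day=float(row["day"]),
                fam=fam,
                vic=droplet_total - fam,
            )
        )
    return PatientTimeline(patient_id=patient_id, events=events, assays=assays)


def canonical_timeline(
    kind: str, seed: int, droplet_total: int = 20_000
) -> tuple[PatientTimeline, str]:
    """Build one canonical patient course; returns (timeline, expected category)."""
    if kind not in SCENARIOS:
        raise ValueError(f"unknown scenario {kind!r}")
    rng = np.random.default_rng(seed)
    sampling = (-7.0,) + tuple(float(d) for d in range(30, 511, 30))
    surgery = ClinicalEvent(0, "surgery")

    if kind == "relapse_shedding":
        # residual disease (1e-3 of the preoperative burden) decays during
        # adjuvant chemotherapy, then regrows at ~6%/day; the plasma VAF
        # re-crosses the 0.01% floor around day 274, months before imaging
        scenario = TrajectoryScenario(
            sampling_days=sampling,
            residual_factor=1e-3,
            epochs=(TreatmentEpoch(20.0, 160.0, 0.02),),
            relapse_day=200.0,
            growth_per_day=0.06,
        )
        shed = {"TP53_c524": 0.02}
        events = [
            surgery,
            ClinicalEvent(20, "chemo_start"),
            ClinicalEvent(160, "chemo_end"),
            ClinicalEvent(430, "imaging_relapse"),
        ]
        tl = _timeline_from_trajectory("P_relapse", scenario, shed, events, droplet_total, rng)
        return tl, "early_relapse_prediction"

    if kind == "relapse_no_shedding":
        scenario = TrajectoryScenario(sampling_days=sampling, residual_factor=0.0)
        shed = {"APC_c4348": 0.0}  # tumour never sheds detectable ctDNA
        events = [surgery, ClinicalEvent(400, "imaging_relapse")]
        tl = _timeline_from_trajectory("P_silent", scenario, shed, events, droplet_total, rng)
        return tl, "false_negative"

    # cure and blip share the resected-and-event-free trajectory
    scenario = TrajectoryScenario(sampling_days=sampling, residual_factor=0.0)
    shed = {"KRAS_c35": 0.02}
    events = [
        surgery,
        ClinicalEvent(20, "chemo_start"),
        ClinicalEvent(160, "chemo_end"),
        ClinicalEvent(500, "imaging_negative"),
    ]
    tl = _timeline_from_trajectory("P_cure", scenario, shed, events, droplet_total, rng)
    if kind == "blip":
        series = tl.assays["KRAS_c35"]
        mid = len(series) // 2
        a = series[mid]
        series[mid] = DpcrAssay(
            mutation_id=a.mutation_id, day=a.day, fam=1, vic=a.vic - 1
        )
        tl.patient_id = "P_blip"
    return tl, "non_relapse_corroboration"
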