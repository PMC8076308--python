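"""Digital-PCR droplet counting: VAF computation, detection calls, concordance.

A dPCR assay partitions plasma cell-free DNA into thousands of reaction dots.
Dots carrying the mutant allele fluoresce FAM, wild-type dots fluoresce VIC,
and the variant allele fraction is the plain dot ratio

    VAF(%) = FAM / (FAM + VIC) x 100.

A single mutant dot is indistinguishable from noise, so a timepoint counts as
detected only when it shows at least two FAM dots on its own, or at least one
FAM dot at each of two adjacent sampling timepoints (the "lenient" rule; a
stricter reading requiring two dots at each adjacent timepoint is available).
Wild-type (VIC) dots must be present for any call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DpcrAssay",
    "DetectionCall",
    "NonEvaluableError",
    "compute_vaf",
    "call_detection",
    "ngs_dpcr_concordance",
    "rescue_rate",
    "vaf_correlation",
]


class NonEvaluableError(ValueError):
    """Raised when an assay has no droplets to evaluate."""


class InsufficientDataError(ValueError):
    """Raised when too few data points remain for a statistic."""


@dataclass(frozen=True)
class DpcrAssay:
    """FAM/VIC droplet counts for one mutation at one timepoint (day)."""

    mutation_id: str
    day: float
    fam: int
    vic: int
    input_volume_ul: float | None = None

    def __post_init__(self) -> None:
        if self.fam < 0 or self.vic < 0:
            raise ValueError("droplet counts must be non-negative")

    @property
    def evaluable(self) -> bool:
        return self.fam + self.vic > 0


@dataclass(frozen=True)
class DetectionCall:
    """Per-timepoint detection flag; VAF% defined only where detected."""

    day: float
    detected: bool
    vaf_pct: float | None


def compute_vaf(fam: int, vic: int) -> float:
    """VAF in percent: 100 * FAM / (FAM + VIC)."""
    if fam < 0 or vic < 0:
        raise ValueError("droplet counts must be non-negative")
    if fam + vic == 0:
        raise NonEvaluableError("no droplets: assay is non-evaluable")
    return 100.0 * fam / (fam + vic)


def _standalone(assay: DpcrAssay, rule: str) -> bool:
    return assay.fam >= 2 and assay.vic >= 1


def _consecutive_min(rule: str) -> int:
    if rule == "lenient":
        return 1
    if rule == "strict":
        return 2
    raise ValueError(f"unknown detection rule {rule!r}")


def call_detection(series: list[DpcrAssay], rule: str = "lenient") -> list[DetectionCall]:
    """Apply the detection rule along an ordered assay series.

    Timepoint t is detected iff (FAM_t >= 2 and VIC_t >= 1) or (FAM_t >= m,
    VIC_t >= 1 and an adjacent timepoint has FAM >= m), with m = 1 under the
    lenient rule and m = 2 under the strict rule (under which the adjacency
    branch is subsumed by the standalone one).
    """
    m = _consecutive_min(rule)
    days = [a.day for a in series]
    if days != sorted(days):
        raise ValueError("assay series must be sorted by timepoint")
    if any(not a.evaluable for a in series):
        raise NonEvaluableError("series contains a non-evaluable assay")
    calls = []
    for i, a in enumerate(series):
        det = _standalone(a, rule)
        if not det and a.fam >= m and a.vic >= 1:
            neighbours = [series[j] for j in (i - 1, i + 1) if 0 <= j < len(series)]
            det = any(b.fam >= m for b in neighbours)
        calls.append(
            DetectionCall(day=a.day, detected=det, vaf_pct=compute_vaf(a.fam, a.vic) if det else None)
        )
    return calls


def ngs_dpcr_concordance(ngs_present: list[bool], dpcr_detected: list[bool]) -> dict:
    """Binary presence/absence agreement between NGS and dPCR calls.

    Returns ``{"n", "n_agree", "pct", "discordant"}`` with pct to one decimal.
    """
    if len(ngs_present) != len(dpcr_detected):
        raise ValueError("paired call lists must have equal length")
    if not ngs_present:
        raise ValueError("need at least one pair")
    agree = [bool(a) == bool(b) for a, b in zip(ngs_present, dpcr_detected)]
    n_agree = sum(agree)
    return {
        "n": len(agree),
        "n_agree": n_agree,
        "pct": round(100.0 * n_agree / len(agree), 1),
        "discordant": [i for i, ok in enumerate(agree) if not ok],
    }


def rescue_rate(ngs_missed: int, dpcr_detected_among_missed: int) -> float | None:
    """Share (%) of NGS-missed mutations recovered by dPCR; None when nothing was missed."""
    if ngs_missed == 0:
        return None
    if not 0 <= dpcr_detected_among_missed <= ngs_missed:
        raise ValueError("detected count must lie in [0, missed]")
    return round(100.0 * dpcr_detected_among_missed / ngs_missed, 1)


def vaf_correlation(
    ngs_vaf: list[float], dpcr_vaf: list[float], min_vaf: float = 1.0
) -> float:
    """Pearson r between paired NGS and dPCR VAFs, restricted to pairs with
    both values >= ``min_vaf`` (percent)."""
    if len(ngs_vaf) != len(dpcr_vaf):
        raise ValueError("paired VAF lists must have equal length")
    x = np.asarray(ngs_vaf, dtype=float)
    y = np.asarray(dpcr_vaf, dtype=float)
    keep = (x >= min_vaf) & (y >= min_vaf)
    if keep.sum() < 3:
        raise InsufficientDataError("fewer than 3 pairs above the VAF filter")
    return float(np.corrcoef(x[keep], y[keep])[0, 1])
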