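"""Founder/non-founder classification and cohort heterogeneity summaries.

A founder mutation is one present in every sampled region of a tumour,
judged in a binary present/absent manner — in contrast to truncal mutations,
which come out of the quantitative clone-tree inference.  Hypermutated
tumours (>10 mutations/Mb) cannot be assumed to derive from a single
transformed cell, so their founder/truncal enumeration is suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

from .profile import InsufficientDataError, VafMatrix

__all__ = [
    "FounderLabels",
    "GroupSummary",
    "classify_founder",
    "flag_hypermutator",
    "group_vaf_summary",
    "overlap_stats",
    "tumour_level_rates",
]


@dataclass
class FounderLabels:
    tumour_id: str
    labels: dict[str, str]  # mutation id -> "founder" | "non-founder"
    hypermutator: bool = False

    @property
    def n_founder(self) -> int:
        return sum(v == "founder" for v in self.labels.values())

    @property
    def n_nonfounder(self) -> int:
        return sum(v == "non-founder" for v in self.labels.values())

    @property
    def founder_set(self) -> set[str]:
        return {m for m, v in self.labels.items() if v == "founder"}


@dataclass
class GroupSummary:
    group: str
    n: int
    median: float
    q1: float
    q3: float
    p_value: float
    u_stat: float  # Mann-Whitney U of this group's values over the other's


def classify_founder(
    matrix: VafMatrix,
    hypermutator: bool = False,
    rescued: dict[str, set[str]] | None = None,
) -> FounderLabels:
    """Label each mutation founder (present in every region) or non-founder.

    Presence defaults to an NGS filter pass; ``rescued`` optionally merges
    dPCR-confirmed presence (mutation id -> regions confirmed) before the
    all-regions test.  Hypermutator tumours get their labels suppressed.
    """
    if len(matrix.regions) < 2:
        raise ValueError("founder classification needs at least two regions")
    if hypermutator:
        return FounderLabels(tumour_id=matrix.tumour_id, labels={}, hypermutator=True)
    present = matrix.present.copy()
    for m, regions in (rescued or {}).items():
        if m in present.index:
            for r in regions:
                if r in present.columns:
                    present.loc[m, r] = True
    labels = {
        m: ("founder" if bool(present.loc[m].all()) else "non-founder")
        for m in present.index
    }
    return FounderLabels(tumour_id=matrix.tumour_id, labels=labels, hypermutator=False)


def flag_hypermutator(burden: float, threshold: float = 10.0) -> bool:
    """Strictly more than ``threshold`` mutations per megabase."""
    if burden < 0:
        raise ValueError("burden must be non-negative")
    return burden > threshold


def group_vaf_summary(vafs_by_group: dict[str, "list[float] | np.ndarray"]) -> list[GroupSummary]:
    """Median and IQR per group (VAF %, linear-interpolation quantiles) with a
    shared two-sided Mann-Whitney U p-value comparing the two groups.

    Uses the exact null distribution when both groups are small (n <= 8) and
    tie-free, the tie-corrected normal approximation with continuity
    correction otherwise.
    """
    if len(vafs_by_group) != 2:
        raise ValueError("exactly two groups expected")
    arrays = {g: np.asarray(v, dtype=float) for g, v in vafs_by_group.items()}
    for g, a in arrays.items():
        if a.size == 0:
            raise InsufficientDataError(f"group {g!r} is empty")
    (ga, xa), (gb, xb) = arrays.items()
    pooled = np.concatenate([xa, xb])
    small = xa.size <= 8 and xb.size <= 8
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if small and not ties else "asymptotic"
    res = mannwhitneyu(xa, xb, alternative="two-sided", method=method)
    p = float(res.pvalue)
    u = {ga: float(res.statistic), gb: xa.size * xb.size - float(res.statistic)}
    out = []
    for g, a in arrays.items():
        q1, med, q3 = np.percentile(a, [25, 50, 75])
        out.append(
            GroupSummary(
                group=g, n=a.size, median=float(med), q1=float(q1), q3=float(q3),
                p_value=p, u_stat=u[g],
            )
        )
    return out


def overlap_stats(set_a: set[str], set_b: set[str]) -> dict:
    """Overlap bookkeeping between two mutation sets.

    ``pct_a_in_b`` is the share of A also in B (percent, one decimal);
    empty denominators report None.
    """
    n_a, n_b = len(set_a), len(set_b)
    n_both = len(set_a & set_b)
    return {
        "n_a": n_a,
        "n_b": n_b,
        "n_both": n_both,
        "pct_a_in_b": round(100.0 * n_both / n_a, 1) if n_a else None,
        "pct_b_in_a": round(100.0 * n_both / n_b, 1) if n_b else None,
    }


def tumour_level_rates(cohort_labels: list[FounderLabels]) -> dict:
    """Cohort rates: tumours with at least one founder mutation and the mean
    founder count per tumour (hypermutators count as founder-free)."""
    if not cohort_labels:
        raise ValueError("need at least one tumour")
    n = len(cohort_labels)
    counts = [fl.n_founder for fl in cohort_labels]
    with_founder = sum(c > 0 for c in counts)
    return {
        "n_tumours": n,
        "n_tumours_with_founder": with_founder,
        "pct": round(100.0 * with_founder / n, 1),
        "mean_founder_per_tumour": float(np.mean(counts)),
    }
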