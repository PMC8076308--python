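"""Per-region somatic call ingestion, retention filtering, VAF matrices.

Calls arrive either as VCF 4.x (tumour sample carrying AD/DP format fields,
optional matched normal as a second sample) or as a tab-separated count table
(chrom, pos, ref, alt, gene, region, depth, alt_reads and optional matched-
normal counts).  Retention follows panel-sequencing practice: minimum depth
20, minimum VAF 5%, at least four supporting reads, and a one-sided Fisher
exact test of tumour alt-read enrichment over the matched normal at p < 0.05.
Retained calls across regions are assembled into a mutations x regions VAF
matrix, the per-tumour unit all downstream classification works from.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

__all__ = [
    "MutationRecord",
    "RegionCall",
    "VafMatrix",
    "FilterThresholds",
    "FilterResult",
    "ParseError",
    "ConflictError",
    "InsufficientDataError",
    "read_region_calls",
    "filter_variant",
    "build_vaf_matrix",
    "mutation_burden",
    "cn_profile_correlation",
]


class ParseError(ValueError):
    pass


class ConflictError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class MutationRecord:
    """A somatic variant keyed by (chrom, pos, ref, alt), 1-based VCF-style.

    Gene symbols are annotation only and never part of identity: two tumours
    can mutate the same gene at different positions.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be 1-based (>= 1)")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def kind(self) -> str:
        return "SNV" if len(self.ref) == len(self.alt) == 1 else "INDEL"

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class RegionCall:
    mutation: MutationRecord
    region: str
    depth: int
    alt_reads: int
    normal_depth: int = 0
    normal_alt: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.alt_reads <= self.depth:
            raise ValueError("need 0 <= alt_reads <= depth")
        if not 0 <= self.normal_alt <= max(self.normal_depth, 0):
            raise ValueError("need 0 <= normal_alt <= normal_depth")

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.depth if self.depth else 0.0


@dataclass(frozen=True)
class FilterThresholds:
    """Count-level retention thresholds (VarScan-style defaults)."""

    min_depth: int = 20
    min_vaf: float = 0.05
    min_alt: int = 4
    max_p: float = 0.05


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reason: str | None  # failing criterion, None on pass

    def __bool__(self) -> bool:
        return self.passed


def filter_variant(call: RegionCall, thresholds: FilterThresholds | None = None) -> FilterResult:
    """Apply the retention filter to one per-region call.

    The Fisher test is one-sided for tumour alt enrichment versus the matched
    normal; it is skipped when no normal coverage is available.
    """
    t = thresholds or FilterThresholds()
    if call.depth < t.min_depth:
        return FilterResult(False, "depth")
    if call.alt_reads < t.min_alt:
        return FilterResult(False, "supporting_reads")
    if call.vaf < t.min_vaf:
        return FilterResult(False, "vaf")
    if call.normal_depth > 0:
        table = [
            [call.alt_reads, call.depth - call.alt_reads],
            [call.normal_alt, call.normal_depth - call.normal_alt],
        ]
        _, p = fisher_exact(table, alternative="greater")
        if not p < t.max_p:
            return FilterResult(False, "fisher_p")
    return FilterResult(True, None)


# ---------------------------------------------------------------------------
# readers

_TSV_REQUIRED = ("chrom", "pos", "ref", "alt", "depth", "alt_reads")


def _read_tsv_calls(path: Path, region_label: str) -> list[RegionCall]:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in _TSV_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    calls = []
    for i, row in df.iterrows():
        if "region" in df.columns and str(row["region"]) != region_label:
            continue
        try:
            rec = MutationRecord(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                gene=str(row.get("gene", "") or ""),
            )
            calls.append(
                RegionCall(
                    mutation=rec,
                    region=region_label,
                    depth=int(row["depth"]),
                    alt_reads=int(row["alt_reads"]),
                    normal_depth=int(row.get("normal_depth", 0) or 0),
                    normal_alt=int(row.get("normal_alt", 0) or 0),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: line {i + 2}: {exc}") from exc
    return calls


def _read_vcf_calls(path: Path, region_label: str) -> list[RegionCall]:
    import pysam

    calls = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if not samples:
            raise ParseError(f"{path}: VCF has no sample columns")
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ParseError(f"{path}: {rec.chrom}:{rec.pos}: need exactly one ALT")
            tum = rec.samples[samples[0]]
            ad = tum.get("AD")
            dp = tum.get("DP")
            if ad is None or all(x is None for x in ad):
                raise ParseError(f"{path}: {rec.chrom}:{rec.pos}: missing AD field")
            alt_reads = int(ad[1])
            depth = int(dp) if dp is not None else int(sum(ad))
            n_depth = n_alt = 0
            if len(samples) > 1:
                nor = rec.samples[samples[1]]
                nad = nor.get("AD")
                if nad is not None and not all(x is None for x in nad):
                    n_alt = int(nad[1])
                    ndp = nor.get("DP")
                    n_depth = int(ndp) if ndp is not None else int(sum(nad))
            gene = rec.info.get("GENE", "")
            mut = MutationRecord(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
                gene=gene if isinstance(gene, str) else (gene[0] if gene else ""),
            )
            calls.append(
                RegionCall(
                    mutation=mut, region=region_label, depth=depth,
                    alt_reads=alt_reads, normal_depth=n_depth, normal_alt=n_alt,
                )
            )
    return calls


def read_region_calls(path: str | Path, region_label: str) -> list[RegionCall]:
    """Read one region's somatic calls from VCF (AD/DP) or the TSV dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in {".vcf", ".bcf"} or path.name.endswith(".vcf.gz"):
        return _read_vcf_calls(path, region_label)
    return _read_tsv_calls(path, region_label)


# ---------------------------------------------------------------------------
# VAF matrix


@dataclass
class VafMatrix:
    """Mutations x regions count/VAF grid for one tumour.

    ``present[m, r]`` records whether the retention filter passed at that
    cell; a mutation appears at all only if it passed in at least one region.
    """

    tumour_id: str
    mutations: list[MutationRecord]
    regions: list[str]
    depth: pd.DataFrame
    alt: pd.DataFrame
    vaf: pd.DataFrame
    present: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.present.any(axis=1).all():
            raise ValueError("every mutation row needs at least one present cell")

    @property
    def mutation_ids(self) -> list[str]:
        return list(self.vaf.index)

    def to_long(self) -> pd.DataFrame:
        rows = []
        by_key = {m.key: m for m in self.mutations}
        for key in self.vaf.index:
            rec = by_key[key]
            for r in self.regions:
                rows.append(
                    {
                        "tumour_id": self.tumour_id,
                        "mutation_id": key,
                        "gene": rec.gene,
                        "kind": rec.kind,
                        "region": r,
                        "depth": self.depth.loc[key, r],
                        "alt_reads": self.alt.loc[key, r],
                        "vaf": self.vaf.loc[key, r],
                        "present": bool(self.present.loc[key, r]),
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_long().to_csv(path, sep="\t", index=False)
        return path

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "tumour_id": self.tumour_id,
            "regions": self.regions,
            "depth": self.depth.to_dict(),
            "alt": self.alt.to_dict(),
            "present": self.present.astype(bool).to_dict(),
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


def build_vaf_matrix(
    calls_by_region: dict[str, list[RegionCall]],
    tumour_id: str,
    thresholds: FilterThresholds | None = None,
) -> VafMatrix:
    """Assemble the per-tumour VAF matrix from per-region calls.

    Keeps the union of mutations passing the filter in at least one region;
    cells without a call keep depth 0.  Conflicting duplicate counts for the
    same (mutation, region) raise :class:`ConflictError`.
    """
    if not calls_by_region:
        raise ValueError("need at least one region")
    regions = list(calls_by_region)
    seen: dict[tuple[str, str], RegionCall] = {}
    records: dict[str, MutationRecord] = {}
    for region, calls in calls_by_region.items():
        for call in calls:
            key = (call.mutation.key, region)
            if key in seen:
                prev = seen[key]
                if (prev.depth, prev.alt_reads) != (call.depth, call.alt_reads):
                    raise ConflictError(
                        f"conflicting counts for {call.mutation.key} in {region}"
                    )
                continue
            seen[key] = call
            records.setdefault(call.mutation.key, call.mutation)

    passing = {
        mkey
        for (mkey, region), call in seen.items()
        if filter_variant(call, thresholds).passed
    }
    if not passing:
        raise InsufficientDataError("no mutation passed the filter in any region")
    keys = sorted(passing, key=lambda k: (records[k].chrom, records[k].pos, records[k].alt))
    shape = (len(keys), len(regions))
    depth = pd.DataFrame(np.zeros(shape, dtype=int), index=keys, columns=regions)
    alt = pd.DataFrame(np.zeros(shape, dtype=int), index=keys, columns=regions)
    present = pd.DataFrame(np.zeros(shape, dtype=bool), index=keys, columns=regions)
    for (mkey, region), call in seen.items():
        if mkey not in passing:
            continue
        depth.loc[mkey, region] = call.depth
        alt.loc[mkey, region] = call.alt_reads
        present.loc[mkey, region] = filter_variant(call, thresholds).passed
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = (alt / depth.replace(0, np.nan)).fillna(0.0)
    return VafMatrix(
        tumour_id=tumour_id,
        mutations=[records[k] for k in keys],
        regions=regions,
        depth=depth,
        alt=alt,
        vaf=vaf,
        present=present,
    )


def mutation_burden(matrix: VafMatrix, panel_footprint_mb: float) -> float:
    """Distinct mutations per megabase of panel footprint."""
    if panel_footprint_mb <= 0:
        raise ValueError("panel footprint must be positive")
    return len(matrix.mutation_ids) / panel_footprint_mb


def cn_profile_correlation(
    cn_tables: dict[str, "pd.Series | dict[str, float]"],
) -> tuple[pd.DataFrame, float]:
    """Pearson correlation of gene copy-number profiles between region pairs.

    Returns the symmetric pairwise-r matrix and the median r over distinct
    pairs; every pair needs at least three shared genes.
    """
    if len(cn_tables) < 2:
        raise InsufficientDataError("need at least two regions")
    series = {r: pd.Series(v, dtype=float) for r, v in cn_tables.items()}
    regions = list(series)
    r_mat = pd.DataFrame(np.eye(len(regions)), index=regions, columns=regions)
    pair_rs = []
    for a, b in itertools.combinations(regions, 2):
        shared = series[a].index.intersection(series[b].index)
        if len(shared) < 3:
            raise InsufficientDataError(f"regions {a}/{b} share fewer than 3 genes")
        r = float(np.corrcoef(series[a][shared], series[b][shared])[0, 1])
        r_mat.loc[a, b] = r_mat.loc[b, a] = r
        pair_rs.append(r)
    return r_mat, float(np.median(pair_rs))
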