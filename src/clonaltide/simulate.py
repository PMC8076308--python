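"""Synthetic tumours, sequencing counts, droplet assays and ctDNA trajectories.

Everything downstream of raw sequencing is testable against this module:
it draws a clone tree, places mutations on its edges, mixes clones into
regional specimens, and emits binomially noised read counts, dPCR droplet
counts and longitudinal plasma-VAF trajectories, all with the ground truth
retained.

The stated world it emulates: three sampled regions per tumour, tumour
cellularity around 40-60%, panel-scale mutation counts (a dozen per tumour,
up to ~50 for hypermutators), binomial read-depth noise around a Poisson
depth, droplet partitioning of plasma templates, and a 0.01% plasma VAF
detection floor.  Mutations are diploid heterozygous SNVs, so a clone
carrying a mutation contributes half its proportion to the expected VAF.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dpcr import DpcrAssay
from .profile import MutationRecord
from .tree import ANCESTRAL, ROOT, CloneTree

__all__ = [
    "SimConfig",
    "SimTruth",
    "TreatmentEpoch",
    "TrajectoryScenario",
    "simulate_clone_tree",
    "assign_mutations",
    "simulate_regions",
    "true_vaf_matrix",
    "simulate_read_counts",
    "simulate_trajectory",
    "simulate_droplets",
    "simulate_tumour",
    "simulate_cohort",
    "write_region_counts",
    "write_region_vcf",
    "write_truth_json",
    "write_trajectory_tsv",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Stated-world parameters for one synthetic tumour."""

    n_clones: int = 3
    n_mutations: int = 8
    n_regions: int = 3
    mean_depth: float = 500.0
    cellularity_per_region: float | tuple[float, ...] = 0.5
    dirichlet_concentration: float = 1.0
    region_clone_bias: float = 0.0
    truncal_weight: float = 0.3
    hypermutator: bool = False
    panel_footprint_mb: float = 1.0
    droplet_total: int = 20_000
    detection_floor: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1 or self.n_mutations < 1 or self.n_regions < 1:
            raise ValueError("all counts must be positive")
        cells = np.atleast_1d(np.asarray(self.cellularity_per_region, dtype=float))
        if np.any((cells <= 0) | (cells > 1)):
            raise ValueError("cellularity must lie in (0, 1]")
        if self.detection_floor < 0 or self.mean_depth <= 0:
            raise ValueError("detection_floor >= 0 and mean_depth > 0 required")
        if not 0 <= self.truncal_weight <= 1:
            raise ValueError("truncal_weight must lie in [0, 1]")

    def cellularity(self) -> np.ndarray:
        cells = np.atleast_1d(np.asarray(self.cellularity_per_region, dtype=float))
        if cells.size == 1:
            cells = np.repeat(cells, self.n_regions)
        if cells.size != self.n_regions:
            raise ValueError("cellularity_per_region length must match n_regions")
        return cells


@dataclass
class SimTruth:
    """Ground truth for one simulated tumour."""

    tumour_id: str
    tree: CloneTree
    mutation_branch: dict[str, str]
    regional_proportions: pd.DataFrame        # clones x regions
    true_vaf: pd.DataFrame                    # mutations x regions
    depth: pd.DataFrame
    alt: pd.DataFrame
    labels: pd.DataFrame                      # columns: truncal, founder (bool)
    records: dict[str, MutationRecord]
    hypermutator: bool
    config: SimConfig

    def __post_init__(self) -> None:
        sums = self.regional_proportions.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each region's clone proportions must sum to 1")
        anc_carriers = self.tree.subtree(ANCESTRAL) if ANCESTRAL in self.tree.parent else set()
        for m, lab in self.labels.iterrows():
            if lab["truncal"] and self.tree.subtree(self.mutation_branch[m]) != anc_carriers:
                raise ValueError(f"truncal mutation {m} not carried by all tumour clones")


# ---------------------------------------------------------------------------
# clone tree


def _prufer_decode(seq: np.ndarray, n: int) -> list[tuple[int, int]]:
    degree = np.ones(n, dtype=int)
    for s in seq:
        degree[s] += 1
    edges = []
    seq = list(seq)
    for s in seq:
        leaf = min(i for i in range(n) if degree[i] == 1)
        edges.append((leaf, s))
        degree[leaf] -= 1
        degree[s] -= 1
    u, v = (i for i in range(n) if degree[i] == 1)
    edges.append((u, v))
    return edges


def simulate_clone_tree(n_clones: int, seed: int) -> CloneTree:
    """Draw a clone tree uniformly over labelled topologies.

    The root is the normal-cell clone; all tumour clones descend from the
    single ancestral tumour clone C1.  Topologies (labelled trees on the
    tumour clones, rooted at C1) are sampled uniformly via a random Prüfer
    sequence, so every labelled rooted topology has probability
    1 / n_clones^(n_clones - 2).
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng(seed)
    labels = [f"C{i + 1}" for i in range(n_clones)]
    parent: dict[str, str | None] = {ROOT: None, labels[0]: ROOT}
    if n_clones >= 2:
        if n_clones == 2:
            edges = [(0, 1)]
        else:
            seq = rng.integers(0, n_clones, size=n_clones - 2)
            edges = _prufer_decode(seq, n_clones)
        adj: dict[int, list[int]] = {i: [] for i in range(n_clones)}
        for u, v in edges:
            adj[u].append(v)
            adj[v].append(u)
        stack = [0]
        seen = {0}
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    parent[labels[v]] = labels[u]
                    seen.add(v)
                    stack.append(v)
    tree = CloneTree(parent=parent)
    tree.validate()
    return tree


def assign_mutations(
    tree: CloneTree,
    n_mutations: int,
    truncal_weight: float,
    seed: int,
    leaf_only: bool = False,
) -> dict[str, str]:
    """Place each mutation on one edge of the clone tree.

    A mutation lands on the truncal edge (root -> C1) with probability
    ``truncal_weight`` and otherwise uniformly on a non-truncal edge.  With
    ``leaf_only`` (the hypermutator pattern) every mutation goes to a leaf
    edge and nothing is truncal.
    """
    if not 0 <= truncal_weight <= 1:
        raise ValueError("truncal_weight must lie in [0, 1]")
    tree.validate()
    rng = np.random.default_rng(seed)
    ids = [f"m{i + 1:03d}" for i in range(n_mutations)]
    non_trunk = [c for c in tree.tumour_clones if c != ANCESTRAL]
    if leaf_only:
        leaves = [c for c in tree.tumour_clones if not tree.children(c)]
        # a single-clone tree has only the truncal edge; that clone is the leaf
        return {m: leaves[rng.integers(len(leaves))] for m in ids}
    out = {}
    for m in ids:
        if not non_trunk or rng.random() < truncal_weight:
            out[m] = ANCESTRAL
        else:
            out[m] = non_trunk[rng.integers(len(non_trunk))]
    return out


def simulate_regions(tree: CloneTree, cfg: SimConfig) -> pd.DataFrame:
    """Mix clones into regional specimens.

    Tumour-clone proportions per region follow a symmetric Dirichlet with
    concentration ``cfg.dirichlet_concentration``, scaled by that region's
    cellularity; the normal clone takes the remainder.  A positive
    ``region_clone_bias`` adds that weight to clone (r mod n_clones) in
    region r, emulating the spatial pattern of multi-region sampling where
    each specimen is enriched for a different subclone — the regime in which
    clone-tree topology is statistically identifiable.
    """
    tree.validate()
    rng = np.random.default_rng(cfg.seed)
    clones = tree.tumour_clones
    cells = cfg.cellularity()
    regions = [f"R{i + 1}" for i in range(cfg.n_regions)]
    props = np.zeros((len(clones) + 1, cfg.n_regions))
    for r in range(cfg.n_regions):
        alpha = np.full(len(clones), cfg.dirichlet_concentration)
        if cfg.region_clone_bias > 0:
            alpha[r % len(clones)] += cfg.region_clone_bias
        frac = rng.dirichlet(alpha)
        props[0, r] = 1.0 - cells[r]
        props[1:, r] = frac * cells[r]
    return pd.DataFrame(props, index=[ROOT] + clones, columns=regions)


def true_vaf_matrix(
    tree: CloneTree, proportions: pd.DataFrame, mutation_branch: dict[str, str]
) -> pd.DataFrame:
    """Expected VAF per mutation per region: half the carrying-clone mass."""
    missing = set(mutation_branch.values()) - set(proportions.index)
    if missing:
        raise ValueError(f"branches absent from proportions: {sorted(missing)}")
    rows = {}
    for m, edge in mutation_branch.items():
        carriers = sorted(tree.subtree(edge))
        rows[m] = 0.5 * proportions.loc[carriers].sum(axis=0)
    vaf = pd.DataFrame(rows).T
    vaf.index.name = "mutation_id"
    return vaf


def simulate_read_counts(
    true_vaf: pd.DataFrame, mean_depth: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noisy panel counts: depth ~ zero-truncated Poisson, alt ~ Binomial."""
    v = np.asarray(true_vaf, dtype=float)
    if np.any((v < 0) | (v > 1)):
        raise ValueError("true VAFs must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    depth = rng.poisson(mean_depth, size=v.shape)
    while np.any(depth == 0):  # truncate at >= 1
        zero = depth == 0
        depth[zero] = rng.poisson(mean_depth, size=int(zero.sum()))
    alt = rng.binomial(depth, v)
    mk = lambda a: pd.DataFrame(a, index=true_vaf.index, columns=true_vaf.columns)
    return mk(depth), mk(alt)


# ---------------------------------------------------------------------------
# plasma dynamics


@dataclass(frozen=True)
class TreatmentEpoch:
    start: float
    end: float
    decay_per_day: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("epoch end must follow its start")


@dataclass(frozen=True)
class TrajectoryScenario:
    """Piecewise-exponential tumour-burden scenario; surgery at day 0."""

    sampling_days: tuple[float, ...]
    residual_factor: float = 0.0
    epochs: tuple[TreatmentEpoch, ...] = ()
    relapse_day: float | None = None
    growth_per_day: float = 0.0
    detection_floor: float = 1e-4

    def __post_init__(self) -> None:
        if list(self.sampling_days) != sorted(self.sampling_days):
            raise ValueError("sampling days must be ordered in time")
        starts = [e.start for e in self.epochs]
        if starts != sorted(starts):
            raise ValueError("treatment epochs must be ordered in time")
        if self.residual_factor < 0:
            raise ValueError("residual factor must be non-negative")


def _burden_multiplier(s: TrajectoryScenario, t: float) -> float:
    """Tumour burden at day t relative to the preoperative burden."""
    if t <= 0:
        return 1.0
    if s.residual_factor == 0.0:
        return 0.0
    log_b = math.log(s.residual_factor)
    for e in s.epochs:
        overlap = max(0.0, min(t, e.end) - max(0.0, e.start))
        log_b -= e.decay_per_day * overlap
    if s.relapse_day is not None and t > s.relapse_day:
        log_b += s.growth_per_day * (t - s.relapse_day)
    return math.exp(log_b)


def simulate_trajectory(
    scenario: TrajectoryScenario, shed_params: dict[str, float], seed: int = 0
) -> pd.DataFrame:
    """Plasma VAF (fraction) per mutation at each sampling day.

    ``shed_params`` maps mutation id to its preoperative plasma VAF; the
    shared burden multiplier applies surgery, treatment decay and relapse
    regrowth.  Values below the detection floor are zeroed; values are capped
    at 0.5 (a fully tumour-derived heterozygous plasma sample).  The
    trajectory is deterministic — sampling noise enters only via droplet or
    read-count simulation.
    """
    del seed  # reserved: the kinetic model itself is noise-free
    rows = []
    for t in scenario.sampling_days:
        b = _burden_multiplier(scenario, t)
        for m, v0 in shed_params.items():
            v = min(v0 * b, 0.5)
            if v < scenario.detection_floor:
                v = 0.0
            rows.append((t, m, v))
    return pd.DataFrame(rows, columns=["day", "mutation_id", "vaf"])


def simulate_droplets(
    true_vaf: float,
    droplet_total: int,
    seed: int,
    mutation_id: str = "m",
    day: float = 0.0,
) -> DpcrAssay:
    """Partition templates into droplets: FAM ~ Binomial(total, VAF)."""
    if not 0 <= true_vaf <= 1:
        raise ValueError("true_vaf must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    fam = int(rng.binomial(droplet_total, true_vaf)) if droplet_total > 0 else 0
    return DpcrAssay(mutation_id=mutation_id, day=day, fam=fam, vic=droplet_total - fam)


# ---------------------------------------------------------------------------
# whole-tumour and cohort convenience


def _make_records(n: int, rng: np.random.Generator) -> dict[str, MutationRecord]:
    records = {}
    for i in range(n):
        chrom = f"chr{(i % 22) + 1}"
        pos = 1_000_000 + 1_000 * (i // 22) + 137 * i
        ref = str(_BASES[rng.integers(4)])
        alt = str(rng.choice(_BASES[_BASES != ref]))
        records[f"m{i + 1:03d}"] = MutationRecord(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene=f"GENE{i + 1:03d}"
        )
    return records


def simulate_tumour(cfg: SimConfig, tumour_id: str = "T1") -> SimTruth:
    """Generate one tumour end to end with ground truth.

    Hypermutator mode raises the mutation count above 10 per Mb of panel
    footprint and places every mutation on a leaf edge, so the tumour has
    neither truncal nor founder mutations.
    """
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(2**31, size=5)
    n_mut = cfg.n_mutations
    if cfg.hypermutator:
        n_mut = max(4 * cfg.n_mutations, int(10 * cfg.panel_footprint_mb) + 2)
    tree = simulate_clone_tree(cfg.n_clones, int(seeds[0]))
    branch = assign_mutations(
        tree, n_mut, cfg.truncal_weight, int(seeds[1]), leaf_only=cfg.hypermutator
    )
    props = simulate_regions(tree, replace(cfg, seed=int(seeds[2])))
    vaf = true_vaf_matrix(tree, props, branch)
    depth, alt = simulate_read_counts(vaf, cfg.mean_depth, int(seeds[3]))
    labels = pd.DataFrame(
        {
            "truncal": [branch[m] == ANCESTRAL and not cfg.hypermutator for m in vaf.index],
            "founder": (vaf > 0).all(axis=1),
        },
        index=vaf.index,
    )
    if cfg.hypermutator:
        labels["founder"] = False  # labels suppressed for hypermutators
    tree.branch_assignments = dict(branch)
    tree.proportions = props
    return SimTruth(
        tumour_id=tumour_id,
        tree=tree,
        mutation_branch=branch,
        regional_proportions=props,
        true_vaf=vaf,
        depth=depth,
        alt=alt,
        labels=labels,
        records=_make_records(n_mut, np.random.default_rng(int(seeds[4]))),
        hypermutator=cfg.hypermutator,
        config=cfg,
    )


def simulate_cohort(
    n_tumours: int,
    base: SimConfig,
    seed: int,
    n_hypermutators: int = 0,
) -> list[SimTruth]:
    """A cohort of independent tumours; the last ``n_hypermutators`` are hypermutated."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_tumours):
        cfg = replace(
            base,
            seed=int(rng.integers(2**31)),
            hypermutator=i >= n_tumours - n_hypermutators,
        )
        out.append(simulate_tumour(cfg, tumour_id=f"T{i + 1:02d}"))
    return out


# ---------------------------------------------------------------------------
# writers


def write_region_counts(truth: SimTruth, outdir: str | Path) -> list[Path]:
    """One TSV per region: chrom, pos, ref, alt, gene, region, depth,
    alt_reads, plus matched-normal counts (alt-free by construction)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    normal_depth = int(round(truth.config.mean_depth))
    for region in truth.true_vaf.columns:
        rows = []
        for m in truth.true_vaf.index:
            rec = truth.records[m]
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alt,
                    "gene": rec.gene,
                    "region": region,
                    "depth": int(truth.depth.loc[m, region]),
                    "alt_reads": int(truth.alt.loc[m, region]),
                    "normal_depth": normal_depth,
                    "normal_alt": 0,
                }
            )
        path = outdir / f"{truth.tumour_id}_{region}.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def write_region_vcf(truth: SimTruth, region: str, path: str | Path) -> Path:
    """Minimal VCF 4.2 for one region (tumour + matched-normal samples)."""
    import pysam

    header = pysam.VariantHeader()
    for c in sorted({r.chrom for r in truth.records.values()}):
        header.contigs.add(c, length=250_000_000)
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.add_sample("TUMOR")
    header.add_sample("NORMAL")
    path = Path(path)
    normal_depth = int(round(truth.config.mean_depth))
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        order = sorted(
            truth.true_vaf.index, key=lambda m: (truth.records[m].chrom, truth.records[m].pos)
        )
        for m in order:
            rec = truth.records[m]
            depth = int(truth.depth.loc[m, region])
            alt = int(truth.alt.loc[m, region])
            v = vf.new_record(
                contig=rec.chrom, start=rec.pos - 1, alleles=(rec.ref, rec.alt)
            )
            v.info["GENE"] = rec.gene
            v.samples["TUMOR"]["DP"] = depth
            v.samples["TUMOR"]["AD"] = (depth - alt, alt)
            v.samples["NORMAL"]["DP"] = normal_depth
            v.samples["NORMAL"]["AD"] = (normal_depth, 0)
            vf.write(v)
    return path


def write_truth_json(truth: SimTruth, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "tumour_id": truth.tumour_id,
        "hypermutator": truth.hypermutator,
        "tree_newick": truth.tree.to_newick(),
        "parent": truth.tree.parent,
        "mutation_branch": truth.mutation_branch,
        "regional_proportions": truth.regional_proportions.to_dict(),
        "true_vaf": truth.true_vaf.to_dict(),
        "labels": truth.labels.astype(bool).to_dict(),
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def write_trajectory_tsv(
    trajectory: pd.DataFrame, assays: list[DpcrAssay], path: str | Path
) -> Path:
    """Tidy TSV: day, mutation_id, vaf_fraction, fam, vic."""
    by_key = {(a.day, a.mutation_id): a for a in assays}
    rows = []
    for _, r in trajectory.iterrows():
        a = by_key.get((r["day"], r["mutation_id"]))
        rows.append(
            {
                "day": r["day"],
                "mutation_id": r["mutation_id"],
                "vaf_fraction": r["vaf"],
                "fam": a.fam if a else "",
                "vic": a.vic if a else "",
            }
        )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
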