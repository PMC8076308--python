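"""Clonal phylogeny inference from multiregional read counts.

A tumour is modelled as a mixture of cell populations (clones): a normal-cell
clone at the root plus one or more tumour clones forming a single subtree
under an ancestral tumour clone.  Each somatic mutation cluster sits on one
edge of the tree and is carried by every clone below that edge.  Under a
diploid-heterozygous model the expected variant allele frequency of a
mutation in a region is half the summed proportion of the clones that carry
it.  Inference is Metropolis-Hastings MCMC over (topology, cluster-to-edge
assignment, per-region clone proportions) with a binomial read-count
likelihood; the number of clones is selected by BIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binom

ROOT = "normal"
ANCESTRAL = "C1"
_EPS = 1e-9

__all__ = [
    "CloneTree",
    "MutationCluster",
    "McmcConfig",
    "McmcDiagnostics",
    "cluster_mutations",
    "tree_log_likelihood",
    "mcmc_infer",
    "identify_truncal",
    "mutation_relations",
    "proportions_table",
]


@dataclass
class CloneTree:
    """Rooted clone tree with mutation placements and mixture proportions.

    Parameters
    ----------
    parent
        Mapping node -> parent node; the root (``"normal"``) maps to ``None``.
        Edges are identified by their child node, so the truncal edge (root ->
        ancestral tumour clone) is the edge ``"C1"``.
    branch_assignments
        Mapping mutation id -> edge (child-node label) carrying it.
    proportions
        clones x regions DataFrame of mixture fractions; every region column
        sums to 1 and includes the normal-cell clone.
    """

    parent: dict[str, str | None]
    branch_assignments: dict[str, str] = field(default_factory=dict)
    proportions: pd.DataFrame | None = None

    @property
    def root(self) -> str:
        return ROOT

    @property
    def nodes(self) -> list[str]:
        return list(self.parent)

    @property
    def tumour_clones(self) -> list[str]:
        return [n for n in self.parent if n != ROOT]

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [(p, c) for c, p in self.parent.items() if p is not None]

    def children(self, node: str) -> list[str]:
        return [c for c, p in self.parent.items() if p == node]

    def subtree(self, node: str) -> set[str]:
        """The clone set carrying a mutation on the edge above ``node``."""
        out = {node}
        stack = [node]
        while stack:
            for c in self.children(stack.pop()):
                out.add(c)
                stack.append(c)
        return out

    @property
    def ancestral_clone(self) -> str | None:
        """The single tumour clone hanging directly off the normal root."""
        kids = self.children(ROOT)
        return kids[0] if len(kids) == 1 else None

    def validate(self) -> None:
        roots = [n for n, p in self.parent.items() if p is None]
        if roots != [ROOT]:
            raise ValueError(f"tree must have the single root {ROOT!r}")
        for node, par in self.parent.items():
            if par is not None and par not in self.parent:
                raise ValueError(f"parent of {node!r} missing from tree")
        if self.ancestral_clone is None and len(self.parent) > 1:
            raise ValueError("tumour clones must descend from one ancestral clone")
        # reachability / acyclicity
        seen = self.subtree(ROOT)
        if seen != set(self.parent):
            raise ValueError("tree contains unreachable nodes or a cycle")
        if self.proportions is not None:
            sums = self.proportions.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValueError("region proportions must sum to 1")

    def mutations_on(self, edge: str) -> list[str]:
        return [m for m, e in self.branch_assignments.items() if e == edge]

    def to_newick(self) -> str:
        def fmt(node: str) -> str:
            kids = self.children(node)
            if not kids:
                return node
            return "(" + ",".join(fmt(k) for k in sorted(kids)) + ")" + node

        return fmt(ROOT) + ";"


@dataclass
class MutationCluster:
    """A group of mutations sharing a VAF pattern, with pooled counts."""

    cluster_id: int
    members: list[str]
    alt: np.ndarray    # pooled alt reads per region
    depth: np.ndarray  # pooled depth per region

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must be non-empty")


@dataclass
class McmcConfig:
    """Sampler settings; defaults follow common practice for panel-scale data."""

    n_chains: int = 10
    max_steps: int = 100_000
    burn_in: float = 0.5
    proposal_weights: tuple[float, float, float] = (0.3, 0.3, 0.4)
    k_range: tuple[int, int] = (2, 6)
    convergence_window: float = 0.1
    convergence_tol: float = 1e-4
    proportion_kappa: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_steps < 1 or not (0.0 <= self.burn_in < 1.0):
            raise ValueError("max_steps >= 1 and 0 <= burn_in < 1 required")
        if self.k_range[0] < 2 or self.k_range[1] < self.k_range[0]:
            raise ValueError("k_range must be (lo, hi) with lo >= 2")


@dataclass
class McmcDiagnostics:
    traces: list[np.ndarray]          # per-chain log-likelihood trace
    acceptance_rates: list[dict[str, float]]
    converged: list[bool]
    best_chain: int
    best_k: int
    bic_by_k: dict[int, float]
    log_likelihood: float

    @property
    def any_nonconverged(self) -> bool:
        return not all(self.converged)


# ---------------------------------------------------------------------------
# clustering


def _kmeans_bic(x: np.ndarray, k: int, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Lloyd's algorithm + spherical-Gaussian BIC for one k."""
    n, d = x.shape
    # k-means++ style init
    centers = x[rng.choice(n, size=1)]
    while len(centers) < k:
        d2 = ((x[:, None, :] - centers[None]) ** 2).sum(-1).min(1)
        if d2.sum() <= 0:
            probs = np.full(n, 1.0 / n)
        else:
            probs = d2 / d2.sum()
        centers = np.vstack([centers, x[rng.choice(n, p=probs)]])
    labels = np.zeros(n, dtype=int)
    for _ in range(100):
        dist = ((x[:, None, :] - centers[None]) ** 2).sum(-1)
        new = dist.argmin(1)
        if np.array_equal(new, labels) and _ > 0:
            break
        labels = new
        for j in range(k):
            pts = x[labels == j]
            if len(pts):
                centers[j] = pts.mean(0)
    sse = ((x - centers[labels]) ** 2).sum()
    var = max(sse / max(n * d - k * d, 1), 1e-12)
    ll = -0.5 * n * d * (math.log(2 * math.pi * var) + 1.0)
    n_params = k * d + 1
    bic = -2 * ll + n_params * math.log(max(n, 2))
    return labels, bic


def cluster_mutations(matrix, max_clusters: int = 6, seed: int = 0) -> list[MutationCluster]:
    """Group mutations by per-region VAF vector; k chosen by minimum BIC.

    ``matrix`` is a :class:`~clonaltide.profile.VafMatrix` (anything exposing
    ``vaf``, ``alt`` and ``depth`` DataFrames indexed by mutation id works).
    """
    vaf = np.asarray(matrix.vaf, dtype=float)
    ids = list(matrix.vaf.index)
    n = len(ids)
    if n == 0:
        raise ValueError("need at least one mutation")
    rng = np.random.default_rng(seed)
    if n == 1:
        labels = np.zeros(1, dtype=int)
    else:
        best_bic, labels = math.inf, np.zeros(n, dtype=int)
        for k in range(1, min(max_clusters, n) + 1):
            lab, bic = _kmeans_bic(vaf, k, np.random.default_rng(rng.integers(2**31)))
            if bic < best_bic - 1e-12:
                best_bic, labels = bic, lab
    clusters = []
    alt = np.asarray(matrix.alt, dtype=float)
    depth = np.asarray(matrix.depth, dtype=float)
    for j, lab in enumerate(sorted(set(labels.tolist()))):
        idx = np.flatnonzero(labels == lab)
        clusters.append(
            MutationCluster(
                cluster_id=j,
                members=[ids[i] for i in idx],
                alt=alt[idx].sum(0),
                depth=depth[idx].sum(0),
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# likelihood


def _expected_vaf(tree: CloneTree, mutation: str) -> pd.Series:
    edge = tree.branch_assignments[mutation]
    carriers = tree.subtree(edge)
    return 0.5 * tree.proportions.loc[sorted(carriers & set(tree.proportions.index))].sum(0)


def tree_log_likelihood(tree: CloneTree, alt: pd.DataFrame, depth: pd.DataFrame) -> float:
    """Binomial log-likelihood of observed counts under a clone tree.

    For mutation m in region r the success probability is
    q(m, r) = 0.5 * sum of proportions of clones carrying m, clamped to
    [1e-9, 1 - 1e-9] so empty cells stay finite.
    """
    tree.validate()
    if tree.proportions is None:
        raise ValueError("tree has no proportions")
    if list(alt.index) != list(depth.index) or list(alt.columns) != list(depth.columns):
        raise ValueError("alt/depth tables must be aligned")
    total = 0.0
    for m in alt.index:
        if m not in tree.branch_assignments:
            raise ValueError(f"mutation {m!r} has no branch assignment")
        q = _expected_vaf(tree, m).reindex(alt.columns).to_numpy()
        q = np.clip(q, _EPS, 1 - _EPS)
        total += binom.logpmf(alt.loc[m].to_numpy(), depth.loc[m].to_numpy(), q).sum()
    return float(total)


# ---------------------------------------------------------------------------
# MCMC internals (integer-indexed state for speed)


def _subtree_matrix(parent: np.ndarray) -> np.ndarray:
    """S[c, j] = True iff clone j is in the subtree rooted at clone c."""
    k = len(parent)
    s = np.eye(k, dtype=bool)
    for j in range(1, k):
        a = parent[j]
        while a > 0:
            s[a, j] = True
            a = parent[a]
    return s


def _pooled_ll(assign, s, f, alt, ref):
    # q[c, r] = 0.5 * sum_{j in subtree(edge_c)} f[j, r]
    q = 0.5 * (s[assign].astype(float) @ f)
    q = np.clip(q, _EPS, 1 - _EPS)
    return float((alt * np.log(q) + ref * np.log1p(-q)).sum())


def _dirichlet_logpdf(x: np.ndarray, alpha: np.ndarray) -> float:
    x = np.clip(x, 1e-12, None)
    x = x / x.sum()
    return float(
        gammaln(alpha.sum()) - gammaln(alpha).sum() + ((alpha - 1) * np.log(x)).sum()
    )


def _run_chain(alt, ref, n_clusters, k, cfg: McmcConfig, rng: np.random.Generator):
    """One Metropolis-Hastings chain at fixed clone count ``k`` (incl. normal)."""
    n_regions = alt.shape[1]
    # init: random recursive tumour tree; the highest-VAF cluster starts on
    # the truncal edge (a cheap informed guess), the rest land randomly
    parent = np.full(k, -1, dtype=np.int64)
    parent[1] = 0
    for j in range(2, k):
        parent[j] = rng.integers(1, j)
    assign = rng.integers(1, k, size=n_clusters)
    with np.errstate(invalid="ignore"):
        mean_vaf = np.nansum(alt, axis=1) / np.maximum((alt + ref).sum(axis=1), 1)
    assign[int(np.argmax(mean_vaf))] = 1
    f = rng.dirichlet(np.ones(k), size=n_regions).T  # k x regions
    s = _subtree_matrix(parent)
    ll = _pooled_ll(assign, s, f, alt, ref)

    best = (ll, parent.copy(), assign.copy(), f.copy())
    trace = np.empty(cfg.max_steps + 1)
    trace[0] = ll  # initial state, so the retained maximum provably dominates it
    w = np.asarray(cfg.proposal_weights, dtype=float)
    w = w / w.sum()
    n_prop = np.zeros(3)
    n_acc = np.zeros(3)
    kappa = cfg.proportion_kappa
    tumour = np.arange(1, k)

    for step in range(cfg.max_steps):
        move = rng.choice(3, p=w)
        if move == 0 and k > 2:
            # subtree prune-regraft on a non-ancestral tumour clone
            c = int(rng.integers(2, k)) if k > 2 else 1
            sub = s[c]
            cand = tumour[~sub[1:]]
            if len(cand) == 0:
                n_prop[0] += 1
                trace[step + 1] = ll
                continue
            new_parent = int(rng.choice(cand))
            old = parent[c]
            parent[c] = new_parent
            s2 = _subtree_matrix(parent)
            ll2 = _pooled_ll(assign, s2, f, alt, ref)
            n_prop[0] += 1
            if math.log(rng.random()) < ll2 - ll:
                ll, s = ll2, s2
                n_acc[0] += 1
            else:
                parent[c] = old
        elif move == 1:
            c = int(rng.integers(n_clusters))
            old = assign[c]
            assign[c] = int(rng.integers(1, k))
            ll2 = _pooled_ll(assign, s, f, alt, ref)
            n_prop[1] += 1
            if math.log(rng.random()) < ll2 - ll:
                ll = ll2
                n_acc[1] += 1
            else:
                assign[c] = old
        else:
            r = int(rng.integers(n_regions))
            cur = f[:, r]
            # mixture of a fine and a coarse random-walk kernel; the coarse
            # one lets pinned small-clone proportions escape local optima
            scale = kappa if rng.random() < 0.7 else kappa / 10.0
            a_fwd = scale * cur + 0.5
            prop = rng.dirichlet(a_fwd)
            a_rev = scale * prop + 0.5
            f2 = f.copy()
            f2[:, r] = prop
            ll2 = _pooled_ll(assign, s, f2, alt, ref)
            hastings = _dirichlet_logpdf(cur, a_rev) - _dirichlet_logpdf(prop, a_fwd)
            n_prop[2] += 1
            if math.log(rng.random()) < ll2 - ll + hastings:
                ll, f = ll2, f2
                n_acc[2] += 1
        trace[step + 1] = ll
        if ll > best[0]:
            best = (ll, parent.copy(), assign.copy(), f.copy())

    rates = {
        name: (n_acc[i] / n_prop[i] if n_prop[i] else float("nan"))
        for i, name in enumerate(("topology", "reassignment", "proportions"))
    }
    # convergence: improvement of the running-best likelihood over the final
    # window must be negligible relative to its magnitude
    win = max(int(cfg.max_steps * cfg.convergence_window), 1)
    running_best = np.maximum.accumulate(trace)
    gain = running_best[-1] - running_best[-win]
    converged = bool(gain <= cfg.convergence_tol * max(abs(running_best[-1]), 1.0))
    return best, trace, rates, converged


def _ll_constant(alt: np.ndarray, depth: np.ndarray) -> float:
    """Binomial choose terms dropped from the pooled per-step likelihood."""
    return float(
        (gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)).sum()
    )


def mcmc_infer(
    clusters: list[MutationCluster],
    counts,
    cfg: McmcConfig | None = None,
) -> tuple[CloneTree, McmcDiagnostics]:
    """Infer a clone tree from clustered multiregional counts.

    ``counts`` is the VafMatrix the clusters were built from (used for the
    per-mutation likelihood constant and region labels).  Runs
    ``cfg.n_chains`` chains for each clone count K in ``cfg.k_range``
    (K counts the normal root too), selects K by BIC, and returns the
    maximum-posterior state across chains with per-chain traces, acceptance
    rates and a convergence flag per chain.  Non-convergence is flagged in
    the diagnostics, never suppressed.
    """
    if not clusters:
        raise ValueError("need at least one cluster")
    cfg = cfg or McmcConfig()
    regions = list(counts.vaf.columns)
    alt = np.vstack([c.alt for c in clusters]).astype(float)
    depth = np.vstack([c.depth for c in clusters]).astype(float)
    ref = depth - alt
    const = _ll_constant(
        np.asarray(counts.alt, dtype=float), np.asarray(counts.depth, dtype=float)
    )
    n_obs = int(np.asarray(counts.depth).size)

    root_rng = np.random.default_rng(cfg.seed)
    k_lo, k_hi = cfg.k_range
    bic_by_k: dict[int, float] = {}
    results = {}
    for k in range(k_lo, k_hi + 1):
        chain_out = []
        for _ in range(cfg.n_chains):
            rng = np.random.default_rng(root_rng.integers(2**31))
            chain_out.append(_run_chain(alt, ref, len(clusters), k, cfg, rng))
        lls = [c[0][0] for c in chain_out]
        best_chain = int(np.argmax(lls))  # ties -> lowest index
        best_ll = lls[best_chain] + const
        n_params = len(regions) * (k - 1)
        bic_by_k[k] = -2.0 * best_ll + n_params * math.log(n_obs)
        results[k] = (chain_out, best_chain, best_ll)

    best_k = min(bic_by_k, key=lambda k: (bic_by_k[k], k))
    chain_out, best_chain, best_ll = results[best_k]
    ll_pooled, parent, assign, f = chain_out[best_chain][0]

    labels = [ROOT] + [f"C{i}" for i in range(1, best_k)]
    parent_map: dict[str, str | None] = {ROOT: None}
    for j in range(1, best_k):
        parent_map[labels[j]] = labels[parent[j]]
    branch = {}
    for ci, cl in enumerate(clusters):
        for m in cl.members:
            branch[m] = labels[assign[ci]]
    tree = CloneTree(
        parent=parent_map,
        branch_assignments=branch,
        proportions=pd.DataFrame(f, index=labels, columns=regions),
    )
    tree.validate()
    diags = McmcDiagnostics(
        traces=[c[1] + const for c in chain_out],
        acceptance_rates=[c[2] for c in chain_out],
        converged=[c[3] for c in chain_out],
        best_chain=best_chain,
        best_k=best_k,
        bic_by_k=bic_by_k,
        log_likelihood=best_ll,
    )
    return tree, diags


# ---------------------------------------------------------------------------
# downstream labels


def identify_truncal(tree: CloneTree) -> dict[str, str]:
    """Label each mutation truncal (on the root -> ancestral-clone edge) or branch.

    A tree whose root edge carries no mutations — the hypermutator / star
    pattern — yields an empty truncal set.
    """
    tree.validate()
    anc = tree.ancestral_clone
    if anc is None:
        return {m: "branch" for m in tree.branch_assignments}
    return {
        m: ("truncal" if e == anc else "branch")
        for m, e in tree.branch_assignments.items()
    }


def mutation_relations(tree: CloneTree) -> dict[tuple[str, str], str]:
    """Label-free topology signature: the ancestry relation between every
    mutation pair (same edge / ancestor / descendant / sibling).

    Two trees place their mutations identically — up to arbitrary clone
    labels — exactly when these relation maps are equal, so this is the
    ancestor-set comparison used to score topology recovery.
    """
    tree.validate()
    muts = sorted(tree.branch_assignments)
    sub = {e: tree.subtree(e) for e in set(tree.branch_assignments.values())}
    out = {}
    for i, a in enumerate(muts):
        ea = tree.branch_assignments[a]
        for b in muts[i + 1 :]:
            eb = tree.branch_assignments[b]
            if ea == eb:
                rel = "same"
            elif eb in sub[ea]:
                rel = "ancestor"
            elif ea in sub[eb]:
                rel = "descendant"
            else:
                rel = "sibling"
            out[(a, b)] = rel
    return out


def proportions_table(tree: CloneTree) -> pd.DataFrame:
    """Per-region clone percentages, rounded to one decimal."""
    if tree.proportions is None:
        raise ValueError("tree has no proportions")
    return (tree.proportions * 100).round(1)
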