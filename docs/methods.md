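# Methods

## Setting and model

A resected primary tumour is sampled in `R` regions (default 3, the
practical minimum for clinical workflows). Each region is a mixture of a
normal-cell population and one or more tumour clones; the clones form a
rooted tree in which the *ancestral* clone hangs off the normal root and
every other tumour clone descends from it. A somatic mutation sits on one
edge of this tree and is carried by every clone at or below that edge.

All variants are treated as diploid heterozygous SNVs, so the expected
variant allele frequency of mutation `m` in region `r` is

    q(m, r) = 0.5 · Σ_{c ∈ carriers(m)} φ(c, r)

where `φ` is the clone-proportion matrix (columns sum to 1 and include the
normal clone). Copy-number effects on VAF are deliberately excluded: the
panel data this models cannot support joint SNV/CNA genotyping, and the
SNV-only simplification keeps the likelihood identifiable. Copy-number
profiles are consumed only for between-region Pearson correlation
summaries.

Two mutation classes drive everything downstream:

- **founder** — present in *every* sampled region, judged binarily from
  filter passes (optionally augmented by dPCR-rescued presence);
- **truncal** — assigned by tree inference to the edge above the ancestral
  clone, i.e. acquired before any clonal divergence.

Founder status is an observable property of the data; truncal status is a
model-based inference. In the noise-free limit every truncal mutation is a
founder mutation (it is carried by all tumour clones, hence present
wherever tumour cells are), and the test suite asserts this containment.
The converse fails: a mutation private to a clone that happens to be
present in all regions is founder but not truncal.

Hypermutators (> 10 mutations per Mb of panel footprint, strict
inequality) cannot be assumed to derive from a single transformed cell;
their founder/truncal enumeration is suppressed and the simulator's
hypermutator mode reproduces the pattern by placing all mutations on leaf
edges.

## Variant retention filter

Per-region calls are kept when depth ≥ 20, VAF ≥ 5%, alt reads ≥ 4 and a
one-sided Fisher exact test of tumour alt enrichment over the matched
normal gives p < 0.05 (skipped when no normal coverage is supplied). These
re-express caller-level retention rules as pure count filters; BAM-level
read QC is upstream and out of scope. The filter is monotone in alt reads
at fixed depth — a property test guards this. Thresholds are a frozen
dataclass and configurable.

## Clone-tree MCMC

Mutations are first clustered on their per-region VAF vectors (Lloyd's
k-means with k-means++ seeding; k chosen by minimum spherical-Gaussian BIC
over 1..max_clusters). Clustering pools per-cluster read counts, which is
likelihood-exact for placement because members of a cluster share `q`.

The sampler is Metropolis–Hastings over three blocks (default mix
0.3/0.3/0.4):

- **topology**: subtree prune–regraft of a non-ancestral clone onto any
  clone outside its own subtree (symmetric, since the number of valid
  attachment points depends only on the moved subtree's size);
- **assignment**: move one cluster to a uniformly chosen edge (symmetric);
- **proportions**: per-region Dirichlet random walk, proposal
  `Dir(κ·φ + ½)` with the Hastings correction, where κ is drawn from a
  fine/coarse mixture (κ, κ/10 with probability 0.7/0.3) so that pinned
  small-clone proportions can escape local modes.

Priors are uniform (topology, assignment) and flat Dirichlet
(proportions), so the retained maximum-posterior state is the maximum-
likelihood state. Success probabilities are clamped to `[1e-9, 1 − 1e-9]`
so empty cells stay finite. Each chain starts from a random recursive tree
with the highest-VAF cluster on the truncal edge. The initial state's
log-likelihood heads the trace, and the running maximum is retained, so
the returned state provably dominates every chain's starting point.

Defaults mirror long-run practice: 10 chains, 100,000 maximum steps, 50%
burn-in (benchmarks in this repository run 10,000 steps, scaled down to
fit a single-CPU budget; recovery is unchanged). The clone count K
(including the normal root) is selected by BIC over a user range (default
2–6) with `n_regions · (K − 1)` free parameters. Convergence is
programmatic rather than visual: a chain is flagged converged when its
running-best log-likelihood improves by less than `1e-4` (relative) over
the final 10% of steps; non-convergence is reported in the diagnostics,
never suppressed. Ties in the maximum across chains break to the lowest
chain index, making runs bit-reproducible per seed.

### Identifiability and the recovery benchmark

Chain vs star topologies are *not* always distinguishable from regional
VAFs: a star reproduces a chain's expected VAFs exactly whenever the trunk
clone's proportion exceeds the nested clone's in every region (absorb the
grandchild into the child and subtract it from the trunk). Under symmetric
Dirichlet(1) mixes this degeneracy is common, and on such draws the
mimicking topology can even exceed the truth's likelihood — no sampler can
recover it. The topology-recovery benchmark therefore uses the standard
multi-region simulation design in which each sampled region is enriched
for a different subclone (`region_clone_bias = 8` added to that clone's
Dirichlet weight), which violates the degeneracy condition with a margin
far above binomial noise at depth 1000. Recovered topologies are compared
label-free via the pairwise mutation ancestry relation (same edge /
ancestor / descendant / sibling). The general-purpose simulator default
remains the unbiased symmetric Dirichlet.

## dPCR model and detection rule

`VAF(%) = FAM / (FAM + VIC) × 100`, a plain dot ratio with no Poisson
multi-template-per-dot correction (matching how such assays are read out
at the low template numbers that matter here; 2 FAM dots among 20,000
equal the 0.01% system floor). The detection rule requires wild-type dots
and either ≥ 2 FAM dots at one timepoint or ≥ 1 FAM dot at each of two
*adjacent sampling* timepoints ("adjacent" ignores the calendar gap, since
sampling is irregular). The adjacency clause is ambiguous in prose; the
lenient reading above is the default and a strict reading (≥ 2 dots at
each adjacent timepoint, which collapses into the standalone rule) is
available via `rule="strict"`. Detection is monotone in FAM counts
(property-tested), and under the binomial partitioning model a
zero-template sample can never produce a mutant dot, so the false-detection
rate at true VAF 0 is exactly zero.

## Monitoring logic

Day 0 is the primary-resection day; negative days are preoperative.
Molecular relapse is the earliest *sustained* post-operative positivity:
the timepoint either satisfies the two-dot rule alone or its next sampled
timepoint is also detected, and (unless positivity starts at the first
post-operative sample) at least one earlier post-operative sample was
negative. Lead time is `imaging_relapse day − molecular relapse day`
(positive = ctDNA first). Clinical-validity categories:

- *early relapse prediction* — lead time > 0;
- *treatment efficacy* — within a chemotherapy epoch, the last sampled VAF
  falls below 50% (configurable) of the first detected sample's VAF, or
  clears entirely; the margin is an operationalisation of qualitatively
  described declines;
- *non-relapse corroboration* — no imaging relapse and every post-operative
  timepoint undetected (excludes early relapse prediction by construction);
- *false negative* — imaging relapse without a molecular call;
- *false positive* — molecular call without imaging relapse by the end of
  follow-up (last sampled day; later relapse is censored).

CEA series are carried for reporting only and never enter ctDNA logic.

## Synthetic data: what it emulates, and what it does not

Defaults state the emulated world: 3 regions; cellularity 0.5 per region
(the 40–60% band typical of banked resection specimens); 8 mutations per
tumour (the per-tumour average once hypermutators are excluded — also the
only value consistent with the 1.0 Mb default footprint and the strict
> 10/Mb hypermutator rule); truncal weight 0.3; mean panel depth 500
(benchmarks use 1000); 20,000 droplets per assay so that the two-dot
minimum equals the 0.01% floor; hypermutator mode multiplies the mutation
count fourfold. Clone-tree topologies are drawn uniformly over labelled
rooted topologies via random Prüfer sequences. Depth is zero-truncated
Poisson; alt counts are binomial — no sequence-context error model, no
UMIs, no CNA, no spatial geometry. Plasma trajectories are piecewise-
exponential in total burden (surgery multiplies by a residual factor,
treatment epochs apply per-day decay, relapse applies per-day growth),
capped at VAF 0.5 and floored to 0 below the detection floor; published
evidence on ctDNA shedding kinetics is qualitative, so the trajectory
module claims logical structure, not kinetic realism. A green monitoring
test therefore establishes that the decision logic is correct on its
stated inputs, not that real relapse dynamics look like these curves.

## Numerical choices

- Quantiles: linear interpolation between order statistics.
- Mann–Whitney U: exact null when both groups have n ≤ 8 and no ties,
  otherwise the tie-corrected normal approximation with continuity
  correction.
- Percentages reported to one decimal; proportion tables to one decimal
  with columns re-summing to 100 ± 0.2 after rounding.
- All generators are `numpy.random.default_rng` with explicit integer
  seeds; one root generator per simulation spawns child seeds, so outputs
  are bit-identical across runs.

## Known limitations

- SNV-only likelihood: CNA-driven VAF distortion will mislead placement.
- K-selection by BIC is a heuristic; with few regions, adjacent K values
  can be near-tied.
- Chain-vs-star degeneracy (above) is intrinsic to mixture data: on
  unbiased Dirichlet mixes the inferred topology is the likelihood's
  choice, not necessarily the generative one.
- The Fisher exact filter stands in for the original caller's p-value; the
  two need not match record-for-record.
- Double-primary patients are handled one tumour at a time; no shared-tree
  modelling.
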