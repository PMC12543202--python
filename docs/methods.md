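# Methods

This note documents the models, defaults and design choices behind
`gczoner`, in the order the pipeline runs them.

## Marker catalogs

A GC-substage catalog pairs, for each substage, one upregulated and one
downregulated marker set.  GMT has no pairing concept, so pairing is
encoded in set names (`<substage>__up` / `<substage>__down`, delimiter
configurable); a catalog with an unpaired substage is rejected at parse
time rather than silently scored one-sided.  Before scoring, every set is
intersected with the measured gene universe; a substage is dropped (and
reported) when either direction retains fewer than `min_set_size` genes
(default 5 — enrichment statistics on smaller sets are dominated by a
handful of rank positions and are not worth reporting).  Gene identifiers
are opaque strings; symbol/Ensembl mapping is deliberately out of scope.

## Synthetic cohorts

The generator emulates an integrated multi-group bulk RNA-seq cohort with
planted, fully known signal.  Per gene g and sample s the log2 mean is

    baseline_g + delta·[g ∈ up(z_s)] − delta·[g ∈ down(z_s)]
               + batch_offset(b_s)_g + Normal(0, sigma)

where z_s is the sample's planted substage (or none) and b_s its batch.
Counts are Gamma–Poisson (negative binomial) around the exp2 of that,
rescaled so each sample's expected total equals a uniform-random library
size.  Defaults:

| parameter | default | meaning |
|---|---|---|
| n_genes | 5000 | gene universe |
| n_substages, n_up, n_down | 13, 50, 50 | catalog shape |
| groups | 5 × 20 | naive, cd27dull, cd27bright, mcll, umcll |
| delta | 2.0 | planted log2 shift on markers |
| sigma | 0.5 | per-gene, per-sample log2 noise SD |
| batch_offsets | {cohort1: 0, cohort2: 0.5} | SD of per-gene additive log2 batch offsets |
| nb_dispersion | 0.15 | NB dispersion φ (var = m + φm²), typical bulk RNA-seq |
| lib_size_range | 1–2 M | uniform library sizes |

Choices worth stating:

- **Additive log-scale signal.**  Planted shifts are additive in log2 so
  that log-CPM shifts equal delta up to normalization, keeping
  parameter-recovery assertions analytic.
- **Disjoint marker sets.**  Real GC signatures overlap; the simulated
  ones are pairwise disjoint by default (an `overlap_fraction` knob
  exists, default 0).  Disjointness makes the planted truth unambiguous.
- **Planted assignment.**  The five default groups are planted with five
  distinct substages (umcll→DZ_a, mcll→INT_c, cd27bright→LZ_a,
  cd27dull→INT_a, naive→LZ_b), a deliberately arbitrary assignment that
  loosely echoes a dark-zone origin for UM-CLL and a later intermediate
  state for M-CLL.  Nothing downstream depends on which substage goes
  where, only that they differ.
- **What the generator does not emulate:** gene–gene correlation beyond
  the planted blocks, composition effects, GC-content/length biases,
  sample-quality heterogeneity, overlapping signatures, or any real
  dataset's expression distribution after integration.  Passing recovery
  tests therefore demonstrates correctness of the machinery under the
  stated generative model, not calibrated performance on real cohorts.

All randomness flows from a single seed through named `SeedSequence`
children (catalog vs cohort), so every output is bit-reproducible.

## Expression preparation

Counts → CPM with a prior count: `(c + prior) / (L + 2·prior) · 1e6`,
then log2 (prior default 0.5; the 2·prior denominator offset keeps the
transform finite at zero counts).  Gene filtering keeps genes with
CPM ≥ 1 in ≥ 3 samples by default — conventional bulk practice at this
cohort size; both thresholds are arguments.  No TMM/quantile
normalization and no outlier detection are applied; samples enter as
given.

Batch adjustment fits, per gene, the additive fixed-effects model
`expression ~ group + batch + run_type` by least squares and subtracts
only the fitted batch/run-type contributions, protecting group effects.
This is deterministic and closed-form (no cross-gene shrinkage), and is
idempotent.  A nuisance column that is a linear combination of other
nuisance columns (run type fully determined by batch, say) is dropped
silently; a nuisance column aliased with the group design raises an
error naming the factor, since its effect cannot be separated.  Sample
quality weights are not implemented: the unweighted fit feeds a
moderated t downstream, and the package's validation surface is
synthetic-data recovery, where per-sample weights add nothing.

## Enrichment scoring

The single-sample score follows the published GSVA construction for
continuous expression, implemented here from its definition:

1. Gaussian-kernel CDF per gene across **all samples jointly** (healthy
   and disease together), bandwidth `sd/4`.  Genes with zero spread get
   z = 0.5 everywhere (uninformative mid-rank) instead of being dropped,
   preserving matrix shape; the count of such genes is logged.
2. Per-sample ranking of z descending with ties broken lexicographically
   by gene id — determinism across platforms beats any statistical
   nicety here — mapped to the symmetric statistic `r = |p/2 − rank|`.
3. A weighted random walk in rank order: in-set steps add
   `r^τ / Σ_set r^τ` (τ = 1), out-of-set steps subtract `1/(p − |S|)`;
   the score is `max(0, max dev) + min(0, min dev)` ("max_diff", the
   default) or the signed largest-magnitude deviation ("max_abs").

Kernel, τ and score mode are all config-exposed (`WalkConfig`); an
empirical-CDF kernel ("none") is available.  Degenerate corner: if every
in-set gene sits exactly at the rank center (all r = 0), in-set steps
fall back to equal weights `1/|S|` so the walk stays defined.  Scores
are bounded in [−1, 1] by construction (each side of the walk sums to at
most 1).  No Poisson kernel (inputs are log-CPM by contract), no ssGSEA
variant, no empirical ES p-values.

## Mapping and dominance

Differential enrichment `D(z, s) = ES_up − ES_down` lies in [−2, 2] and
is invariant to any constant shift of the ES matrix.  The dominant call
is the argmax, assigned only when strictly positive — a literal reading
of "highest positive" — with exact ties resolved to the
lexicographically smallest substage name, flagged and logged (ties are
measure-zero on continuous scores but arise from degenerate inputs).
"Unassigned" is first-class in composition tables and counts as
not-dominant in every 2×2 test.

The 2×2 encoding per (group, substage) is in-group/out-of-group ×
dominant/not.  Fisher's exact test enumerates the hypergeometric support
directly (no approximation); the one-sided "greater" alternative is the
default because dominance is directional (two-sided available).  BH runs
across all (group × substage) tests jointly — the more conservative
family choice.  Cohen's d is computed on the substage's differential
scores, in-group vs all other samples, because the differential score is
the quantity the dominance claim is about.  The combined gate is
`adj_p < 0.05` and `|d| ≥ 0.3`, mirroring dot-plot reference lines at
1.3 (−log10 0.05), 0.3 and 0.5; both thresholds are arguments.  The
effect classes overlap at |d| = 0.5 in their published wording ("≤ 0.5"
medium, "≥ 0.5" large); this implementation assigns 0.5 to large and
documents the ambiguity rather than guessing intent.  Groups with fewer
than two samples on either side get an undefined (NaN) effect size and
can never be flagged, though their Fisher test still runs.

## Differential expression

Two-group fits only (the analyses this supports are all pairwise):
logFC = mean difference, pooled within-group variance s²_g on
d_g = n_A + n_B − 2 df, v = 1/n_A + 1/n_B.  The variance prior
(d₀, s₀²) is estimated by moment matching on log variances under the
scaled-F model `s²_g ~ s₀²·F(d_g, d₀)`, using digamma/trigamma
identities and a Newton inversion of the trigamma function; when the
spread of log s² is at or below the pure chi-square component the prior
degenerates to d₀ = ∞ with s₀² the arithmetic mean of s² (unbiased for
the common variance in that regime).  The moderated statistic uses
`s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)` on d₀ + d_g df; d₀ = 0 is
accepted as the explicit no-shrinkage (ordinary t) limit.  With a
fold-change threshold τ > 0 the interval-null p-value
`P[T > (|logFC| − τ)/se] + P[T > (|logFC| + τ)/se]` replaces the point
null; it is conservative relative to τ = 0 by construction.  The test
suite cross-checks both branches against values computed independently
with limma on fixed matrices; the only intentional divergence is the df
convention at d₀ = ∞, where this implementation takes the literal
normal limit while limma caps df at the pooled residual total.

## Pipeline and reproducibility

`run_pipeline` executes simulate → prep → enrich → map → test → de from
a YAML-serializable config (defaults mirror everything above), writing
plain-text artifacts and a manifest of SHA-256 checksums; identical
config + seed gives identical checksums, which is how end-to-end
determinism is tested.  Tie-breaks, dropped substages and constant genes
are logged at INFO/WARNING so every discretionary rule actually
exercised in a run is auditable.  The IGHV labeller is the standard
cutoff: SHM ≤ 2.0% → unmutated, > 2.0% → mutated.

## Problem sizes in the shipped checks

The planted-recovery check runs the full default cohort (5000 genes,
100 samples, 13 substages); the type-I check uses 12 replicate null
cohorts at 800 genes × 24 samples with 10/10-gene marker sets; prior
recovery uses 5000 synthetic variances; DE recovery plants 40 up / 60
down genes in a 500 × 16 matrix.  These sizes give stable pass/fail
behaviour across seeds while keeping the whole suite fast.

## Known limitations

- The enrichment parameters (kernel, bandwidth, τ, score mode) are the
  published GSVA defaults, declared rather than fitted; other choices
  would shift absolute ES values.
- Fisher's enumeration is exact but O(min(row, column) margin) per
  table — fine for cohort-scale counts, not for thousands of samples
  per cell.
- The 2×2 layout, test sidedness and the variable under Cohen's d are
  documented conventions of this package; other encodings of "dominant
  in a group" are defensible and would move p-values.
- No probabilistic (soft) substage assignment; a sample whose top two
  differential scores are close still gets a single hard call.
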