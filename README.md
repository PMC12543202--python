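# gczoner

Map bulk B-cell transcriptomes onto germinal-center (GC) substages.

Chronic lymphocytic leukemia (CLL) splits into two subtypes by somatic
hypermutation (SHM) of the IGHV locus — unmutated (UM-CLL, SHM ≤ 2.0%) and
mutated (M-CLL, SHM > 2.0%) — and a long-standing question is where in the
B-cell maturation path each subtype originates.  One way to ask the question
of transcriptomes: score every sample against marker signatures of the
thirteen GC B-cell substages (dark zone → intermediate → light zone states)
defined from single-cell atlases of tonsillar GC B cells, and test which
substage dominates each patient group.  `gczoner` implements that analysis
as a tested, fully synthetic-data-backed pipeline for anyone who wants to
place bulk B-cell or B-cell-malignancy samples on the GC map: no external
cohort is required, and every stage can be validated against planted ground
truth.

## The method

Each GC substage *z* is described by a **paired signature**: 50 upregulated
and 50 downregulated marker genes (26 marker sets for 13 substages).  For a
log2-CPM expression matrix with *p* genes and *n* samples:

1. **Single-sample enrichment (GSVA-style).**  Per gene *g*, a Gaussian-kernel
   CDF estimate across all samples, `z_gs = (1/n) Σ_k Φ((x_gs − x_gk)/h_g)`
   with bandwidth `h_g = sd_g / 4`; per sample, genes are ranked by `z`
   descending and mapped to the symmetric statistic `r = |p/2 − rank|`; a
   weighted Kolmogorov–Smirnov-like random walk over the ranking (in-set
   steps `∝ r^τ`, τ = 1; out-of-set steps `−1/(p − |S|)`) gives the
   enrichment score `ES(S, s) ∈ [−1, 1]` for every marker set *S*.
2. **Differential enrichment and dominant substage.**
   `D(z, s) = ES(z_up, s) − ES(z_down, s)`; the dominant substage of a sample
   is `argmax_z D(z, s)`, assigned only when the maximum is strictly
   positive, otherwise "unassigned".
3. **Group-level dominance.**  Per (group, substage), a 2×2 table (in-group ×
   dominant) is tested with Fisher's exact test (one-sided, by direct
   hypergeometric enumeration), Benjamini–Hochberg adjusted across all
   tests jointly, and gated by Cohen's d on the differential scores
   (in-group vs rest).  A substage is *dominant* in a group when
   `adj_p < 0.05` **and** `|d| ≥ 0.3`; effect classes follow Cohen
   (small ≤ 0.3 < medium < 0.5 ≤ large).
4. **Differential expression.**  Two-group empirical-Bayes moderated t with
   variance shrinkage `s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)`, the prior
   (d₀, s₀²) estimated by moment matching on log variances, and an
   interval-null fold-change threshold test (|log2FC| > 1 at FDR 0.05).
5. **Synthetic cohorts.**  A generator plants substage signatures
   (log2 shift ±δ on the up/down markers) into negative-binomial counts with
   per-batch offsets and lognormal baselines, and returns the ground truth,
   so recovery, type-I error and effect estimation are all checkable.

## Worked example

```python
import gczoner as gz

cfg = gz.SimConfig(seed=1)               # 5 groups x 20 samples, delta=2.0
catalog = gz.make_marker_catalog(cfg)    # 13 substages, 26 marker sets
counts, meta, truth = gz.simulate_cohort(cfg, catalog)

expr = gz.batch_adjust(gz.log_cpm(gz.filter_low_expression(counts)), meta)
rcat, _ = gz.restrict_to_universe(catalog, expr)
es = gz.score_catalog(expr, rcat)        # 26 sets x 100 samples, in [-1, 1]
diff = gz.differential_scores(es, rcat)
calls = gz.dominant_call(diff)
zones = gz.zone_tests(calls, diff, meta)
print(zones[zones.dominant_flag][["group", "substage", "adj_p", "cohens_d"]])
```

prints

```
         group substage         adj_p   cohens_d
9        naive     LZ_b  2.425448e-20  17.759949
16    cd27dull    INT_a  2.425448e-20  21.316757
34  cd27bright     LZ_a  2.425448e-20  17.938891
44        mcll    INT_c  2.425448e-20  19.196829
52       umcll     DZ_a  2.425448e-20  19.596655
```

— each group is flagged for exactly the substage that was planted into it,
with BH-adjusted Fisher p-values far below 0.05 and large Cohen's d; 100 of
100 samples get the correct dominant call.  The `examples/` scripts walk
through each capability (simulation + mapping, raw enrichment scoring,
dominance testing with the dot-plot export, differential expression), and
the same steps are available from a shell via `gczoner {simulate, prep,
enrich, map, test, de, run}`.

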