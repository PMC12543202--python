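"""Simulate a five-group B-cell cohort and map every sample onto its
dominant germinal-center substage.

Each group carries one planted substage signature (log2 shift +2 on its
50 up-markers, -2 on its 50 down-markers).  The printed recovery rate is
the fraction of samples whose dominant call matches the planted truth —
near 100% at this signal strength.
"""

import numpy as np

import gczoner as gz

cfg = gz.SimConfig(seed=1)  # 13 substages, 5 groups x 20 samples, delta=2, sigma=0.5
catalog = gz.make_marker_catalog(cfg)
counts, meta, truth = gz.simulate_cohort(cfg, catalog)
print(f"cohort: {counts.shape[0]} genes x {counts.shape[1]} samples, "
      f"{catalog.n_substages} substages ({len(catalog)} marker sets)")

expr = gz.batch_adjust(gz.log_cpm(gz.filter_low_expression(counts)), meta)
rcat, _ = gz.restrict_to_universe(catalog, expr)
es = gz.score_catalog(expr, rcat)
diff = gz.differential_scores(es, rcat)
calls = gz.dominant_call(diff)

recovery = np.mean([calls.loc[s, "dominant"] == truth.planted_for(s)
                    for s in calls.index])
print(f"dominant-call recovery vs planted truth: {100 * recovery:.1f}%")

comp = gz.composition(calls, meta, substage_order=list(diff.index))
print("\nper-group composition (non-zero rows):")
print(comp[comp["count"] > 0].to_string(index=False))
# Each group's modal substage should be the one planted for it.
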