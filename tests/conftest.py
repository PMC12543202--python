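import numpy as np
import pandas as pd
import pytest

import gczoner as gz


@pytest.fixture(scope="session")
def small_sim_config():
    """A fast 4-substage, 2-group cohort for module-level checks."""
    return gz.SimConfig(
        n_genes=1000,
        n_substages=4,
        n_up=20,
        n_down=20,
        groups=(("g1", 8, "DZ_a"), ("g2", 8, "INT_a")),
        substage_names=("DZ_a", "INT_a", "LZ_a", "PreM"),
        batch_offsets={"b1": 0.0, "b2": 0.3},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_sim_config):
    catalog = gz.make_marker_catalog(small_sim_config)
    counts, meta, truth = gz.simulate_cohort(small_sim_config, catalog)
    return {"catalog": catalog, "counts": counts, "meta": meta, "truth": truth}


@pytest.fixture(scope="session")
def planted_run():
    """The planted study-condition cohort (delta 2.0, sigma 0.5, 20/group,
    13 substages, 50/50 markers) run through the whole analysis once."""
    cfg = gz.SimConfig(seed=1)
    catalog = gz.make_marker_catalog(cfg)
    counts, meta, truth = gz.simulate_cohort(cfg, catalog)
    expr = gz.log_cpm(gz.filter_low_expression(counts))
    expr = gz.batch_adjust(expr, meta)
    rcat, report = gz.restrict_to_universe(catalog, expr)
    es = gz.score_catalog(expr, rcat)
    diff = gz.differential_scores(es, rcat)
    calls = gz.dominant_call(diff)
    zones = gz.zone_tests(calls, diff, meta)
    return {
        "config": cfg,
        "catalog": rcat,
        "report": report,
        "counts": counts,
        "meta": meta,
        "truth": truth,
        "expr": expr,
        "es": es,
        "diff": diff,
        "calls": calls,
        "zones": zones,
    }


@pytest.fixture()
def toy_meta():
    def make(groups, batches=None, runs=None):
        n = len(groups)
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "group": groups,
                "batch": batches or ["b1"] * n,
                "run_type": runs or ["paired"] * n,
            }
        )

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
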