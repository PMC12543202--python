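"""End-to-end orchestration: simulate -> prep -> enrich -> map -> test -> de.

A run is described by a YAML-serializable config dict; every stage reads
the previous stage's artifacts from the output directory, so stages can
be toggled independently as long as their inputs exist.  The manifest
records the config hash and a SHA-256 checksum of every produced file,
making end-to-end determinism checkable as manifest equality.

Also houses the IGHV somatic-hypermutation labeller used to split CLL
cohorts into mutated / unmutated subtypes.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import catalog as cat
from . import de as de_mod
from . import enrichment, io, mapping, prep, simulate, stats

logger = logging.getLogger(__name__)

STAGES = ("simulate", "prep", "enrich", "map", "test", "de")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "stages": list(STAGES),
    "sim": {},  # SimConfig overrides; ignored when input paths are given
    "inputs": {"counts": None, "meta": None, "gmt": None},
    "prep": {"prior_count": 0.5, "min_cpm": 1.0, "min_samples": 3,
             "batch_cols": ["batch", "run_type"]},
    "catalog": {"min_set_size": 5, "delim": "__"},
    "enrichment": {"tau": 1.0, "score_mode": "max_diff", "kernel": "gaussian"},
    "test": {"alpha": 0.05, "effect_gate": 0.3, "sided": "greater"},
    "de": {"contrast": ["mcll", "umcll"], "lfc_threshold": 1.0, "alpha": 0.05},
}


def ighv_label(shm_percent: float) -> str:
    """CLL subtype from percent somatic hypermutation in the IGHV locus:
    <= 2.0% -> "unmutated" (UM-CLL), > 2.0% -> "mutated" (M-CLL)."""
    if not (0.0 <= shm_percent <= 100.0):
        raise ValueError(f"SHM percent must be in [0, 100], got {shm_percent}")
    return "unmutated" if shm_percent <= 2.0 else "mutated"


def _merge(base: Mapping, override: Mapping) -> dict:
    out = copy.deepcopy(dict(base))
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), Mapping):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path_or_dict: str | Path | Mapping | None = None) -> dict:
    """Merge a YAML file or dict over the documented defaults."""
    if path_or_dict is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    if isinstance(path_or_dict, Mapping):
        user = dict(path_or_dict)
    else:
        user = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = _merge(DEFAULT_CONFIG, user)
    for st in cfg["stages"]:
        if st not in STAGES:
            raise ValueError(f"unknown stage {st!r}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: Mapping | str | Path | None, out_dir: str | Path) -> dict:
    """Execute the enabled stages in dependency order; return the manifest.

    Identical config + seed gives identical output checksums.  A stage
    failure propagates after earlier stages' outputs are on disk.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    enabled = list(cfg["stages"])
    produced: dict[str, list[str]] = {}
    warnings_log: list[str] = []

    def _emit(stage: str, name: str) -> Path:
        produced.setdefault(stage, []).append(name)
        return out / name

    if "simulate" in enabled:
        sim_cfg = simulate.SimConfig(**{**cfg["sim"], "seed": seed})
        catalog = simulate.make_marker_catalog(sim_cfg)
        counts, meta, truth = simulate.simulate_cohort(sim_cfg, catalog)
        io.write_counts_tsv(counts, _emit("simulate", "counts.tsv"))
        io.write_meta_tsv(meta, _emit("simulate", "meta.tsv"))
        cat.write_gmt(catalog, _emit("simulate", "markers.gmt"))
        io.write_truth_json(truth, _emit("simulate", "truth.json"))

    counts_path = cfg["inputs"]["counts"] or out / "counts.tsv"
    meta_path = cfg["inputs"]["meta"] or out / "meta.tsv"
    gmt_path = cfg["inputs"]["gmt"] or out / "markers.gmt"

    if "prep" in enabled:
        pc = cfg["prep"]
        counts = io.read_counts_tsv(counts_path)
        meta = io.read_meta_tsv(meta_path)
        filtered = prep.filter_low_expression(
            counts, min_cpm=pc["min_cpm"], min_samples=pc["min_samples"]
        )
        expr = prep.log_cpm(filtered, prior_count=pc["prior_count"])
        expr = prep.batch_adjust(expr, meta, batch_cols=tuple(pc["batch_cols"]))
        io.write_expr_tsv(expr, _emit("prep", "expr.tsv"))

    if "enrich" in enabled:
        ec = cfg["enrichment"]
        expr = io.read_expr_tsv(out / "expr.tsv")
        catalog = cat.read_gmt(gmt_path, delim=cfg["catalog"]["delim"])
        catalog, report = cat.restrict_to_universe(
            catalog, expr, min_set_size=cfg["catalog"]["min_set_size"]
        )
        if report["dropped_substages"]:
            warnings_log.append(f"dropped substages: {sorted(report['dropped_substages'])}")
        cat.write_report(report, _emit("enrich", "catalog_report.json"))
        wcfg = enrichment.WalkConfig(
            tau=ec["tau"], score_mode=ec["score_mode"], kernel=ec["kernel"]
        )
        es = enrichment.score_catalog(expr, catalog, wcfg)
        es.to_csv(_emit("enrich", "es.tsv"), sep="\t", float_format="%.10g")

    if "map" in enabled:
        es = io.read_expr_tsv(out / "es.tsv")
        delim = cfg["catalog"]["delim"]
        catalog = cat.read_gmt(gmt_path, delim=delim)
        # keep only substages actually scored (some may have been dropped
        # when restricting to the measured universe)
        scored_sets = [
            s for s in catalog.sets if s.name(delim) in es.index
        ]
        catalog = cat.MarkerCatalog(sets=scored_sets)
        scored = catalog.substages
        diff = mapping.differential_scores(es, catalog, delim=delim)
        diff.to_csv(_emit("map", "diff.tsv"), sep="\t", float_format="%.10g")
        calls = mapping.dominant_call(diff)
        if calls["tie"].any():
            warnings_log.append(f"{int(calls['tie'].sum())} tie(s) in dominant calls")
        calls.to_csv(_emit("map", "calls.tsv"), sep="\t")
        meta = io.read_meta_tsv(meta_path)
        comp = mapping.composition(calls, meta, substage_order=scored)
        comp.to_csv(_emit("map", "composition.tsv"), sep="\t", index=False)

    if "test" in enabled:
        import pandas as pd

        tc = cfg["test"]
        calls = pd.read_csv(out / "calls.tsv", sep="\t", index_col=0)
        diff = io.read_expr_tsv(out / "diff.tsv")
        meta = io.read_meta_tsv(meta_path)
        zones = stats.zone_tests(
            calls, diff, meta,
            alpha=tc["alpha"], effect_gate=tc["effect_gate"], sided=tc["sided"],
        )
        zones.to_csv(_emit("test", "zones.tsv"), sep="\t", index=False, float_format="%.10g")

    if "de" in enabled:
        dc = cfg["de"]
        expr = io.read_expr_tsv(out / "expr.tsv")
        meta = io.read_meta_tsv(meta_path)
        fit = de_mod.fit_groupwise(expr, meta, tuple(dc["contrast"]))
        res = de_mod.moderated_t(
            fit, lfc_threshold=dc["lfc_threshold"], alpha=dc["alpha"]
        )
        res.to_csv(_emit("de", "de.tsv"), sep="\t", index_label="gene_id",
                   float_format="%.10g")

    cfg_text = json.dumps(cfg, sort_keys=True, default=str)
    manifest = {
        "artifact": "gczoner 0.1.0",
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": seed,
        "stages_run": enabled,
        "files": {
            name: _sha256(out / name)
            for names in produced.values()
            for name in names
        },
        "warnings": warnings_log,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
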