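"""Synthetic multi-group B-cell cohorts with planted GC-substage signal.

The generator emulates the shape of an integrated bulk RNA-seq cohort:
several sample groups (healthy B-cell subsets and CLL subtypes), each
optionally carrying one planted germinal-center substage signature, with
additive per-batch offsets on the log scale and negative-binomial
(Gamma-Poisson) count noise around library-size-scaled means.

Every downstream stage can be checked against the returned :class:`SimTruth`.
Planted shifts are additive on the log2 scale so that log-CPM shifts equal
``delta`` up to normalization, which keeps parameter-recovery assertions
analytic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import MarkerCatalog, MarkerSet

# 13 tonsillar GC B-cell substages: dark zone, intermediate and light zone
# states plus post-GC precursors, mirroring single-cell GC atlases.
DEFAULT_SUBSTAGES = (
    "DZ_a", "DZ_b", "DZ_c",
    "INT_a", "INT_b", "INT_c", "INT_d", "INT_e",
    "LZ_a", "LZ_b",
    "PreM", "FCRL_hi", "PBL",
)

# Distinct planted substages per group, loosely echoing a GC-origin story:
# UM-CLL dark zone, M-CLL later intermediate, CD27-bright light zone.
DEFAULT_GROUPS = (
    ("naive", 20, "LZ_b"),
    ("cd27dull", 20, "INT_a"),
    ("cd27bright", 20, "LZ_a"),
    ("mcll", 20, "INT_c"),
    ("umcll", 20, "DZ_a"),
)

RUN_TYPES = ("paired", "single")


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort.

    Attributes
    ----------
    n_genes : int
        Total gene universe size.
    n_substages, n_up, n_down : int
        Catalog shape: number of substages and markers per direction.
    groups : sequence of (name, n_samples, planted substage or "none")
        Cohort composition.  ``"none"`` plants no signature.
    delta : float
        Planted log2-scale shift: +delta on a planted substage's
        up-markers, -delta on its down-markers.
    sigma : float
        Log2-scale biological noise SD added per gene and sample.
    batch_offsets : mapping batch name -> float
        SD of the per-gene additive log2 offset of that batch; samples are
        assigned to batches round-robin within each group.
    nb_dispersion : float
        Negative-binomial dispersion phi (variance = m + phi * m^2);
        0 degrades to Poisson.
    lib_size_range : (int, int)
        Library sizes drawn uniformly from this inclusive range.
    overlap_fraction : float
        Fraction of each marker set allowed to be re-drawn from the whole
        universe (sets are pairwise disjoint at the default 0).
    seed : int
        Fixes all randomness bit-for-bit.
    """

    n_genes: int = 5000
    n_substages: int = 13
    n_up: int = 50
    n_down: int = 50
    groups: Sequence[tuple[str, int, str]] = DEFAULT_GROUPS
    delta: float = 2.0
    sigma: float = 0.5
    batch_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"cohort1": 0.0, "cohort2": 0.5}
    )
    nb_dispersion: float = 0.15
    lib_size_range: tuple[int, int] = (1_000_000, 2_000_000)
    overlap_fraction: float = 0.0
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 1.5
    substage_names: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_substages <= 0 or self.n_up <= 0 or self.n_down <= 0:
            raise ValueError("n_genes, n_substages, n_up, n_down must be positive")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be in [0, 1]")
        if len(self.groups) == 0:
            raise ValueError("groups must be non-empty")
        if self.lib_size_range[0] <= 0 or self.lib_size_range[1] < self.lib_size_range[0]:
            raise ValueError("lib_size_range must be a positive increasing pair")

    def substage_list(self) -> list[str]:
        if self.substage_names is not None:
            names = list(self.substage_names)
            if len(names) != self.n_substages:
                raise ValueError("substage_names length must equal n_substages")
            return names
        if self.n_substages <= len(DEFAULT_SUBSTAGES):
            return list(DEFAULT_SUBSTAGES[: self.n_substages])
        return [f"SUB_{i:02d}" for i in range(self.n_substages)]


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort.

    ``samples`` maps sample id -> (group, batch, planted substage or "none");
    ``baseline_log2`` holds the per-gene baseline log2 mean shared by all
    samples before planted/batch/noise terms.
    """

    samples: dict[str, tuple[str, str, str]]
    catalog: MarkerCatalog
    baseline_log2: pd.Series
    batch_offsets_log2: dict[str, np.ndarray] = field(default_factory=dict)

    def planted_for(self, sample_id: str) -> str:
        return self.samples[sample_id][2]


def gene_universe(n_genes: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n_genes)]


def make_marker_catalog(config: SimConfig) -> MarkerCatalog:
    """Draw a paired marker catalog from the simulated gene universe.

    All ``2 * n_substages`` sets are pairwise disjoint (at the default
    ``overlap_fraction = 0``) and the draw is fixed by ``config.seed``.
    """
    needed = config.n_substages * (config.n_up + config.n_down)
    if needed > config.n_genes:
        raise ValueError(
            f"catalog needs {needed} distinct marker genes but the universe has "
            f"only {config.n_genes}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    genes = np.array(gene_universe(config.n_genes))
    order = rng.permutation(config.n_genes)
    sets: list[MarkerSet] = []
    pos = 0
    for sub in config.substage_list():
        for direction, size in (("up", config.n_up), ("down", config.n_down)):
            chosen = list(genes[order[pos : pos + size]])
            pos += size
            n_overlap = int(np.floor(config.overlap_fraction * size))
            if n_overlap > 0:
                repl = rng.choice(genes, size=n_overlap, replace=False)
                chosen[:n_overlap] = list(repl)
                chosen = list(dict.fromkeys(chosen))  # drop accidental dups
            sets.append(MarkerSet(substage=sub, direction=direction, genes=tuple(chosen)))
    return MarkerCatalog(sets=sets)


def simulate_cohort(
    config: SimConfig, catalog: MarkerCatalog
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate counts, metadata and ground truth for one cohort.

    Per sample, the log2 mean of gene g is::

        baseline_g + delta*[g in planted up-set] - delta*[g in planted down-set]
                   + batch_offset_g + Normal(0, sigma)

    Counts are Gamma-Poisson around the exp2 of that, rescaled so each
    sample's expected total equals its uniform-random library size.

    Returns
    -------
    counts : DataFrame (genes x samples, int)
    meta : DataFrame with columns sample_id, group, batch, run_type
    truth : SimTruth
    """
    known = set(catalog.substages)
    for name, _n, planted in config.groups:
        if planted != "none" and planted not in known:
            raise ValueError(f"group {name!r} plants unknown substage {planted!r}")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genes = gene_universe(config.n_genes)
    gene_idx = {g: i for i, g in enumerate(genes)}

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)

    batch_names = list(config.batch_offsets.keys())
    batch_shift = {
        b: (rng.normal(0.0, sd, config.n_genes) if sd > 0 else np.zeros(config.n_genes))
        for b, sd in config.batch_offsets.items()
    }
    run_type_of_batch = {b: RUN_TYPES[i % len(RUN_TYPES)] for i, b in enumerate(batch_names)}

    up_mask: dict[str, np.ndarray] = {}
    down_mask: dict[str, np.ndarray] = {}
    for sub in catalog.substages:
        um = np.zeros(config.n_genes)
        dm = np.zeros(config.n_genes)
        um[[gene_idx[g] for g in catalog.get(sub, "up").genes if g in gene_idx]] = 1.0
        dm[[gene_idx[g] for g in catalog.get(sub, "down").genes if g in gene_idx]] = 1.0
        up_mask[sub], down_mask[sub] = um, dm

    sample_ids: list[str] = []
    meta_rows: list[tuple[str, str, str, str]] = []
    truth_samples: dict[str, tuple[str, str, str]] = {}
    cols: list[np.ndarray] = []
    lo, hi = config.lib_size_range
    for gname, n, planted in config.groups:
        if n <= 0:
            raise ValueError(f"group {gname!r} has non-positive sample count {n}")
        for i in range(n):
            sid = f"{gname}_{i + 1:02d}"
            batch = batch_names[i % len(batch_names)]
            log2mu = baseline + batch_shift[batch]
            if planted != "none":
                log2mu = log2mu + config.delta * up_mask[planted] - config.delta * down_mask[planted]
            if config.sigma > 0:
                log2mu = log2mu + rng.normal(0.0, config.sigma, config.n_genes)
            rel = np.exp2(log2mu)
            lib = int(rng.integers(lo, hi + 1))
            mean = rel / rel.sum() * lib
            if config.nb_dispersion > 0:
                shape = 1.0 / config.nb_dispersion
                lam = rng.gamma(shape, mean / shape)
                counts = rng.poisson(lam)
            else:
                counts = rng.poisson(mean)
            sample_ids.append(sid)
            meta_rows.append((sid, gname, batch, run_type_of_batch[batch]))
            truth_samples[sid] = (gname, batch, planted)
            cols.append(counts.astype(np.int64))

    counts_df = pd.DataFrame(np.column_stack(cols), index=genes, columns=sample_ids)
    counts_df.index.name = "gene_id"
    meta_df = pd.DataFrame(meta_rows, columns=["sample_id", "group", "batch", "run_type"])
    truth = SimTruth(
        samples=truth_samples,
        catalog=catalog,
        baseline_log2=pd.Series(baseline, index=genes, name="baseline_log2"),
        batch_offsets_log2=batch_shift,
    )
    return counts_df, meta_df, truth
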