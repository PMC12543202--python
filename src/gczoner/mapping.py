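"""From paired enrichment scores to per-sample dominant GC substage.

For each substage z and sample s the differential enrichment score is

    D(z, s) = ES(z up-set, s) - ES(z down-set, s),

so a sample resembling substage z (up-markers high, down-markers low)
scores strongly positive.  The dominant substage of a sample is the
argmax of D, assigned only when that maximum is strictly positive;
otherwise the sample is "unassigned".  Exact ties go to the
lexicographically smallest substage name with an explicit tie flag.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import DEFAULT_DELIM, MarkerCatalog

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


def differential_scores(
    es: pd.DataFrame, catalog: MarkerCatalog, delim: str = DEFAULT_DELIM
) -> pd.DataFrame:
    """Up-minus-down differential enrichment per substage and sample."""
    rows = {}
    for sub in catalog.substages:
        up, down = f"{sub}{delim}up", f"{sub}{delim}down"
        for name in (up, down):
            if name not in es.index:
                raise ValueError(f"enrichment matrix lacks row {name!r}")
        rows[sub] = es.loc[up] - es.loc[down]
    diff = pd.DataFrame(rows).T.loc[catalog.substages]
    diff.index.name = "substage"
    return diff


def dominant_call(diff: pd.DataFrame) -> pd.DataFrame:
    """Per-sample dominant substage from differential scores.

    Returns a DataFrame indexed by sample with columns ``dominant``
    (substage name or "unassigned"), ``score`` (the winning differential
    score; the maximum even when unassigned) and ``tie`` (True when the
    maximum was achieved by more than one substage).
    """
    if diff.shape[0] < 1:
        raise ValueError("need at least one substage")
    records = []
    subs = np.asarray(diff.index, dtype=object)
    D = diff.to_numpy(dtype=float)
    for j, sample in enumerate(diff.columns):
        col = D[:, j]
        best = col.max()
        winners = sorted(str(s) for s in subs[col == best])
        tie = len(winners) > 1
        if tie:
            logger.warning(
                "dominant_call: tie at score %.6g in sample %s among %s",
                best, sample, winners,
            )
        dominant = winners[0] if best > 0 else UNASSIGNED
        records.append((sample, dominant, best, tie))
    out = pd.DataFrame(records, columns=["sample_id", "dominant", "score", "tie"])
    return out.set_index("sample_id")


def composition(
    calls: pd.DataFrame,
    meta: pd.DataFrame,
    substage_order: Sequence[str] | None = None,
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-group counts and percentages of dominant substages.

    Rows are ordered by group, then substage (catalog order when
    ``substage_order`` is given, else order of first appearance), with an
    "unassigned" row last per group.  Percentages within a group sum to
    100.
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    missing = [s for s in calls.index if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    group_of = meta.loc[list(calls.index), "group"]
    if groups is None:
        groups = list(dict.fromkeys(group_of))
    if substage_order is None:
        substage_order = sorted(set(calls["dominant"]) - {UNASSIGNED})
    order = list(substage_order) + [UNASSIGNED]

    records = []
    for g in groups:
        members = calls.loc[group_of[group_of == g].index]
        n = len(members)
        if n == 0:
            raise ValueError(f"group {g!r} has no samples")
        vc = members["dominant"].value_counts()
        for sub in order:
            cnt = int(vc.get(sub, 0))
            records.append((g, sub, cnt, 100.0 * cnt / n))
    out = pd.DataFrame(records, columns=["group", "substage", "count", "percent"])
    return out
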