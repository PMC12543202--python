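"""Plain-text readers and writers for the pipeline's tabular artifacts.

Counts travel as TSV (genes in rows, header = sample ids) or as a
MatrixMarket triple (.mtx + rows.tsv + cols.tsv); metadata as TSV with
columns sample_id, group, batch, run_type; marker catalogs as GMT
(see :mod:`gczoner.catalog`); ground truth and reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .simulate import SimTruth

META_COLUMNS = ("sample_id", "group", "batch", "run_type")


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate gene or sample ids")
    return df


read_expr_tsv = read_counts_tsv


def write_expr_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def write_counts_mtx(counts: pd.DataFrame, prefix: str | Path) -> None:
    """Write ``<prefix>.mtx`` plus ``<prefix>.rows.tsv`` / ``.cols.tsv``."""
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix) + ".mtx", scipy.sparse.csr_matrix(counts.to_numpy()))
    Path(str(prefix) + ".rows.tsv").write_text("\n".join(counts.index) + "\n")
    Path(str(prefix) + ".cols.tsv").write_text("\n".join(counts.columns) + "\n")


def read_counts_mtx(prefix: str | Path) -> pd.DataFrame:
    prefix = Path(prefix)
    mat = scipy.io.mmread(str(prefix) + ".mtx")
    rows = Path(str(prefix) + ".rows.tsv").read_text().splitlines()
    cols = Path(str(prefix) + ".cols.tsv").read_text().splitlines()
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    return pd.DataFrame(dense, index=rows, columns=cols)


def write_meta_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_meta_tsv(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: metadata lacks columns {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return meta


def write_truth_json(truth: SimTruth, path: str | Path) -> None:
    payload = {
        "samples": {
            sid: {"group": g, "batch": b, "planted": pl}
            for sid, (g, b, pl) in truth.samples.items()
        },
        "substages": truth.catalog.substages,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_truth_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
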