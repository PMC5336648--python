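"""Readers, writers and normalization for expression matrices and loadings.

File conventions: expression matrices are TSV/CSV with a header row of
variable ids and a first column of observation ids (delimiter sniffed
from the extension, tab otherwise).  Loadings specs are two-column TSV
(variable_id, cluster_index 1..q) for a shared Lambda, with an optional
third ``component`` column for per-component specs.  All cluster indices
are 1-based on disk, 0-based in memory.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, InvalidSpecError, LoadingsSpec


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression_matrix(path, orientation: str = "rows") -> ExpressionMatrix:
    """Parse a delimited matrix file into an :class:`ExpressionMatrix`.

    ``orientation="rows"`` (default) means rows already are the
    observations to be clustered; ``"columns"`` transposes on read.
    Missing or non-numeric cells and duplicate ids raise with the
    offending location named.
    """
    if orientation not in ("rows", "columns"):
        raise ValueError("orientation must be 'rows' or 'columns'")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate observation ids: {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate variable ids: {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(~np.isfinite(numeric.to_numpy(dtype=float, na_value=np.nan)))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"missing or non-numeric value at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    if orientation == "columns":
        numeric = numeric.T
    return ExpressionMatrix(
        values=numeric.to_numpy(dtype=float),
        row_ids=[str(i) for i in numeric.index],
        col_ids=[str(c) for c in numeric.columns],
    )


def write_expression_matrix(x: ExpressionMatrix, path) -> None:
    pd.DataFrame(x.values, index=x.row_ids, columns=x.col_ids).to_csv(
        path, sep=_sep_for(path), index_label="observation_id"
    )


def read_loadings_spec(path, col_ids=None) -> LoadingsSpec:
    """Read a loadings spec TSV; validates against ``col_ids`` order if given."""
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"variable_id", "cluster_index"}
    if not required.issubset(df.columns):
        raise InvalidSpecError(
            f"loadings spec needs columns {sorted(required)}, got {list(df.columns)}"
        )
    per_component = "component" in df.columns
    groups = df.groupby("component") if per_component else [(1, df)]
    q = int(df["cluster_index"].max())
    mats = []
    for _, sub in groups:
        if col_ids is not None:
            order = {str(v): k for k, v in enumerate(col_ids)}
            missing = set(order) - set(sub["variable_id"].astype(str))
            if missing:
                raise InvalidSpecError(f"loadings spec missing variables: {sorted(missing)}")
            sub = sub.set_index(sub["variable_id"].astype(str)).loc[list(order)]
        lam = np.zeros((len(sub), q))
        lam[np.arange(len(sub)), sub["cluster_index"].to_numpy() - 1] = 1.0
        mats.append(lam)
    return LoadingsSpec(matrices=mats)


def write_loadings_spec(spec: LoadingsSpec, path, col_ids=None) -> None:
    p = spec.p
    ids = list(col_ids) if col_ids is not None else [f"var{j+1}" for j in range(p)]
    rows = []
    for g, mat in enumerate(spec.matrices):
        for j, lab in enumerate(np.argmax(mat, axis=1)):
            row = {"variable_id": ids[j], "cluster_index": int(lab) + 1}
            if not spec.shared:
                row["component"] = g + 1
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each observation row to mean 0, variance 1 across variables.

    Per-gene scaling is what makes expression profiles from different
    sample types comparable; rows with zero variance cannot be scaled and
    raise with the offending ids listed.
    """
    mean = x.values.mean(axis=1, keepdims=True)
    sd = x.values.std(axis=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        ids = [x.row_ids[i] for i in flat]
        raise ValueError(f"zero-variance rows cannot be normalized: {ids}")
    return ExpressionMatrix(
        values=(x.values - mean) / sd,
        row_ids=list(x.row_ids),
        col_ids=list(x.col_ids),
    )
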