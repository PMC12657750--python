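"""Readers and writers for the pipeline's tabular formats.

Count matrices travel as TSV (``gene_id`` column + one column per sample)
or MatrixMarket (``.mtx`` with ``.rows`` / ``.cols`` sidecar files, one id
per line). Sample, truth and diameter tables are plain TSV; configuration
is YAML. All TSVs are tab-separated UTF-8 with a mandatory header row and
'.' decimals.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml


def _validate_counts(counts: pd.DataFrame, origin: str) -> pd.DataFrame:
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"{origin}: duplicate gene id {dup!r}")
    if counts.columns.duplicated().any():
        dup = counts.columns[counts.columns.duplicated()][0]
        raise ValueError(f"{origin}: duplicate sample id {dup!r}")
    arr = counts.to_numpy()
    neg = np.argwhere(arr < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"{origin}: negative count at gene {counts.index[i]!r}, sample {counts.columns[j]!r}"
        )
    frac = np.argwhere(arr != np.floor(arr))
    if frac.size:
        i, j = frac[0]
        raise ValueError(
            f"{origin}: non-integer count at gene {counts.index[i]!r}, sample {counts.columns[j]!r}"
        )
    return counts.astype(np.int64)


def read_counts(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a count matrix from TSV or MatrixMarket.

    The format is inferred from the suffix unless given; MTX expects
    ``<stem>.rows`` / ``<stem>.cols`` sidecars next to the matrix file.
    Duplicate ids and negative or fractional entries are rejected with the
    offending cell named.
    """
    path = Path(path)
    fmt = format or ("mtx" if path.suffix == ".mtx" else "tsv")
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        # a fully-string column means malformed numeric data
        non_numeric = df.select_dtypes(exclude="number").columns
        if len(non_numeric):
            raise ValueError(f"{path}: non-numeric counts in column {non_numeric[0]!r}")
        return _validate_counts(df, str(path))
    if fmt == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = Path(path.with_suffix(".rows")).read_text().splitlines()
        samples = Path(path.with_suffix(".cols")).read_text().splitlines()
        df = pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"), columns=samples)
        return _validate_counts(df, str(path))
    raise ValueError(f"unknown count format {fmt!r}")


def write_counts(counts: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    """Write a count matrix as TSV or MatrixMarket (+ id sidecars)."""
    path = Path(path)
    fmt = format or ("mtx" if path.suffix == ".mtx" else "tsv")
    if fmt == "tsv":
        counts.rename_axis("gene_id").to_csv(path, sep="\t")
    elif fmt == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.csr_matrix(counts.to_numpy()))
        path.with_suffix(".rows").write_text("\n".join(map(str, counts.index)) + "\n")
        path.with_suffix(".cols").write_text("\n".join(map(str, counts.columns)) + "\n")
    else:
        raise ValueError(f"unknown count format {fmt!r}")


def read_samples(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t")
    required = {"sample_id", "arm", "stage"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"{path}: sample table is missing columns {sorted(missing)}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    return samples


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_diameters(path: str | Path) -> pd.DataFrame:
    ds = pd.read_csv(path, sep="\t")
    missing = {"value", "stratum"} - set(ds.columns)
    if missing:
        raise ValueError(f"{path}: diameter table is missing columns {sorted(missing)}")
    if (ds["value"] <= 0).any():
        bad = ds.index[ds["value"] <= 0][0]
        raise ValueError(f"{path}: non-positive diameter at row {bad}")
    return ds


def write_diameters(ds: pd.DataFrame, path: str | Path) -> None:
    ds[["value", "stratum"]].to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Generic TSV writer for contrast / DiPa / migration tables."""
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, index_col: str | int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
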