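"""Readers and writers for the pipeline's tab-separated interchange formats.

Supported dialects:

* wide count table — header row of sample ids, first column gene ids;
* triplet count table — columns ``gene_id``, ``sample_id``, ``count``,
  absent cells are zero;
* metadata / annotation tables — one row per sample or gene.

All files are UTF-8, tab-delimited, with a header row.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (CountMatrix, ValidationError, validate_annotation,
                        validate_metadata)


def read_counts(path, format: str = "wide_tsv",
                gene_ids=None, sample_ids=None) -> CountMatrix:
    """Read a count table into a :class:`CountMatrix` (genes x samples).

    Parameters
    ----------
    format
        ``"wide_tsv"`` or ``"triplet"``. For triplet input, ``gene_ids`` /
        ``sample_ids`` optionally declare the full axes so that unlisted
        cells become explicit zeros; otherwise the axes are the ids observed
        in the file.
    """
    path = Path(path)
    if format == "wide_tsv":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        dup = {h for h in header if header.count(h) > 1}
        if dup:  # pandas would silently mangle repeated columns
            raise ValidationError(
                f"{path}: duplicate sample id(s): {sorted(dup)}")
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        _check_integer(df, path)
        return CountMatrix(df)
    if format == "triplet":
        tri = pd.read_csv(path, sep="\t", comment="#",
                          dtype={"gene_id": str, "sample_id": str})
        for col in ("gene_id", "sample_id", "count"):
            if col not in tri.columns:
                raise ValidationError(f"{path}: triplet file missing column {col!r}")
        dup = tri.duplicated(subset=["gene_id", "sample_id"])
        if dup.any():
            row = tri[dup].iloc[0]
            raise ValidationError(
                f"{path}: duplicate cell for gene {row['gene_id']!r}, "
                f"sample {row['sample_id']!r}")
        bad = tri[(tri["count"] % 1 != 0) | (tri["count"] < 0)]
        if len(bad):
            raise ValidationError(
                f"{path}: negative or non-integer count at file row "
                f"{bad.index[0] + 2}")  # +2: header line, 1-based
        genes = list(gene_ids) if gene_ids is not None else \
            list(dict.fromkeys(tri["gene_id"]))
        samples = list(sample_ids) if sample_ids is not None else \
            list(dict.fromkeys(tri["sample_id"]))
        wide = (tri.pivot(index="gene_id", columns="sample_id", values="count")
                .reindex(index=genes, columns=samples)
                .fillna(0).astype(np.int64))
        wide.index.name = None
        wide.columns.name = None
        return CountMatrix(wide)
    raise ValueError(f"unknown count format {format!r}")


def _check_integer(df: pd.DataFrame, path: Path) -> None:
    values = df.to_numpy()
    if np.issubdtype(values.dtype, np.integer):
        if (values < 0).any():
            row = int(np.argwhere((values < 0).any(axis=1))[0][0])
            raise ValidationError(f"{path}: negative count at table row {row + 1}")
        return
    frac = np.mod(values.astype(float), 1) != 0
    if frac.any():
        row = int(np.argwhere(frac.any(axis=1))[0][0])
        raise ValidationError(f"{path}: non-integer count at table row {row + 1}")
    if (values < 0).any():
        row = int(np.argwhere((values < 0).any(axis=1))[0][0])
        raise ValidationError(f"{path}: negative count at table row {row + 1}")


def read_metadata(path, somite_window=(5, 9)) -> pd.DataFrame:
    """Read and validate a sample metadata table."""
    meta = pd.read_csv(path, sep="\t", comment="#",
                       dtype={"sample_id": str, "conceptus_id": str})
    return validate_metadata(meta, somite_window=somite_window)


def read_annotation(path) -> pd.DataFrame:
    """Read and validate a gene annotation table (gene_id, chromosome[, symbol])."""
    ann = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return validate_annotation(ann)


def write_table(records: pd.DataFrame, path, float_digits: int = 6) -> None:
    """Write any result table as TSV with fixed-precision floats.

    Floating values are rendered with ``float_digits`` significant digits so a
    round-trip reproduces them to that precision. An empty table produces a
    header-only file and a warning.
    """
    path = Path(path)
    if len(records) == 0:
        warnings.warn(f"writing empty table to {path}", stacklevel=2)
    records.to_csv(path, sep="\t", index=False,
                   float_format=f"%.{float_digits}g")


def write_counts(cm: CountMatrix, path) -> None:
    """Write a count matrix in the wide TSV dialect (exact integer round-trip)."""
    df = cm.counts.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_table(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", comment="#")
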