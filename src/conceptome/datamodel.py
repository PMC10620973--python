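"""Core containers for the paired embryo / yolk-sac expression pipeline.

Count matrices are stored genes-as-rows, samples-as-columns throughout; every
operation that consumes or produces a matrix states this orientation in its
docstring. Sample metadata is a validated :class:`pandas.DataFrame` carrying
the experimental design: tissue, metabolic condition, somite-pair stage, the
conceptus pairing key, and (optionally) dam and sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TISSUES = ("embryo", "yolk_sac")
CONDITIONS = ("normal", "diabetic")
SEXES = ("female", "male", "unknown")

#: chromosome vocabulary: mouse autosomes plus the sex chromosomes; "unknown"
#: marks genes lacking annotation.
CHROMOSOMES = tuple(str(i) for i in range(1, 20)) + ("X", "Y", "MT", "unknown")

META_REQUIRED = ("sample_id", "tissue", "condition", "somite_pairs", "conceptus_id")

#: somite-pair inclusion window used by the study design (config value, not a
#: hard-coded constraint of the containers).
DEFAULT_SOMITE_WINDOW = (5, 9)


class ValidationError(ValueError):
    """Raised when an input table violates a design invariant."""


@dataclass
class CountMatrix:
    """UMI-corrected counts, genes x samples (nonnegative integers)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene id(s): {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample id(s): {dup}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise ValidationError("counts must be integers")
            df = df.astype(np.int64)
        if (df.to_numpy() < 0).any():
            raise ValidationError("counts must be nonnegative")
        self.counts = df

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)])

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(self.counts[list(samples)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts)


def validate_metadata(meta: pd.DataFrame,
                      somite_window: tuple[int, int] | None = DEFAULT_SOMITE_WINDOW,
                      ) -> pd.DataFrame:
    """Validate a sample-metadata table and return a normalized copy.

    Checks: required columns present, vocabularies respected, each conceptus
    contributes at most one sample per tissue, and both members of a conceptus
    agree on somite stage, condition, sex and dam. A missing ``sex`` column is
    filled with ``"unknown"`` (sex is inferred later from marker expression,
    never imputed at read time).
    """
    missing = [c for c in META_REQUIRED if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing required column(s): {missing}")
    meta = meta.copy()
    if "sex" not in meta.columns:
        meta["sex"] = "unknown"
    meta["sex"] = meta["sex"].fillna("unknown")
    if "dam_id" not in meta.columns:
        meta["dam_id"] = pd.NA
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample id(s): {dup}")
    for col, vocab in (("tissue", TISSUES), ("condition", CONDITIONS), ("sex", SEXES)):
        bad = set(meta[col]) - set(vocab)
        if bad:
            raise ValidationError(f"invalid {col} value(s): {sorted(bad)}")
    meta["somite_pairs"] = meta["somite_pairs"].astype(int)
    if somite_window is not None:
        lo, hi = somite_window
        out = meta[(meta["somite_pairs"] < lo) | (meta["somite_pairs"] > hi)]
        if len(out):
            raise ValidationError(
                f"somite_pairs outside inclusion window [{lo}, {hi}] for "
                f"sample(s): {out['sample_id'].tolist()}")
    for cid, grp in meta.groupby("conceptus_id"):
        counts = grp["tissue"].value_counts()
        multi = counts[counts > 1]
        if len(multi):
            raise ValidationError(
                f"conceptus {cid!r} has multiple samples for tissue(s): "
                f"{multi.index.tolist()}")
        for col in ("somite_pairs", "condition", "sex"):
            if grp[col].nunique() > 1:
                raise ValidationError(
                    f"conceptus {cid!r}: members disagree on {col} "
                    f"({grp[col].tolist()})")
        if grp["dam_id"].dropna().nunique() > 1:
            raise ValidationError(f"conceptus {cid!r}: members disagree on dam_id")
    return meta.reset_index(drop=True)


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene annotation table (gene_id, chromosome, optional symbol)."""
    for col in ("gene_id", "chromosome"):
        if col not in annotation.columns:
            raise ValidationError(f"annotation missing required column {col!r}")
    annotation = annotation.copy()
    if annotation["gene_id"].duplicated().any():
        dup = annotation.loc[annotation["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValidationError(f"duplicate gene id(s) in annotation: {dup}")
    annotation["chromosome"] = annotation["chromosome"].astype(str)
    bad = set(annotation["chromosome"]) - set(CHROMOSOMES)
    if bad:
        raise ValidationError(f"chromosome label(s) outside vocabulary: {sorted(bad)}")
    if "symbol" not in annotation.columns:
        annotation["symbol"] = annotation["gene_id"]
    return annotation.reset_index(drop=True)


@dataclass
class Dataset:
    """One count matrix per tissue plus the shared design and annotation."""

    counts: dict[str, CountMatrix]
    meta: pd.DataFrame
    annotation: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def samples(self, tissue: str) -> pd.DataFrame:
        """Metadata rows for one tissue, ordered as the count-matrix columns."""
        sub = self.meta[self.meta["tissue"] == tissue].set_index("sample_id")
        return sub.loc[self.counts[tissue].sample_ids].reset_index()


def validate_dataset(counts: dict[str, CountMatrix],
                     meta: pd.DataFrame,
                     annotation: pd.DataFrame,
                     somite_window: tuple[int, int] | None = DEFAULT_SOMITE_WINDOW,
                     ) -> Dataset:
    """Cross-reference counts, metadata and annotation into a Dataset.

    Every sample in each count matrix must appear in the metadata with the
    matching tissue. Genes missing from the annotation are tolerated: they are
    assigned chromosome ``"unknown"`` and reported in ``Dataset.warnings``.
    """
    meta = validate_metadata(meta, somite_window=somite_window)
    annotation = validate_annotation(annotation)
    warnings: list[str] = []
    meta_by_id = meta.set_index("sample_id")
    for tissue, cm in counts.items():
        if tissue not in TISSUES:
            raise ValidationError(f"unknown tissue key {tissue!r}")
        for sid in cm.sample_ids:
            if sid not in meta_by_id.index:
                raise ValidationError(
                    f"sample {sid!r} in {tissue} counts absent from metadata")
            if meta_by_id.loc[sid, "tissue"] != tissue:
                raise ValidationError(
                    f"sample {sid!r} is in the {tissue} count matrix but "
                    f"metadata assigns tissue {meta_by_id.loc[sid, 'tissue']!r}")
    known = set(annotation["gene_id"])
    all_genes: list[str] = []
    seen: set[str] = set()
    for cm in counts.values():
        for g in cm.gene_ids:
            if g not in seen:
                seen.add(g)
                all_genes.append(g)
    unannotated = [g for g in all_genes if g not in known]
    if unannotated:
        warnings.append(
            f"{len(unannotated)} gene(s) lack annotation, chromosome set to "
            f"'unknown': {unannotated[:10]}")
        extra = pd.DataFrame({"gene_id": unannotated,
                              "chromosome": "unknown",
                              "symbol": unannotated})
        annotation = pd.concat([annotation, extra], ignore_index=True)
    return Dataset(counts=counts, meta=meta, annotation=annotation,
                   warnings=warnings)
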