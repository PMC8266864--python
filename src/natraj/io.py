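"""Core data containers and the tab-delimited interchange formats.

Every pipeline stage exchanges three plain TSV tables:

* ``counts.tsv``     — gene × sample read counts, first column ``gene_id``;
* ``metadata.tsv``   — one row per sample: tissue group (N / NAT / T), sex,
  age, lymphocytic-thyroiditis status and an optional patient ID used to
  pair tumor samples with their adjacent-tissue sample;
* ``annotation.tsv`` — one row per gene: symbol, Ensembl biotype, chromosome.

Gene identifiers are opaque strings; versioned Ensembl IDs (``ENSG...18``)
are kept verbatim, never stripped.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

TISSUE_GROUPS = ("N", "NAT", "T")
SEXES = ("F", "M")
LT_STATUSES = ("LT+", "LT-", "NA")

METADATA_COLUMNS = ("sample_id", "tissue_group", "sex", "age", "lt_status", "patient_id")
ANNOTATION_COLUMNS = ("gene_id", "symbol", "biotype", "chromosome")


@dataclasses.dataclass
class CountMatrix:
    """Non-negative integer read counts, genes × samples.

    Wraps a :class:`pandas.DataFrame` whose index holds gene IDs and whose
    columns hold sample IDs; both must be unique and all cells must be
    integers ≥ 0.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene IDs: {dupes[:5]}")
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dupes[:5]}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values % 1 != 0):
                raise ValidationError("counts must be finite integers")
            df = df.astype(np.int64)
        if (df.to_numpy() < 0).any():
            gi, sj = np.argwhere(df.to_numpy() < 0)[0]
            raise ValidationError(
                f"negative count at gene {df.index[gi]!r}, sample {df.columns[sj]!r}"
            )
        self.counts = df

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    # -- subsetting ------------------------------------------------------
    def subset(
        self,
        gene_ids: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> "CountMatrix":
        """Return a new matrix restricted to the requested IDs, in request order."""
        df = self.counts
        if gene_ids is not None:
            missing = [g for g in gene_ids if g not in df.index]
            if missing:
                raise KeyError(f"unknown gene IDs: {missing[:5]}")
            df = df.loc[list(gene_ids)]
        if sample_ids is not None:
            missing = [s for s in sample_ids if s not in df.columns]
            if missing:
                raise KeyError(f"unknown sample IDs: {missing[:5]}")
            df = df[list(sample_ids)]
        return CountMatrix(df.copy())

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", lineterminator="\n")


def read_counts(path: str | Path) -> CountMatrix:
    """Read a gene × sample count table.

    The file must be tab-delimited with a header row of sample IDs and gene
    IDs in the first column; every cell must be a non-negative integer.
    Offending cells are reported by gene and sample ID.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValidationError(f"duplicate sample IDs in header: {dupes}")
    raw.columns = header
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        gi, sj = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric count {raw.iloc[gi, sj]!r} at gene "
            f"{raw.index[gi]!r}, sample {raw.columns[sj]!r}"
        )
    if numeric.isna().to_numpy().any():
        gi, sj = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(f"missing count at gene {raw.index[gi]!r}, sample {raw.columns[sj]!r}")
    vals = numeric.to_numpy()
    if np.any(vals % 1 != 0):
        gi, sj = np.argwhere(vals % 1 != 0)[0]
        raise FormatError(
            f"non-integer count {vals[gi, sj]} at gene {raw.index[gi]!r}, "
            f"sample {raw.columns[sj]!r}"
        )
    if np.any(vals < 0):
        gi, sj = np.argwhere(vals < 0)[0]
        raise FormatError(
            f"negative count at gene {raw.index[gi]!r}, sample {raw.columns[sj]!r}"
        )
    df = numeric.astype(np.int64)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return CountMatrix(df)


def _validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample IDs in metadata: {dupes[:5]}")
    for column, allowed in (
        ("tissue_group", TISSUE_GROUPS),
        ("sex", SEXES),
        ("lt_status", LT_STATUSES),
    ):
        bad = sorted(set(meta[column].dropna()) - set(allowed))
        if bad:
            raise ValidationError(
                f"unknown {column} token(s) {bad}; allowed: {list(allowed)}"
            )
    if (meta["age"].dropna() < 0).any():
        raise ValidationError("negative age in metadata")
    # a patient may contribute at most one NAT sample (the pairing key)
    nat = meta[(meta["tissue_group"] == "NAT") & meta["patient_id"].notna()]
    if nat["patient_id"].duplicated().any():
        dupes = nat.loc[nat["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValidationError(f"patient(s) {dupes[:5]} have more than one NAT sample")
    return meta.set_index("sample_id", drop=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and vocabulary-validate the per-sample metadata table.

    Returns a DataFrame indexed by ``sample_id`` with columns
    ``tissue_group`` ∈ {N, NAT, T}, ``sex`` ∈ {F, M}, ``age`` (years, may be
    missing), ``lt_status`` ∈ {LT+, LT-, NA} and ``patient_id`` (may be
    missing for unpaired samples).
    """
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata is missing required column(s): {missing}")
    meta = meta[list(METADATA_COLUMNS)].copy()
    meta["age"] = pd.to_numeric(meta["age"], errors="coerce")
    meta["lt_status"] = meta["lt_status"].fillna("NA")
    return _validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.reset_index(drop=True).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the gene annotation table (gene_id, symbol, biotype, chromosome)."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise FormatError(f"annotation is missing required column(s): {missing}")
    ann = ann[list(ANNOTATION_COLUMNS)].copy()
    if ann["gene_id"].duplicated().any():
        dupes = ann.loc[ann["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValidationError(f"duplicate gene IDs in annotation: {dupes[:5]}")
    if len(ann) and ann["biotype"].isna().any():
        raise ValidationError("empty biotype in annotation")
    return ann.set_index("gene_id", drop=False)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.reset_index(drop=True).to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclasses.dataclass
class Issue:
    level: str  # "error" | "warning"
    message: str


@dataclasses.dataclass
class ValidationReport:
    issues: list[Issue]

    @property
    def ok(self) -> bool:
        return not any(i.level == "error" for i in self.issues)

    def messages(self, level: str | None = None) -> list[str]:
        return [i.message for i in self.issues if level is None or i.level == level]


def validate_dataset(
    counts: CountMatrix, meta: pd.DataFrame, ann: pd.DataFrame
) -> ValidationReport:
    """Cross-check the three tables without mutating any of them.

    Reports samples present in only one of counts/metadata, genes without
    annotation, and pairing integrity of tumor samples (every T sample with a
    patient ID should have a NAT sample from the same patient).
    """
    issues: list[Issue] = []
    count_samples = set(counts.sample_ids)
    meta_samples = set(meta.index)
    for s in sorted(count_samples - meta_samples):
        issues.append(Issue("error", f"sample without metadata: {s}"))
    for s in sorted(meta_samples - count_samples):
        issues.append(Issue("warning", f"metadata sample absent from counts: {s}"))
    unannotated = sorted(set(counts.gene_ids) - set(ann.index))
    if unannotated:
        issues.append(
            Issue(
                "warning",
                f"{len(unannotated)} gene(s) without annotation "
                f"(will be reported as biotype 'unknown'): {unannotated[:5]}...",
            )
        )
    nat_patients = set(
        meta.loc[(meta["tissue_group"] == "NAT") & meta["patient_id"].notna(), "patient_id"]
    )
    tumors = meta[(meta["tissue_group"] == "T") & meta["patient_id"].notna()]
    for sample_id, patient in zip(tumors.index, tumors["patient_id"]):
        if patient not in nat_patients:
            issues.append(
                Issue(
                    "warning",
                    f"T sample {sample_id} (patient {patient}) matches no NAT sample",
                )
            )
    return ValidationReport(issues)
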