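"""DEG calling: fold-change / adjusted-p / permutation-p thresholds and the
sex-bias exclusion screen.

A gene is a DEG when |log2fc| >= log2(fold_change_min) (inclusive), the
BH-adjusted p is strictly below ``padj_max`` and, when present, the
permutation p is strictly below ``perm_p_max``.  To guard against sex
artifacts, genes differing between males and females among the
tumor-adjacent (NAT) samples at raw p < 0.05 are removed from the final
list.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DesignError
from .de import DesignSpec, run_de
from .io import CountMatrix


@dataclasses.dataclass
class DEGCallConfig:
    fold_change_min: float = 1.5
    padj_max: float = 0.05
    perm_p_max: float = 0.05
    sex_p_max: float = 0.05

    def validate(self) -> None:
        if self.fold_change_min < 1:
            raise ConfigurationError("fold_change_min must be >= 1")
        for name in ("padj_max", "perm_p_max", "sex_p_max"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")


@dataclasses.dataclass
class DEGList:
    """A called DEG list with the thresholds that produced it."""

    contrast: str
    table: pd.DataFrame  # index gene_id; log2fc, padj, [perm_p], direction
    provenance: dict = dataclasses.field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# contrast={self.contrast}\n")
            for key, value in self.provenance.items():
                fh.write(f"# {key}={value}\n")
            out = self.table.copy()
            out.index.name = "gene_id"
            out.to_csv(fh, sep="\t", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DEGList":
        provenance: dict = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                provenance[key.strip()] = value
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            table = pd.read_csv(fh, sep="\t", index_col="gene_id")
        contrast = provenance.pop("contrast", "")
        return cls(contrast=contrast, table=table, provenance=provenance)


def call_degs(
    de: pd.DataFrame,
    config: DEGCallConfig | None = None,
    contrast: str = "",
) -> DEGList:
    """Apply the DEG thresholds to a differential-expression table.

    The fold-change criterion is inclusive (|log2fc| >= log2(fold_change_min))
    while both p criteria are strict (<).  When the table has no ``perm_p``
    column that criterion is skipped and recorded in provenance.
    """
    config = config or DEGCallConfig()
    config.validate()
    lfc_min = float(np.log2(config.fold_change_min))
    mask = (de["log2fc"].abs() >= lfc_min) & (de["padj"] < config.padj_max)
    has_perm = "perm_p" in de.columns
    if has_perm:
        mask &= de["perm_p"] < config.perm_p_max
    cols = ["log2fc", "padj"] + (["perm_p"] if has_perm else [])
    table = de.loc[mask, cols].copy()
    table["direction"] = np.where(table["log2fc"] > 0, "up", "down")
    provenance = {
        "fold_change_min": config.fold_change_min,
        "log2fc_min": lfc_min,
        "padj_max": config.padj_max,
        "perm_p_max": config.perm_p_max if has_perm else "skipped (no perm_p column)",
    }
    contrast = contrast or de.attrs.get("contrast", "")
    return DEGList(contrast=contrast, table=table, provenance=provenance)


def find_sex_biased_genes(
    counts: CountMatrix,
    meta: pd.DataFrame,
    sex_p_max: float = 0.05,
    covariates: tuple[str, ...] = ("age", "lt_status"),
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Screen NAT samples for male-vs-female expression differences.

    Runs the NB Wald engine with contrast M vs F restricted to NAT samples
    (covariates age and LT by default) and returns the genes with raw
    p < ``sex_p_max`` (log2fc, pvalue, padj columns, indexed by gene_id).
    """
    nat = meta[meta["tissue_group"] == "NAT"]
    if nat["sex"].nunique() < 2:
        raise DesignError("sex screen needs both sexes among NAT samples")
    spec = DesignSpec(test="M", reference="F", factor="sex", covariates=covariates)
    nat_counts = counts.subset(sample_ids=list(nat.index))
    de = run_de(nat_counts, nat, spec, size_factors=size_factors)
    return de.loc[de["pvalue"] < sex_p_max, ["log2fc", "pvalue", "padj"]].copy()


def apply_sex_filter(degs: DEGList, sex_genes: Iterable[str]) -> DEGList:
    """Remove sex-biased genes from a DEG list; provenance records the removals."""
    sex_set = set(sex_genes)
    removed = [g for g in degs.gene_ids if g in sex_set]
    table = degs.table.drop(index=removed)
    provenance = dict(degs.provenance)
    provenance["sex_filter_removed_n"] = len(removed)
    provenance["sex_filter_removed_ids"] = ",".join(removed)
    return DEGList(contrast=degs.contrast, table=table, provenance=provenance)
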