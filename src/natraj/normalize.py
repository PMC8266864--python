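"""Low-expression gene filtering and median-of-ratios normalization.

Filtering removes a gene when, in every tissue group, more than a given
fraction of samples have a zero count, or when the gene's mean raw count
across all samples falls below a floor.  Normalization is the classic
median-of-ratios method: each sample's size factor is the median, over
genes expressed in every sample, of the ratio of that sample's count to the
gene's geometric mean across samples.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, NormalizationError
from .io import CountMatrix


@dataclasses.dataclass
class NormalizedMatrix:
    """Size-factor-normalized expression with its log2(x + 1) transform."""

    normalized: pd.DataFrame  # genes × samples, counts / size factor
    size_factors: pd.Series  # per sample, > 0
    log_expression: pd.DataFrame  # log2(normalized + 1)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.normalized.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.normalized.columns)

    def subset(
        self,
        gene_ids: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> "NormalizedMatrix":
        norm, logx, sf = self.normalized, self.log_expression, self.size_factors
        if gene_ids is not None:
            missing = [g for g in gene_ids if g not in norm.index]
            if missing:
                raise KeyError(f"unknown gene IDs: {missing[:5]}")
            norm, logx = norm.loc[list(gene_ids)], logx.loc[list(gene_ids)]
        if sample_ids is not None:
            missing = [s for s in sample_ids if s not in norm.columns]
            if missing:
                raise KeyError(f"unknown sample IDs: {missing[:5]}")
            norm, logx = norm[list(sample_ids)], logx[list(sample_ids)]
            sf = sf.loc[list(sample_ids)]
        return NormalizedMatrix(norm.copy(), sf.copy(), logx.copy())


def filter_low_expression(
    counts: CountMatrix,
    meta: pd.DataFrame,
    zero_fraction_threshold: float = 0.25,
    min_mean: float = 10.0,
    zero_rule: Literal["all", "any"] = "all",
) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove very low expressed genes.

    A gene is removed when the fraction of zero counts exceeds
    ``zero_fraction_threshold`` in every tissue group (``zero_rule='all'``;
    ``'any'`` requires only one group), or when its mean raw count over all
    samples is strictly below ``min_mean``.  Returns the surviving matrix
    (gene order preserved) and a report of removed genes with the rule that
    triggered each removal.
    """
    samples = counts.sample_ids
    missing = [s for s in samples if s not in meta.index]
    if missing:
        raise ConfigurationError(f"samples without tissue_group: {missing[:5]}")
    groups = meta.loc[samples, "tissue_group"]
    present = [g for g in groups.unique()]
    if not present:
        raise ConfigurationError("no tissue groups present")

    values = counts.values()
    zero_exceeds = []
    for g in present:
        cols = np.asarray(groups.to_numpy() == g)
        if cols.sum() == 0:
            raise ConfigurationError(f"empty tissue group {g!r}")
        frac_zero = (values[:, cols] == 0).mean(axis=1)
        zero_exceeds.append(frac_zero > zero_fraction_threshold)
    zero_exceeds = np.column_stack(zero_exceeds)
    zero_hit = zero_exceeds.all(axis=1) if zero_rule == "all" else zero_exceeds.any(axis=1)
    mean_hit = values.mean(axis=1) < min_mean
    removed = zero_hit | mean_hit

    rules = np.where(
        zero_hit & mean_hit, "zero_fraction+low_mean",
        np.where(zero_hit, "zero_fraction", "low_mean"),
    )
    report = pd.DataFrame(
        {"gene_id": np.asarray(counts.gene_ids)[removed], "rule": rules[removed]}
    )
    kept = counts.counts.loc[~removed]
    return CountMatrix(kept.copy()), report


def compute_size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    Reference genes are those with a strictly positive count in every sample
    (geometric mean > 0).  For sample *j* the size factor is the median over
    reference genes of counts[g, j] / geomean(g).
    """
    values = counts.values().astype(float)
    reference = (values > 0).all(axis=1)
    if not reference.any():
        raise NormalizationError(
            "no gene has a positive count in every sample; "
            "relax filtering before normalizing"
        )
    ref = values[reference]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = ref / np.exp(log_geomean)[:, None]
    sf = np.median(ratios, axis=0)
    return pd.Series(sf, index=counts.sample_ids, name="size_factor")


def normalize(counts: CountMatrix, size_factors: pd.Series) -> NormalizedMatrix:
    """Divide counts by per-sample size factors; add log2(x + 1) expression."""
    sf = size_factors.reindex(counts.sample_ids)
    if sf.isna().any():
        raise DataError("size factors missing for some samples")
    if (sf <= 0).any():
        raise DataError("size factors must all be > 0")
    normalized = counts.counts / sf
    log_expression = np.log2(normalized + 1.0)
    return NormalizedMatrix(normalized, sf.astype(float), log_expression)
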