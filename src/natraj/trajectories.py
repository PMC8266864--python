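"""Trajectory patterns along N → NAT → T, DEG-list overlaps and biotype
composition.

Each NAT-vs-N DEG is classified on two arms — NAT vs N (arm 1) and
T vs NAT (arm 2) — into one of six patterns (up-up, up-stable, up-down,
down-down, down-stable, down-up).  An arm is "up" when p < 0.05 and
log2fc >= 0.584 (inclusive), "down" when p < 0.05 and log2fc < -0.584
(strict), otherwise "stable"; a stable gene may have a large fold change
with a non-significant p.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .calling import DEGList

PATTERNS = ("up-up", "up-stable", "up-down", "down-down", "down-stable", "down-up")

#: printed classification threshold on |log2fc| (log2(1.5) rounded to 0.584)
ARM_LFC_THRESHOLD = 0.584
ARM_P_THRESHOLD = 0.05


def classify_arm(
    log2fc: float,
    p: float,
    lfc_threshold: float = ARM_LFC_THRESHOLD,
    p_threshold: float = ARM_P_THRESHOLD,
) -> str:
    """Classify one expression change as up / down / stable.

    up: p < p_threshold and log2fc >= lfc_threshold (inclusive);
    down: p < p_threshold and log2fc < -lfc_threshold (strict);
    stable: everything else.
    """
    if p < p_threshold:
        if log2fc >= lfc_threshold:
            return "up"
        if log2fc < -lfc_threshold:
            return "down"
    return "stable"


def _classify_arm_vec(lfc: np.ndarray, p: np.ndarray,
                      lfc_threshold: float, p_threshold: float) -> np.ndarray:
    sig = p < p_threshold
    out = np.full(lfc.shape, "stable", dtype=object)
    out[sig & (lfc >= lfc_threshold)] = "up"
    out[sig & (lfc < -lfc_threshold)] = "down"
    return out


def classify_trajectories(
    degs: DEGList,
    de_arm2: pd.DataFrame,
    use_adjusted: bool = True,
    lfc_threshold: float = ARM_LFC_THRESHOLD,
    p_threshold: float = ARM_P_THRESHOLD,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Assign every DEG a six-way trajectory pattern.

    Arm-1 statistics come from the DEG list itself (so arm 1 is up or down
    by construction); arm 2 comes from the T-vs-NAT table ``de_arm2``.  By
    default the BH-adjusted p is classified (``use_adjusted=False`` selects
    the raw p, available only when the inputs carry a ``pvalue`` column).
    Genes absent from ``de_arm2`` are excluded and returned in the missing
    list rather than being called stable.

    Returns (per-gene table, per-pattern counts over all six patterns,
    missing gene IDs).
    """
    p_col = "padj" if use_adjusted else "pvalue"
    if p_col not in degs.table.columns or p_col not in de_arm2.columns:
        raise ValidationError(f"both inputs need a {p_col!r} column")
    present = [g for g in degs.gene_ids if g in de_arm2.index]
    missing = [g for g in degs.gene_ids if g not in de_arm2.index]
    if missing:
        warnings.warn(
            f"{len(missing)} DEG(s) absent from the arm-2 table were excluded",
            stacklevel=2,
        )
    arm1_lfc = degs.table.loc[present, "log2fc"].to_numpy(float)
    arm1_p = degs.table.loc[present, p_col].to_numpy(float)
    arm2_lfc = de_arm2.loc[present, "log2fc"].to_numpy(float)
    arm2_p = de_arm2.loc[present, p_col].to_numpy(float)
    a1 = _classify_arm_vec(arm1_lfc, arm1_p, lfc_threshold, p_threshold)
    a2 = _classify_arm_vec(arm2_lfc, arm2_p, lfc_threshold, p_threshold)
    pattern = np.array([f"{x}-{y}" for x, y in zip(a1, a2)], dtype=object)
    table = pd.DataFrame(
        {
            "arm1_log2fc": arm1_lfc,
            "arm1_p": arm1_p,
            "arm2_log2fc": arm2_lfc,
            "arm2_p": arm2_p,
            "pattern": pattern,
        },
        index=pd.Index(present, name="gene_id"),
    )
    counts = pd.Series(
        {p: int((pattern == p).sum()) for p in PATTERNS}, name="n_genes"
    )
    return table, counts, missing


# ---------------------------------------------------------------------------
# set overlaps
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class OverlapReport:
    """Exact Venn region counts for two or three DEG lists.

    ``region_counts`` maps a tuple of list labels to the number of genes in
    exactly those lists; ``pairwise_direction`` maps a label pair to
    (shared, same-direction, opposite-direction) counts.
    """

    labels: tuple[str, ...]
    region_counts: dict[tuple[str, ...], int]
    union_size: int
    pairwise_direction: dict[tuple[str, str], tuple[int, int, int]]

    def intersection(self, *labels: str) -> int:
        """Genes present in all the named lists (regardless of the others)."""
        want = set(labels)
        return sum(
            n for region, n in self.region_counts.items() if want <= set(region)
        )


def overlap(lists: Sequence[DEGList]) -> OverlapReport:
    """Venn-region counts and direction concordance for 2–3 DEG lists."""
    if not 2 <= len(lists) <= 3:
        raise ValidationError("overlap expects two or three DEG lists")
    labels = tuple(lst.contrast or f"list{i + 1}" for i, lst in enumerate(lists))
    if len(set(labels)) != len(labels):
        labels = tuple(f"{lab}#{i + 1}" for i, lab in enumerate(labels))
    sets: dict[str, set[str]] = {}
    for label, lst in zip(labels, lists):
        ids = lst.gene_ids
        if len(ids) != len(set(ids)):
            raise ValidationError(f"duplicate gene IDs within list {label!r}")
        sets[label] = set(ids)

    region_counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(labels) + 1):
        for inside in itertools.combinations(labels, r):
            outside = [lab for lab in labels if lab not in inside]
            region = set.intersection(*(sets[lab] for lab in inside))
            for lab in outside:
                region -= sets[lab]
            region_counts[inside] = len(region)
    union = set.union(*sets.values())

    direction: dict[tuple[str, str], tuple[int, int, int]] = {}
    for (la, a), (lb, b) in itertools.combinations(zip(labels, lists), 2):
        shared = sorted(sets[la] & sets[lb])
        sign_a = np.sign(a.table.loc[shared, "log2fc"].to_numpy(float))
        sign_b = np.sign(b.table.loc[shared, "log2fc"].to_numpy(float))
        agree = int((sign_a == sign_b).sum())
        direction[(la, lb)] = (len(shared), agree, len(shared) - agree)

    return OverlapReport(
        labels=labels,
        region_counts=region_counts,
        union_size=len(union),
        pairwise_direction=direction,
    )


# ---------------------------------------------------------------------------
# composition summaries
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CompositionReport:
    """Biotype breakdown of a DEG list with coding up/down split."""

    total: int
    table: pd.DataFrame  # biotype, count, percent (one decimal)
    coding_total: int
    coding_up: int
    coding_down: int
    coding_up_percent: float
    coding_down_percent: float
    noncoding_total: int


def biotype_composition(degs: DEGList, ann: pd.DataFrame) -> CompositionReport:
    """Counts and percentages per biotype; up/down split for coding genes.

    Genes missing from the annotation are counted under biotype "unknown".
    Biotype percentages use the list size as denominator; the up/down
    percentages use the coding subtotal.  Percentages are rounded to one
    decimal, matching how such summaries are conventionally reported.
    """
    ids = degs.gene_ids
    total = len(ids)
    if total == 0:
        empty = pd.DataFrame(columns=["biotype", "count", "percent"])
        return CompositionReport(0, empty, 0, 0, 0, float("nan"), float("nan"), 0)
    biotypes = ann["biotype"].reindex(ids).fillna("unknown")
    counts = biotypes.value_counts()
    table = pd.DataFrame(
        {
            "biotype": counts.index,
            "count": counts.to_numpy(),
            "percent": np.round(100.0 * counts.to_numpy() / total, 1),
        }
    ).reset_index(drop=True)
    coding_ids = [g for g, b in zip(ids, biotypes) if b == "protein_coding"]
    coding_total = len(coding_ids)
    direction = degs.table.loc[coding_ids, "direction"] if coding_total else pd.Series(dtype=object)
    coding_up = int((direction == "up").sum())
    coding_down = coding_total - coding_up
    up_pct = round(100.0 * coding_up / coding_total, 1) if coding_total else float("nan")
    down_pct = round(100.0 * coding_down / coding_total, 1) if coding_total else float("nan")
    return CompositionReport(
        total=total,
        table=table,
        coding_total=coding_total,
        coding_up=coding_up,
        coding_down=coding_down,
        coding_up_percent=up_pct,
        coding_down_percent=down_pct,
        noncoding_total=total - coding_total,
    )


def chromosome_composition(gene_ids: Iterable[str], ann: pd.DataFrame) -> pd.DataFrame:
    """Autosome / X / Y / other breakdown of a gene set (counts and percents)."""
    ids = list(gene_ids)
    chrom = ann["chromosome"].reindex(ids).fillna("unknown")
    autosomes = {str(i) for i in range(1, 23)}

    def classify(c: str) -> str:
        if c in autosomes:
            return "autosome"
        if c in ("X", "Y"):
            return c
        return "other"

    klass = chrom.map(classify)
    counts = klass.value_counts()
    return pd.DataFrame(
        {
            "chromosome_class": counts.index,
            "count": counts.to_numpy(),
            "percent": np.round(100.0 * counts.to_numpy() / max(len(ids), 1), 1),
        }
    ).reset_index(drop=True)
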