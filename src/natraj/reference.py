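"""Published summary statistics of the papillary thyroid carcinoma
tumor-adjacent tissue cohort this pipeline models (12 normal, 46
tumor-adjacent, 16 paired tumor samples).

These numbers are *inputs* for consistency checks — printed cohort-level
results whose internal arithmetic (partition sums, percentage shares, set
differences) the pipeline's own reporting functions can recompute.  They
are not produced by this package and the raw cohort data are not required
to use it.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: genes retained by the low-expression filter in the cohort analysis
FILTERED_GENE_COUNT = 22411

#: NAT vs N DEGs before / after removing sex-biased genes
DEG_NAT_VS_N_PREFILTER = 650
SEX_OVERLAP_WITH_DEGS = 4
DEG_NAT_VS_N = 646

#: six-way N → NAT → T trajectory pattern sizes for the 646 DEGs
TRAJECTORY_PATTERN_COUNTS = {
    "up-up": 38,
    "up-stable": 354,
    "up-down": 37,
    "down-down": 31,
    "down-stable": 148,
    "down-up": 38,
}

#: biotype composition of the 646 DEGs
CODING_DEGS = 273
CODING_UP = 131
CODING_DOWN = 142
NONCODING_BIOTYPE_COUNTS = {
    "pseudogene": 244,
    "lincRNA": 26,
    "snRNA": 20,
    "antisense": 20,
    "snoRNA": 17,
    "processed_transcript": 14,
    "sense_intronic": 11,
    "misc_RNA": 11,
    "scaRNA": 5,
    "sense_overlapping": 2,
    "TEC": 2,
    "retained_intron": 1,
}

#: male-vs-female screen among the 46 NAT samples (37 F, 9 M)
SEX_GENES_TOTAL = 52
SEX_GENES_Y = 22
SEX_GENES_X = 7
SEX_GENES_AUTOSOME = 23

#: other contrasts and overlaps
DEG_LTNEG_VS_N = 632
DEG_LTPOS_VS_LTNEG = 1793
COMMON_NAT_AND_LTNEG = 474
COMMON_NAT_AND_LT_CONTRAST = 37
LT_COMMON_OPPOSITE_DIRECTION = 23
DEG_T_VS_NAT = 6713

#: external lymphocytic-thyroiditis gene panel (healthy-thyroid co-expression
#: study): 456 of its genes fall in the cohort's filtered gene list, 440 of
#: those overlap the LT+ vs LT- DEGs
LT_PANEL_IN_UNIVERSE = 456
LT_PANEL_OVERLAP = 440


def load_top_coding_table() -> pd.DataFrame:
    """The cohort's printed top-40 coding DEGs for NAT vs N.

    Columns: gene_id (versioned Ensembl), symbol, padj (BH-adjusted),
    fold_change (NAT over N, negative = downregulated), in_ltneg_deg_list
    ("yes"/"no": membership in the NAT/LT- vs N DEG list).
    """
    with resources.files("natraj.data").joinpath(
        "top_coding_degs_nat_vs_n.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"gene_id": str})
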