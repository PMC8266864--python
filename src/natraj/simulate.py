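"""Synthetic three-group thyroid RNA-seq count generator with ground truth.

Emulates the study design this pipeline targets: 12 normal (N), 46
tumor-adjacent (NAT) and 16 tumor (T) samples, the tumors paired with a
subset of the NAT patients, with negative-binomial counts

    K_gs ~ NB(mean = sf_s * mu_g * 2^(design effects), dispersion alpha_g)

Baseline means are log-normal and dispersions gamma-distributed; the
defaults put roughly a quarter of the genes under the low-expression
filter so filtering is exercised.  Planted structure:

* six N → NAT → T trajectory patterns (each pattern sets the sign of the
  NAT-vs-N and T-vs-NAT log2 fold changes);
* sex-biased genes split across Y-like (near-zero mean in females),
  X-like (female-biased) and autosomal genes;
* lymphocytic-thyroiditis (LT) responsive genes affected only in LT+
  samples;
* a per-patient log-normal intercept shared by the two members of a
  tumor/adjacent pair, giving the paired design something to absorb;
* per-sample log-normal size factors.

Effects are planted only on genes with baseline mean >= 20 so the planted
signal is not silently destroyed by the expression filter.  A single
integer seed drives one root generator for every draw.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import CountMatrix
from .trajectories import PATTERNS

TRUTH_GENE_COLUMNS = (
    "gene_id", "true_log2fc_NATvsN", "true_log2fc_TvsNAT", "true_pattern",
    "sex_biased", "lt_responsive", "true_dispersion", "baseline_mean",
)

_BIOTYPE_POOL = (
    ("protein_coding", 0.45),
    ("processed_pseudogene", 0.28),
    ("lincRNA", 0.07),
    ("antisense", 0.05),
    ("snRNA", 0.03),
    ("snoRNA", 0.025),
    ("misc_RNA", 0.02),
    ("processed_transcript", 0.02),
    ("sense_intronic", 0.015),
    ("unprocessed_pseudogene", 0.015),
    ("scaRNA", 0.01),
    ("TEC", 0.005),
)

_MIN_PLANT_MEAN = 20.0  # plant effects only on genes the filter will keep


def _default_pattern_counts() -> dict[str, int]:
    return {p: 25 for p in PATTERNS}


@dataclasses.dataclass
class SimulationConfig:
    """Generator parameters; defaults emulate the target study design."""

    n_genes: int = 4000
    n_N: int = 12
    n_NAT: int = 46
    n_T: int = 16  # paired with the first n_T NAT patients
    frac_LT_pos: float = 21 / 46
    pattern_counts: dict[str, int] = dataclasses.field(
        default_factory=_default_pattern_counts
    )
    effect_log2fc: float = 1.0
    n_sex_genes: int = 30  # split into Y-like / X-like / autosomal thirds
    lt_effect_genes: int = 60
    lt_log2fc: float = 1.0
    dispersion_shape: float = 2.0
    dispersion_scale: float = 0.05
    mean_log_mu: float = 3.5  # natural-log scale of the log-normal baseline
    sd_log_mu: float = 1.8
    size_factor_sd: float = 0.3
    patient_effect_sd: float = 0.3  # log2-scale SD of the shared pair intercept
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.pattern_counts) - set(PATTERNS)
        if unknown:
            raise ConfigurationError(f"unknown trajectory pattern(s): {sorted(unknown)}")
        if any(v < 0 for v in self.pattern_counts.values()):
            raise ConfigurationError("pattern counts must be >= 0")
        if sum(self.pattern_counts.values()) > self.n_genes:
            raise ConfigurationError("sum of pattern_counts exceeds n_genes")
        if not 0.0 <= self.frac_LT_pos <= 1.0:
            raise ConfigurationError("frac_LT_pos must lie in [0, 1]")
        for name in ("effect_log2fc", "lt_log2fc"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("n_genes", "n_N", "n_NAT", "n_sex_genes", "lt_effect_genes"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_T > self.n_NAT:
            raise ConfigurationError("n_T cannot exceed n_NAT (tumors pair with NAT)")


@dataclasses.dataclass
class GroundTruth:
    """Planted per-gene effects and per-sample size factors."""

    genes: pd.DataFrame  # indexed by gene_id, TRUTH_GENE_COLUMNS
    size_factors: pd.Series  # per sample

    def pattern_of(self, gene_id: str) -> str:
        return str(self.genes.loc[gene_id, "true_pattern"])


def _pattern_signs(pattern: str) -> tuple[int, int]:
    arm1, arm2 = pattern.split("-")
    to_sign = {"up": 1, "down": -1, "stable": 0}
    return to_sign[arm1], to_sign[arm2]


def _make_metadata(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    # NAT samples: roughly the cohort's 37 F / 9 M split, scaled
    n_male_nat = max(1, round(config.n_NAT * 9 / 46)) if config.n_NAT else 0
    nat_sex = np.array(["M"] * n_male_nat + ["F"] * (config.n_NAT - n_male_nat))
    rng.shuffle(nat_sex)
    n_lt = round(config.frac_LT_pos * config.n_NAT)
    nat_lt = np.array(["LT+"] * n_lt + ["LT-"] * (config.n_NAT - n_lt))
    rng.shuffle(nat_lt)
    ages = np.clip(rng.normal(48, 12, config.n_NAT + config.n_N), 18, 85).round(1)
    for i in range(config.n_NAT):
        rows.append(
            dict(sample_id=f"NAT{i + 1:02d}", tissue_group="NAT", sex=nat_sex[i],
                 age=ages[i], lt_status=nat_lt[i], patient_id=f"P{i + 1:02d}")
        )
    # tumors pair with the first n_T NAT patients and share their covariates
    for i in range(config.n_T):
        rows.append(
            dict(sample_id=f"T{i + 1:02d}", tissue_group="T", sex=nat_sex[i],
                 age=ages[i], lt_status=nat_lt[i], patient_id=f"P{i + 1:02d}")
        )
    n_male_n = max(1, round(config.n_N * 0.25)) if config.n_N else 0
    n_sex = np.array(["M"] * n_male_n + ["F"] * (config.n_N - n_male_n))
    rng.shuffle(n_sex)
    for i in range(config.n_N):
        rows.append(
            dict(sample_id=f"N{i + 1:02d}", tissue_group="N", sex=n_sex[i],
                 age=ages[config.n_NAT + i], lt_status="NA",
                 patient_id=f"C{i + 1:02d}")
        )
    meta = pd.DataFrame(rows)
    return meta.set_index("sample_id", drop=False)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one dataset: counts, metadata, annotation and ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    gene_ids = [f"SIMG{i + 1:05d}.1" for i in range(G)]

    meta = _make_metadata(config, rng)
    samples = list(meta.index)
    n_samples = len(samples)
    is_nat_or_t = meta["tissue_group"].isin(["NAT", "T"]).to_numpy()
    is_t = (meta["tissue_group"] == "T").to_numpy()
    is_female = (meta["sex"] == "F").to_numpy()
    is_ltpos = (meta["lt_status"] == "LT+").to_numpy()

    baseline = np.exp(rng.normal(config.mean_log_mu, config.sd_log_mu, G))
    dispersion = np.maximum(
        rng.gamma(config.dispersion_shape, config.dispersion_scale, G), 1e-6
    )
    size_factors = np.exp(rng.normal(0.0, config.size_factor_sd, n_samples))

    # assign gene roles on well-expressed genes, disjointly
    eligible = np.flatnonzero(baseline >= _MIN_PLANT_MEAN)
    n_needed = (
        config.n_sex_genes + config.lt_effect_genes + sum(config.pattern_counts.values())
    )
    if len(eligible) < n_needed:
        raise ConfigurationError(
            f"only {len(eligible)} genes with baseline mean >= {_MIN_PLANT_MEAN}; "
            f"{n_needed} needed for planted effects — increase n_genes or mean_log_mu"
        )
    chosen = rng.choice(eligible, size=n_needed, replace=False)
    cursor = 0

    n_y = config.n_sex_genes // 3
    n_x = config.n_sex_genes // 3
    n_auto = config.n_sex_genes - n_y - n_x
    y_like = chosen[cursor:cursor + n_y]; cursor += n_y
    x_like = chosen[cursor:cursor + n_x]; cursor += n_x
    auto_sex = chosen[cursor:cursor + n_auto]; cursor += n_auto
    lt_genes = chosen[cursor:cursor + config.lt_effect_genes]
    cursor += config.lt_effect_genes

    b_nat = np.zeros(G)  # log2fc NAT vs N
    b_t = np.zeros(G)  # log2fc T vs NAT
    true_pattern = np.full(G, "null", dtype=object)
    for pattern in PATTERNS:
        count = config.pattern_counts.get(pattern, 0)
        idx = chosen[cursor:cursor + count]
        cursor += count
        s1, s2 = _pattern_signs(pattern)
        b_nat[idx] = s1 * config.effect_log2fc
        b_t[idx] = s2 * config.effect_log2fc
        if config.effect_log2fc > 0:
            true_pattern[idx] = pattern

    sex_biased = np.zeros(G, dtype=bool)
    sex_biased[np.concatenate([y_like, x_like, auto_sex]).astype(int)] = True
    lt_responsive = np.zeros(G, dtype=bool)
    lt_responsive[lt_genes] = config.lt_log2fc > 0 and config.lt_effect_genes > 0

    # log2-scale mean model
    log2mu = np.tile(np.log2(baseline)[:, None], (1, n_samples))
    log2mu += np.outer(b_nat, is_nat_or_t.astype(float))
    log2mu += np.outer(b_t, is_t.astype(float))
    # X-like genes: female-biased by +1; autosomal sex genes: random sign
    log2mu[np.ix_(x_like, np.flatnonzero(is_female))] += 1.0
    auto_signs = rng.choice([-1.0, 1.0], size=len(auto_sex))
    for g, s in zip(auto_sex, auto_signs):
        log2mu[g, is_female] += s
    lt_signs = rng.choice([-1.0, 1.0], size=len(lt_genes))
    for g, s in zip(lt_genes, lt_signs):
        log2mu[g, is_ltpos] += s * config.lt_log2fc
    # gene-specific per-patient intercepts: biological between-subject
    # variability that the two members of a tumor/adjacent pair share (a
    # patient effect uniform across genes would just be sequencing depth)
    patients = list(dict.fromkeys(meta["patient_id"]))
    pat_col = [patients.index(p) for p in meta["patient_id"]]
    pat_effects = rng.normal(0.0, config.patient_effect_sd, size=(G, len(patients)))
    log2mu += pat_effects[:, pat_col]

    mu = size_factors[None, :] * 2.0**log2mu
    # Y-like genes: near-zero mean in females regardless of other effects
    mu[np.ix_(y_like, np.flatnonzero(is_female))] *= 0.01

    r = 1.0 / dispersion[:, None]
    p = r / (r + mu)
    counts = rng.negative_binomial(np.broadcast_to(r, mu.shape), p)
    count_df = pd.DataFrame(
        counts.astype(np.int64), index=pd.Index(gene_ids, name="gene_id"),
        columns=samples,
    )

    # annotation: planted sex genes get their chromosome, the rest are random
    biotype_names = [b for b, _ in _BIOTYPE_POOL]
    biotype_probs = np.array([w for _, w in _BIOTYPE_POOL])
    biotype_probs = biotype_probs / biotype_probs.sum()
    biotypes = rng.choice(biotype_names, size=G, p=biotype_probs)
    autosome_pool = [str(i) for i in range(1, 23)]
    chroms = rng.choice(autosome_pool + ["X"], size=G)
    chroms[y_like] = "Y"
    chroms[x_like] = "X"
    chroms[auto_sex] = rng.choice(autosome_pool, size=len(auto_sex))
    ann = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": [f"SYM{i + 1:05d}" for i in range(G)],
            "biotype": biotypes,
            "chromosome": chroms,
        }
    ).set_index("gene_id", drop=False)

    truth_genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_log2fc_NATvsN": b_nat,
            "true_log2fc_TvsNAT": b_t,
            "true_pattern": true_pattern,
            "sex_biased": sex_biased,
            "lt_responsive": lt_responsive,
            "true_dispersion": dispersion,
            "baseline_mean": baseline,
        }
    ).set_index("gene_id", drop=False)
    truth = GroundTruth(
        genes=truth_genes,
        size_factors=pd.Series(size_factors, index=samples, name="true_size_factor"),
    )
    return CountMatrix(count_df), meta, ann, truth


def simulate_null_dataset(
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Same generator with all group (trajectory) effects forced to zero.

    Covariate structure — sex-biased genes, LT effects, ages, size-factor
    heterogeneity, patient intercepts — is preserved, so type-I-error runs
    exercise the covariate adjustment, not an artificially clean design.
    """
    null_config = dataclasses.replace(
        config, pattern_counts={p: 0 for p in PATTERNS}, effect_log2fc=0.0
    )
    return simulate_dataset(null_config)


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """TSV dump: gene rows, then a per-sample size-factor block; lossless."""
    with open(path, "w") as fh:
        truth.genes[list(TRUTH_GENE_COLUMNS)].to_csv(
            fh, sep="\t", index=False, lineterminator="\n"
        )
        fh.write("##size_factors\n")
        fh.write("sample_id\ttrue_size_factor\n")
        for sample, sf in truth.size_factors.items():
            fh.write(f"{sample}\t{sf!r}\n")


def read_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        gene_lines: list[str] = []
        sf_lines: list[str] = []
        target = gene_lines
        for line in fh:
            if line.startswith("##size_factors"):
                target = sf_lines
                continue
            target.append(line)
    from io import StringIO

    # keep_default_na: the "null" pattern token is data, not a missing value
    genes = pd.read_csv(StringIO("".join(gene_lines)), sep="\t", keep_default_na=False)
    genes["true_pattern"] = genes["true_pattern"].astype(str)
    genes = genes.set_index("gene_id", drop=False)
    sf = pd.read_csv(StringIO("".join(sf_lines)), sep="\t")
    size_factors = pd.Series(
        sf["true_size_factor"].to_numpy(float),
        index=pd.Index(sf["sample_id"].to_numpy(), name=None),
        name="true_size_factor",
    )
    return GroundTruth(genes=genes, size_factors=size_factors)
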