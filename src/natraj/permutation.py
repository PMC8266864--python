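"""Permutation empirical null for the Wald statistic.

Group labels of the contrast samples are permuted (covariates stay attached
to their samples — the null hypothesis is "no group effect given
covariates"), the Wald pipeline is re-run per permutation with dispersions
frozen at their observed estimates, and the permutation p-value uses the
add-one convention p = (1 + #{|T_b| >= |T_obs|}) / (B + 1), so it is never
exactly zero.  For paired designs the two labels within each pair are
independently swapped with probability 1/2.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .de import DesignSpec, build_design, estimate_dispersions, run_de, _irls_batch, wald_from_fit
from .io import CountMatrix
from .normalize import compute_size_factors


@dataclasses.dataclass
class PermutationConfig:
    n_permutations: int = 1000
    scope: Literal["per-gene", "pooled"] = "per-gene"
    seed: int = 0
    re_estimate_dispersions: bool = False

    def validate(self) -> None:
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        if self.scope not in ("per-gene", "pooled"):
            raise ConfigurationError("scope must be 'per-gene' or 'pooled'")


def permute_labels(
    meta: pd.DataFrame, spec: DesignSpec, rng: np.random.Generator | int
) -> pd.DataFrame:
    """Return a metadata copy with contrast labels permuted among contrast samples.

    Unpaired: a uniform random permutation of the group labels (group sizes
    preserved).  Paired: within each patient pair the test/reference labels
    are swapped with probability 1/2, so no pair ever carries two identical
    labels.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = meta.copy()
    mask = out[spec.factor].isin([spec.test, spec.reference])
    if spec.paired:
        sub = out.loc[mask]
        for _, pair in sub.groupby("patient_id"):
            if rng.random() < 0.5:
                ids = pair.index
                out.loc[ids, spec.factor] = pair[spec.factor].to_numpy()[::-1]
    else:
        labels = out.loc[mask, spec.factor].to_numpy()
        out.loc[mask, spec.factor] = rng.permutation(labels)
    return out


def permutation_pvalues(
    counts: CountMatrix,
    meta: pd.DataFrame,
    spec: DesignSpec,
    config: PermutationConfig,
    observed: pd.DataFrame | None = None,
    size_factors: pd.Series | None = None,
) -> pd.Series:
    """Attach permutation p-values to a contrast.

    ``observed`` is the :func:`natraj.de.run_de` table for the real labels
    (computed here if omitted).  Per-gene scope compares each gene's observed
    |Wald| against its own permuted statistics; pooled scope compares against
    the statistics of all genes across all permutations.  Each permutation's
    label assignment is reproducible in isolation from ``config.seed`` via
    spawned generator streams.
    """
    config.validate()
    design = build_design(meta, spec)
    sub = counts.subset(sample_ids=design.sample_ids)
    if size_factors is None:
        size_factors = compute_size_factors(sub)
    sf = size_factors.reindex(design.sample_ids).to_numpy(float)
    dispersions = estimate_dispersions(sub, size_factors, design=design)
    if observed is None:
        observed = run_de(counts, meta, spec, size_factors=size_factors,
                          dispersions=dispersions)
    t_obs = np.abs(observed["wald_stat"].reindex(sub.gene_ids).to_numpy(float))

    Y = sub.values().astype(float)
    nonzero = Y.sum(axis=1) > 0
    alpha = dispersions.reindex(sub.gene_ids).to_numpy(float)
    B = config.n_permutations
    streams = np.random.SeedSequence(config.seed).spawn(B)

    G = Y.shape[0]
    exceed = np.zeros(G)  # per-gene count of |T_b| >= |T_obs|
    pooled: list[np.ndarray] = []
    meta_sub = meta.loc[design.sample_ids]

    for b in range(B):
        rng = np.random.default_rng(streams[b])
        perm_meta = permute_labels(meta_sub, spec, rng)
        perm_design = build_design(perm_meta, spec)
        # permuting labels keeps the sample set; realign count columns
        Yb = Y[:, [design.sample_ids.index(s) for s in perm_design.sample_ids]]
        sfb = size_factors.reindex(perm_design.sample_ids).to_numpy(float)
        alpha_b = alpha
        if config.re_estimate_dispersions:
            alpha_b = estimate_dispersions(
                sub, size_factors, design=perm_design
            ).to_numpy(float)
        t_b = np.zeros(G)
        if nonzero.any():
            beta, cov, _ = _irls_batch(
                Yb[nonzero], perm_design.matrix, np.log(sfb), alpha_b[nonzero]
            )
            _, _, z, _ = wald_from_fit(beta, cov, perm_design.contrast_index)
            t_b[nonzero] = np.abs(z)
        if config.scope == "per-gene":
            exceed += (t_b >= t_obs).astype(float)
        else:
            pooled.append(t_b)

    if config.scope == "per-gene":
        perm_p = (1.0 + exceed) / (B + 1.0)
    else:
        null = np.sort(np.concatenate(pooled))
        n_null = null.size
        # count of null stats >= each observed stat
        geq = n_null - np.searchsorted(null, t_obs, side="left")
        perm_p = (1.0 + geq) / (n_null + 1.0)
    return pd.Series(perm_p, index=pd.Index(sub.gene_ids, name="gene_id"), name="perm_p")
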