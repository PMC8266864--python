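"""Per-gene negative-binomial GLM Wald testing with covariate adjustment.

The model for gene *g* in sample *s* is

    K_gs ~ NB(mu_gs, alpha_g),      Var = mu + alpha * mu^2
    log mu_gs = log(size_factor_s) + x_s' beta_g

with a log link and the log size factor as offset.  The design matrix holds
an intercept, optional covariates (age, sex, lymphocytic thyroiditis) and,
for paired tumor-vs-adjacent comparisons, one indicator per patient.  The
contrast coefficient is tested with a Wald statistic (coefficient / SE,
referred to the standard normal) and p-values are Benjamini–Hochberg
adjusted across genes.

Dispersions are estimated by method of moments on normalized counts and
shrunk on the log scale toward a mean–dispersion trend fitted by robust
log-log regression.  All genes are fit simultaneously: the iteratively
reweighted least-squares updates are batched over genes with one shared
design matrix.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, ValidationError
from .io import CountMatrix
from .normalize import compute_size_factors

LN2 = float(np.log(2.0))
DISPERSION_FLOOR = 1e-8
DISPERSION_CEIL = 10.0


@dataclasses.dataclass
class DesignSpec:
    """A two-group contrast with optional covariate adjustment and pairing.

    ``test`` and ``reference`` are levels of ``factor`` (a metadata column,
    normally ``tissue_group``); the reported log2 fold change is
    test over reference.  ``paired=True`` adds one indicator column per
    patient and requires every contrast sample to carry a patient_id with
    both arms present.
    """

    test: str
    reference: str
    factor: str = "tissue_group"
    covariates: tuple[str, ...] = ("age", "sex", "lt_status")
    paired: bool = False

    @property
    def label(self) -> str:
        return f"{self.test}_vs_{self.reference}"


@dataclasses.dataclass
class Design:
    """A realized design: numeric matrix plus bookkeeping."""

    matrix: np.ndarray  # n_samples × n_columns
    columns: list[str]
    contrast_index: int
    sample_ids: list[str]
    dropped: list[str]


def _select_contrast_samples(meta: pd.DataFrame, spec: DesignSpec) -> pd.DataFrame:
    if spec.factor not in meta.columns:
        raise DesignError(f"metadata has no column {spec.factor!r}")
    sub = meta[meta[spec.factor].isin([spec.test, spec.reference])]
    n_test = int((sub[spec.factor] == spec.test).sum())
    n_ref = int((sub[spec.factor] == spec.reference).sum())
    if n_test < 2 or n_ref < 2:
        raise DesignError(
            f"contrast {spec.label} needs >= 2 samples per group "
            f"(found {spec.test}: {n_test}, {spec.reference}: {n_ref})"
        )
    return sub


def build_design(meta: pd.DataFrame, spec: DesignSpec) -> Design:
    """Build the numeric design matrix for a contrast.

    Covariates aliased with the patient block of a paired design are dropped
    with a warning; any residual rank deficiency raises a
    :class:`~natraj.errors.DesignError` naming the aliased columns.
    """
    sub = _select_contrast_samples(meta, spec)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(sub))}
    dropped: list[str] = []

    if spec.paired:
        if sub["patient_id"].isna().any():
            bad = sub.index[sub["patient_id"].isna()].tolist()
            raise DesignError(f"paired design but samples lack patient_id: {bad[:5]}")
        by_patient = sub.groupby("patient_id")[spec.factor]
        complete = [
            p for p, levels in by_patient.apply(set).items()
            if levels == {spec.test, spec.reference}
        ]
        if len(complete) < 2:
            raise DesignError(
                f"paired design needs >= 2 patients with both arms (found {len(complete)})"
            )
        if len(complete) < sub["patient_id"].nunique():
            dropped_n = len(sub) - int(sub["patient_id"].isin(complete).sum())
            warnings.warn(
                f"paired contrast restricted to {len(complete)} complete pairs "
                f"({dropped_n} unpaired sample(s) dropped)",
                stacklevel=3,
            )
            sub = sub[sub["patient_id"].isin(complete)]
            cols["intercept"] = np.ones(len(sub))
        patients = sorted(sub["patient_id"].unique())
        for p in patients[1:]:  # first patient absorbed by the intercept
            cols[f"patient[{p}]"] = (sub["patient_id"] == p).to_numpy(float)

    for cov in spec.covariates:
        if cov == spec.factor:
            continue
        if cov == "age":
            age = sub["age"].to_numpy(float)
            if np.isnan(age).any():
                warnings.warn(
                    f"{int(np.isnan(age).sum())} missing age value(s) mean-imputed",
                    stacklevel=2,
                )
                age = np.where(np.isnan(age), np.nanmean(age), age)
            sd = age.std()
            cols["age"] = (age - age.mean()) / (sd if sd > 0 else 1.0)
        elif cov == "sex":
            cols["sex[M]"] = (sub["sex"] == "M").to_numpy(float)
        elif cov == "lt_status":
            # N samples carry lt_status "NA" (no thyroid disease): coded LT-
            cols["lt[LT+]"] = (sub["lt_status"] == "LT+").to_numpy(float)
        else:
            raise DesignError(f"unknown covariate {cov!r}")

    contrast_name = f"{spec.factor}[{spec.test}]"
    cols[contrast_name] = (sub[spec.factor] == spec.test).to_numpy(float)

    names = list(cols)
    X = np.column_stack([cols[c] for c in names])

    # drop covariates aliased with the rest of the design (e.g. sex constant
    # within patients of a paired design), preferring to keep the contrast
    while np.linalg.matrix_rank(X) < X.shape[1]:
        droppable = [
            i for i, c in enumerate(names)
            if c not in ("intercept", contrast_name)
        ]
        removed = False
        for i in reversed(droppable):
            trial = np.delete(X, i, axis=1)
            if np.linalg.matrix_rank(trial) == np.linalg.matrix_rank(X):
                warnings.warn(f"dropping aliased design column {names[i]!r}", stacklevel=2)
                dropped.append(names.pop(i))
                X = trial
                removed = True
                break
        if not removed:
            raise DesignError(
                f"design is rank deficient; aliased columns involve the contrast "
                f"{contrast_name!r} (columns: {names})"
            )

    return Design(
        matrix=X,
        columns=names,
        contrast_index=names.index(contrast_name),
        sample_ids=list(sub.index),
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def estimate_dispersions(
    counts: CountMatrix,
    size_factors: pd.Series,
    design: "Design | None" = None,
    shrinkage: float = 0.5,
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Method-of-moments dispersions with log-scale shrinkage toward a trend.

    Without a design, raw per-gene dispersion is
    ``max(floor, (s² − μ̄) / μ̄²)`` on normalized counts.  With a design the
    moments are taken around design-fitted means: a Poisson fit of the full
    model gives per-sample means μ_gs and the raw estimate is
    ``max(floor, Σ[(y − μ)² − μ] / Σ μ²)`` with an n/(n − p)
    degrees-of-freedom inflation — this keeps patient or covariate structure
    out of the dispersion, which is what makes a paired analysis gain power.
    A mean–dispersion trend ``alpha_tr(mu)`` is then fitted by robust
    (Huber) regression of log raw dispersion on log mean, and the returned
    estimate is ``exp((1-w)·log α̂ + w·log α_tr)`` with weight ``shrinkage``
    (0 = raw moments, 1 = pure trend).
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage weight must be in [0, 1]")
    sf = size_factors.reindex(counts.sample_ids).to_numpy(float)
    norm = counts.values() / sf
    mu = norm.mean(axis=1)
    if design is None:
        s2 = norm.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = (s2 - mu) / mu**2
    else:
        Y = counts.subset(sample_ids=design.sample_ids).values().astype(float)
        sf_d = size_factors.reindex(design.sample_ids).to_numpy(float)
        nonzero = Y.sum(axis=1) > 0
        n, p = design.matrix.shape
        raw = np.full(Y.shape[0], floor)
        if nonzero.any() and n > p:
            raw[nonzero] = _pearson_alpha(
                Y[nonzero], design.matrix, np.log(sf_d), floor
            )
        mu = (Y / sf_d).mean(axis=1)
    raw = np.where(np.isfinite(raw), raw, floor)
    raw = np.clip(raw, floor, DISPERSION_CEIL)

    result = raw.copy()
    if shrinkage > 0:
        usable = (mu > 1.0) & (raw > 10 * floor)
        if usable.sum() >= 20:
            import statsmodels.api as sm

            x = sm.add_constant(np.log(mu[usable]))
            fit = sm.RLM(np.log(raw[usable]), x, M=sm.robust.norms.HuberT()).fit()
            with np.errstate(divide="ignore"):
                trend = fit.params[0] + fit.params[1] * np.log(np.maximum(mu, 1e-8))
            trend = np.clip(np.exp(trend), floor, DISPERSION_CEIL)
            # genes at the Poisson floor stay there; others shrink on log scale
            at_floor = raw <= 10 * floor
            log_shrunk = (1 - shrinkage) * np.log(raw) + shrinkage * np.log(trend)
            result = np.where(at_floor, raw, np.exp(log_shrunk))
    return pd.Series(np.clip(result, floor, DISPERSION_CEIL), index=counts.gene_ids,
                     name="dispersion")


def _pearson_alpha(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    floor: float = DISPERSION_FLOOR,
    rounds: int = 2,
) -> np.ndarray:
    """Pearson chi-square dispersion estimates around design-fitted means.

    For each gene, solve sum((y - mu)^2 / (mu (1 + alpha mu))) = n - p for
    alpha >= 0 by bisection (the left side is decreasing in alpha), with the
    GLM means refitted once at the estimated dispersions.  Genes at or below
    Poisson dispersion get the floor.
    """
    G, n = Y.shape
    p = X.shape[1]
    dof = n - p
    alpha = np.zeros(G)
    for _ in range(rounds):
        beta, _, _ = _irls_batch(Y, X, offset, alpha)
        mu = np.exp(np.clip(beta @ X.T + offset[None, :], -30.0, 30.0))
        resid2 = (Y - mu) ** 2

        def pearson(a: np.ndarray) -> np.ndarray:
            return (resid2 / (mu * (1.0 + a[:, None] * mu))).sum(axis=1) - dof

        lo = np.zeros(G)
        hi = np.full(G, DISPERSION_CEIL)
        at_floor = pearson(lo) <= 0.0  # under- or equi-dispersed
        unbounded = pearson(hi) > 0.0  # still overdispersed at the ceiling
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            go_up = pearson(mid) > 0.0
            lo = np.where(go_up, mid, lo)
            hi = np.where(go_up, hi, mid)
        alpha = 0.5 * (lo + hi)
        alpha[at_floor] = floor
        alpha[unbounded] = DISPERSION_CEIL
    return np.clip(alpha, floor, DISPERSION_CEIL)


# ---------------------------------------------------------------------------
# batched IRLS
# ---------------------------------------------------------------------------

def _irls_batch(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit NB log-linear models for many genes sharing one design matrix.

    Parameters: Y (genes × samples), X (samples × p), offset (samples,),
    alpha (genes,).  Returns natural-log-scale coefficients (genes × p),
    coefficient covariances (genes × p × p) and a converged flag per gene.
    """
    G, n = Y.shape
    p = X.shape[1]
    mu = np.maximum(Y.astype(float), 0.0) + 0.5
    eta = np.log(mu)
    beta = np.zeros((G, p))
    converged = np.zeros(G, dtype=bool)
    ridge = 1e-10 * np.eye(p)

    for _ in range(max_iter):
        w = mu / (1.0 + alpha[:, None] * mu)  # NB IRLS weights, log link
        z = (eta - offset[None, :]) + (Y - mu) / mu  # working response
        XtWX = np.einsum("ni,gn,nj->gij", X, w, X, optimize=True) + ridge
        XtWz = np.einsum("ni,gn,gn->gi", X, w, z, optimize=True)
        new_beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        delta = np.abs(new_beta - beta).max(axis=1)
        beta = new_beta
        eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
        mu = np.exp(eta)
        newly = delta < tol
        converged |= newly
        if newly.all():
            break

    w = mu / (1.0 + alpha[:, None] * mu)
    XtWX = np.einsum("ni,gn,nj->gij", X, w, X, optimize=True) + ridge
    cov = np.linalg.inv(XtWX)
    return beta, cov, converged


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    size_factors: np.ndarray,
    dispersion: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one gene's NB GLM; returns (coefficients, covariance), natural-log scale."""
    y = np.asarray(y, float)
    sf = np.asarray(size_factors, float)
    beta, cov, converged = _irls_batch(
        y[None, :], np.asarray(X, float), np.log(sf), np.array([float(dispersion)])
    )
    if not converged[0]:
        warnings.warn("NB GLM did not converge", stacklevel=2)
    return beta[0], cov[0]


# ---------------------------------------------------------------------------
# Wald testing
# ---------------------------------------------------------------------------

def wald_from_fit(
    beta: np.ndarray, cov: np.ndarray, contrast_index: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """log2fc, SE (log2 scale), Wald z and two-sided normal p for one column."""
    coef = beta[:, contrast_index]
    var = cov[:, contrast_index, contrast_index]
    se_ln = np.sqrt(np.maximum(var, 1e-300))
    z = coef / se_ln
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    pvalue = np.clip(pvalue, np.finfo(float).tiny, 1.0)
    return coef / LN2, se_ln / LN2, z, pvalue


def run_de(
    counts: CountMatrix,
    meta: pd.DataFrame,
    spec: DesignSpec,
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    dispersion_shrinkage: float = 0.5,
) -> pd.DataFrame:
    """Differential expression for one contrast.

    Returns a DataFrame indexed by gene_id with columns ``log2fc`` (test over
    reference), ``se`` (log2 scale), ``wald_stat``, ``pvalue``, ``padj`` (BH
    over all tested genes), ``mean_expression`` (mean normalized count over
    the contrast samples) and ``flag`` (ok / all_zero / not_converged).

    Size factors default to median-of-ratios on the supplied matrix;
    dispersions default to :func:`estimate_dispersions` on the contrast
    samples.  Genes with all-zero counts in the contrast get log2fc 0 and
    p 1, flagged ``all_zero``.
    """
    design = build_design(meta, spec)
    sub = counts.subset(sample_ids=design.sample_ids)
    if size_factors is None:
        size_factors = compute_size_factors(sub)
    sf = size_factors.reindex(design.sample_ids).to_numpy(float)
    if dispersions is None:
        dispersions = estimate_dispersions(
            sub, size_factors, design=design, shrinkage=dispersion_shrinkage
        )
    alpha = dispersions.reindex(sub.gene_ids).to_numpy(float)

    Y = sub.values().astype(float)
    nonzero = Y.sum(axis=1) > 0
    G = Y.shape[0]
    log2fc = np.zeros(G)
    se = np.full(G, np.inf)
    z = np.zeros(G)
    pvalue = np.ones(G)
    flag = np.where(nonzero, "ok", "all_zero").astype(object)

    if nonzero.any():
        beta, cov, converged = _irls_batch(
            Y[nonzero], design.matrix, np.log(sf), alpha[nonzero]
        )
        lfc, s, zz, pp = wald_from_fit(beta, cov, design.contrast_index)
        log2fc[nonzero], se[nonzero], z[nonzero], pvalue[nonzero] = lfc, s, zz, pp
        idx = np.flatnonzero(nonzero)
        flag[idx[~converged]] = "not_converged"

    result = pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": se,
            "wald_stat": z,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue),
            "mean_expression": (Y / sf).mean(axis=1),
            "flag": flag,
        },
        index=pd.Index(sub.gene_ids, name="gene_id"),
    )
    result.attrs["contrast"] = spec.label
    result.attrs["n_samples"] = len(design.sample_ids)
    result.attrs["design_columns"] = design.columns
    return result


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment.

    Sort ascending, multiply p(i) by m/i, enforce monotonicity from the
    largest rank downward, cap at 1, and restore the input order.
    """
    p = np.asarray(pvalues, float)
    if p.ndim != 1:
        raise ValidationError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out
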