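"""Per-gene linear models with empirical-Bayes moderated statistics.

Each gene is fit by ordinary least squares against a design built from the
sample table (treatment-only, or sex + treatment + sex:treatment).  Residual
variances are shrunk toward a common prior by the standard
moments-of-log-variance scheme: the prior degrees of freedom d0 and prior
variance s0^2 are estimated by matching the mean and variance of
log s_g^2 through the digamma/trigamma functions, the posterior variance is

    s2_post = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

and moderated t statistics are referred to a t distribution with
d0 + d_g degrees of freedom.  Genes are called differentially expressed
when FDR < alpha (strict) and |logFC| >= lfc_min, both thresholds
configurable with defaults 0.05 and 0.4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .datamodel import ExpressionMatrix, ExpressionStudy


class DesignError(ValueError):
    pass


@dataclass
class GeneFits:
    """Per-gene OLS results for one design."""

    coef: pd.DataFrame  # genes x design columns
    sigma2: np.ndarray  # residual variance per gene
    df_resid: int
    se_unscaled: np.ndarray  # sqrt of diag (X'X)^-1 per coefficient
    design_columns: list[str]
    gene_ids: list[str]


@dataclass
class EmpiricalBayesParams:
    d0: float  # prior df, may be inf
    s0_sq: float


def build_design(study: ExpressionStudy, formula: str) -> pd.DataFrame:
    """Design matrix. Coding: VEH=0/THC=1, F=0/M=1, interaction = product."""
    trt = study.treatment_indicator()
    if formula == "treatment":
        X = pd.DataFrame({"Intercept": 1.0, "treatment": trt})
    elif formula in ("sex*treatment", "sex + treatment + sex:treatment"):
        sex = (study.design["sex"] == "M").to_numpy(dtype=float)
        X = pd.DataFrame(
            {
                "Intercept": 1.0,
                "sex": sex,
                "treatment": trt,
                "sex:treatment": sex * trt,
            }
        )
    else:
        raise DesignError(f"unknown formula {formula!r}")
    X.index = study.sample_ids
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy()
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        # name the first column lying in the span of its predecessors
        for j in range(1, mat.shape[1]):
            if np.linalg.matrix_rank(mat[:, : j + 1]) <= np.linalg.matrix_rank(
                mat[:, :j]
            ):
                raise DesignError(f"design is rank deficient: column "
                                  f"{X.columns[j]!r} is aliased")
        raise DesignError("design is rank deficient")


def fit_gene_models(study: ExpressionStudy, formula: str = "treatment") -> GeneFits:
    """Ordinary least squares per gene, vectorized over the gene axis."""
    X = build_design(study, formula)
    _check_full_rank(X)
    mat = X.to_numpy()
    n, p = mat.shape
    if n <= p:
        raise DesignError(f"need more samples ({n}) than coefficients ({p})")
    Y = study.expr.values  # genes x samples
    xtx_inv = np.linalg.inv(mat.T @ mat)
    beta = Y @ mat @ xtx_inv  # genes x p
    resid = Y - beta @ mat.T
    df = n - p
    sigma2 = (resid**2).sum(axis=1) / df
    return GeneFits(
        coef=pd.DataFrame(beta, index=study.gene_ids, columns=list(X.columns)),
        sigma2=sigma2,
        df_resid=df,
        se_unscaled=np.sqrt(np.diag(xtx_inv)),
        design_columns=list(X.columns),
        gene_ids=study.gene_ids,
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (x > 0)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(sigma2: np.ndarray, df_resid: int) -> EmpiricalBayesParams:
    """Moment-match log s^2 against a scaled F to get (d0, s0^2)."""
    s2 = np.asarray(sigma2, dtype=float)
    if np.all(s2 == 0):
        raise ValueError("all residual variances are zero; nothing to moderate")
    pos = s2[s2 > 0]
    if len(pos) < 10:
        raise ValueError("need >=10 genes with positive residual variance")
    d = float(df_resid)
    e = np.log(pos) - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    n = len(e)
    evar = float(np.sum((e - emean) ** 2) / (n - 1)) - float(
        special.polygamma(1, d / 2.0)
    )
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return EmpiricalBayesParams(d0=d0, s0_sq=s0_sq)


def moderate_statistics(
    fits: GeneFits,
    coefficient: str = "treatment",
    prior: EmpiricalBayesParams | None = None,
) -> tuple[EmpiricalBayesParams, pd.DataFrame]:
    """Moderated t and p for one coefficient; prior may be forced for limits."""
    if coefficient not in fits.design_columns:
        raise DesignError(f"coefficient {coefficient!r} not in design "
                          f"{fits.design_columns}")
    if prior is None:
        prior = estimate_prior(fits.sigma2, fits.df_resid)
    d0, s0 = prior.d0, prior.s0_sq
    d = fits.df_resid
    if np.isinf(d0):
        s2_post = np.full_like(fits.sigma2, s0)
    else:
        s2_post = (d0 * s0 + d * fits.sigma2) / (d0 + d)
    j = fits.design_columns.index(coefficient)
    se = fits.se_unscaled[j] * np.sqrt(s2_post)
    coef = fits.coef[coefficient].to_numpy()
    t_mod = np.zeros_like(coef)
    ok = se > 0
    t_mod[ok] = coef[ok] / se[ok]
    t_mod[~ok] = np.sign(coef[~ok]) * np.inf  # zero posterior variance
    t_mod[~ok & (coef == 0)] = 0.0
    df_total = d0 + d
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    table = pd.DataFrame(
        {
            "gene_id": fits.gene_ids,
            "logFC": coef,
            "t_mod": t_mod,
            "p": np.clip(p, 0.0, 1.0),
        }
    )
    return prior, table


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def call_degs(
    table: pd.DataFrame, alpha: float = 0.05, lfc_min: float = 0.4
) -> pd.DataFrame:
    """Dual-threshold call: FDR strictly below alpha AND |logFC| >= lfc_min."""
    out = table.copy()
    if "fdr" not in out.columns:
        out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["is_deg"] = (out["fdr"] < alpha) & (out["logFC"].abs() >= lfc_min)
    return out


def deg_table(
    study: ExpressionStudy,
    formula: str = "treatment",
    coefficient: str = "treatment",
    alpha: float = 0.05,
    lfc_min: float = 0.4,
    prior: EmpiricalBayesParams | None = None,
) -> pd.DataFrame:
    """End-to-end DE: fit, moderate, adjust, call."""
    fits = fit_gene_models(study, formula)
    _, table = moderate_statistics(fits, coefficient, prior=prior)
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    return call_degs(table, alpha=alpha, lfc_min=lfc_min)


def interaction_degs(
    study: ExpressionStudy, alpha: float = 0.05, lfc_min: float = 0.4
) -> pd.DataFrame:
    """DEGs on the sex:treatment interaction; both sexes must be present."""
    sexes = set(study.design["sex"])
    if len(sexes) < 2:
        raise DesignError("interaction analysis requires both sexes")
    return deg_table(
        study,
        formula="sex*treatment",
        coefficient="sex:treatment",
        alpha=alpha,
        lfc_min=lfc_min,
    )


def pca_overview(expr: ExpressionMatrix, n_components: int = 10, top_k: int = 50):
    """PCA of gene-standardized expression with top loading genes per PC.

    Zero-variance genes are excluded from standardization; if every gene is
    constant the function reports zero components rather than failing.
    Returns ``(coords, loadings, top_genes)`` where ``top_genes[pc]`` lists
    the ``top_k`` genes ranked by absolute loading.
    """
    if top_k > expr.n_genes:
        raise ValueError(f"top_k={top_k} exceeds n_genes={expr.n_genes}")
    vals = expr.values
    sd = vals.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        return (
            pd.DataFrame(index=expr.sample_ids),
            pd.DataFrame(),
            {},
        )
    genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    Z = (vals[keep] - vals[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    X = Z.T  # samples x genes
    n_components = min(n_components, min(X.shape) - 1) or 1
    U, S, Vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
    coords = pd.DataFrame(
        U[:, :n_components] * S[:n_components],
        index=expr.sample_ids,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    loadings = pd.DataFrame(
        Vt[:n_components].T,
        index=genes,
        columns=coords.columns,
    )
    k = min(top_k, len(genes))
    top_genes = {
        pc: list(loadings[pc].abs().sort_values(ascending=False).index[:k])
        for pc in coords.columns
    }
    return coords, loadings, top_genes
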