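"""Per-metabolite linear models and conditional contrasts.

For every metabolite within a sample type we fit, by ordinary least
squares,

    log2(concentration) ~ Genotype + Microbiome + Genotype:Microbiome
                          + BodyWeight

with treatment coding Genotype = 1{ASO}, Microbiome = 1{SPF} (reference
cell WT-GF) and body weight centered at the dataset mean.  Because of
the interaction, the group differences of scientific interest are
*conditional contrasts*:

* genotype effect within SPF animals  (ASO-SPF vs WT-SPF) = bG + bGxM
* microbiome effect within ASO animals (ASO-SPF vs ASO-GF) = bM + bGxM

Inference is by t-statistics with n - 5 residual degrees of freedom.
Significance sets use the contrast p-values for the genotype and
microbiome terms and the interaction coefficient's p-value for the
interaction term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import ConcentrationDataset, ValidationError

COEF_NAMES = ("intercept", "beta_G", "beta_M", "beta_GxM", "beta_BW")
TERMS = ("genotype", "microbiome", "interaction")

#: residual variance below this (relative to the response scale) is
#: treated as a degenerate, noiseless fit: p-values are reported as 1
_DEGENERATE_REL_TOL = 1e-12


@dataclass
class ModelResult:
    """Fit summary for one metabolite in one sample type."""

    metabolite_id: str
    sample_type: str
    n: int
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    cov: np.ndarray
    df_resid: int
    degenerate: bool
    contrast_genotype_at_SPF: tuple[float, float, float] | None = None
    contrast_microbiome_at_ASO: tuple[float, float, float] | None = None


def build_design(meta: pd.DataFrame) -> pd.DataFrame:
    """Model matrix [1, 1{ASO}, 1{SPF}, interaction, centered body weight]."""
    g = (meta["genotype"] == "ASO").astype(float)
    m = (meta["microbiome"] == "SPF").astype(float)
    bw = meta["body_weight"].astype(float)
    X = pd.DataFrame({
        "intercept": 1.0,
        "beta_G": g,
        "beta_M": m,
        "beta_GxM": g * m,
        "beta_BW": bw - bw.mean(),
    }, index=meta.index)
    return X


def fit_metabolite_model(y, meta: pd.DataFrame,
                         metabolite_id: str = "", sample_type: str = "") -> ModelResult:
    """OLS fit of one metabolite's log2 levels on the 2x2 + body-weight design.

    Requires both genotypes and both microbiome states present, a
    full-rank design, and positive residual degrees of freedom.  A
    degenerate fit (zero residual variance, e.g. constant response)
    reports every p-value as 1 so that downstream set operations stay
    total.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) != len(meta):
        raise ValidationError("y and meta lengths differ")
    if np.isnan(y).any():
        raise ValidationError(f"{metabolite_id!r}: missing values in response")
    X = build_design(meta)
    n, k = X.shape
    df = n - k
    if df <= 0:
        raise ValidationError(
            f"{metabolite_id!r}: {n} samples leave no residual df for "
            f"{k} parameters")
    if np.linalg.matrix_rank(X.to_numpy()) < k:
        raise ValidationError(
            f"{metabolite_id!r}: rank-deficient design (a genotype x "
            "microbiome cell is missing or body weight is constant)")

    fit = sm.OLS(y, X).fit()
    scale_ref = max(np.var(y), 1.0)
    degenerate = fit.ssr / n <= _DEGENERATE_REL_TOL * scale_ref
    params = dict(zip(COEF_NAMES, fit.params))
    ses = dict(zip(COEF_NAMES, fit.bse))
    if degenerate:
        pvals = {c: 1.0 for c in COEF_NAMES}
    else:
        pvals = dict(zip(COEF_NAMES, fit.pvalues))
    res = ModelResult(
        metabolite_id=metabolite_id, sample_type=sample_type, n=n,
        coefficients=params, standard_errors=ses, p_values=pvals,
        cov=np.asarray(fit.cov_params()), df_resid=df, degenerate=degenerate)
    res.contrast_genotype_at_SPF = compute_contrast(res, "genotype_at_SPF")
    res.contrast_microbiome_at_ASO = compute_contrast(res, "microbiome_at_ASO")
    return res


_CONTRASTS = {
    "genotype_at_SPF": np.array([0.0, 1.0, 0.0, 1.0, 0.0]),
    "microbiome_at_ASO": np.array([0.0, 0.0, 1.0, 1.0, 0.0]),
}


def compute_contrast(fit: ModelResult, which: str) -> tuple[float, float, float]:
    """Estimate, SE and two-sided p of a conditional contrast.

    ``genotype_at_SPF`` = bG + bGxM (ASO vs WT within SPF);
    ``microbiome_at_ASO`` = bM + bGxM (SPF vs GF within ASO).
    """
    if which not in _CONTRASTS:
        raise ValidationError(f"unknown contrast {which!r}")
    c = _CONTRASTS[which]
    beta = np.array([fit.coefficients[k] for k in COEF_NAMES])
    est = float(c @ beta)
    var = float(c @ fit.cov @ c)
    se = float(np.sqrt(max(var, 0.0)))
    if fit.degenerate or se == 0.0:
        p = 1.0
    else:
        t = est / se
        p = float(2.0 * stats.t.sf(abs(t), fit.df_resid))
    return est, se, p


def fit_dataset(ds: ConcentrationDataset) -> pd.DataFrame:
    """Fit every metabolite of a log2-scale dataset; tidy one-row-per-
    metabolite output with coefficients, SEs, p-values, contrasts and
    per-term BH q-values."""
    if not ds.log2_scale:
        raise ValidationError(
            f"{ds.sample_type}: fit_dataset expects log2-transformed data")
    rows = []
    for mid in ds.values.columns:
        r = fit_metabolite_model(ds.values[mid].to_numpy(), ds.meta,
                                 metabolite_id=mid, sample_type=ds.sample_type)
        row = {"metabolite_id": mid, "sample_type": ds.sample_type, "n": r.n}
        for c in COEF_NAMES:
            row[c] = r.coefficients[c]
            row[f"se_{c}"] = r.standard_errors[c]
            row[f"p_{c}"] = r.p_values[c]
        for name, (est, se, p) in (
                ("genotype_at_SPF", r.contrast_genotype_at_SPF),
                ("microbiome_at_ASO", r.contrast_microbiome_at_ASO)):
            row[f"contrast_{name}"] = est
            row[f"se_contrast_{name}"] = se
            row[f"p_contrast_{name}"] = p
        rows.append(row)
    out = pd.DataFrame(rows)
    out["q_genotype"] = bh_fdr(out["p_contrast_genotype_at_SPF"])
    out["q_microbiome"] = bh_fdr(out["p_contrast_microbiome_at_ASO"])
    out["q_interaction"] = bh_fdr(out["p_beta_GxM"])
    return out


#: column of the tidy results frame carrying each term's p-value / effect
TERM_P_COLUMN = {
    "genotype": "p_contrast_genotype_at_SPF",
    "microbiome": "p_contrast_microbiome_at_ASO",
    "interaction": "p_beta_GxM",
}
TERM_EFFECT_COLUMN = {
    "genotype": "contrast_genotype_at_SPF",
    "microbiome": "contrast_microbiome_at_ASO",
    "interaction": "beta_GxM",
}


def classify_significance(
    results: pd.DataFrame, alpha: float = 0.05, mode: str = "strict"
) -> dict[tuple[str, str], set[str]]:
    """Per (sample_type, term) sets of significant metabolites.

    ``mode='strict'`` keeps p < alpha (boundary excluded); ``'inclusive'``
    keeps p <= alpha.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    if mode not in ("strict", "inclusive"):
        raise ValidationError(f"unknown significance mode {mode!r}")
    out: dict[tuple[str, str], set[str]] = {}
    for st, sub in results.groupby("sample_type"):
        for term, col in TERM_P_COLUMN.items():
            p = sub[col]
            hit = p < alpha if mode == "strict" else p <= alpha
            out[(st, term)] = set(sub.loc[hit, "metabolite_id"])
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
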