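"""Distance-based permutation tests: PERMANOVA and dispersion homogeneity.

PERMANOVA partitions the total sum of squared Euclidean distances among
the terms of the 2x2 design using sequential (Type I) sums of squares in
the fixed order Genotype, Microbiome, Interaction.  With the Gower
double-centered matrix

    G = -1/2 * J A J,   A_ij = d_ij^2,   J = I - 11'/n,

the sum of squares explained by adding a block of columns to the model
is tr((H_k - H_{k-1}) G), where H_k is the hat matrix of the design
built from the first k terms.  The pseudo-F for each term is

    F = (SS_term / df_term) / (SS_residual / df_residual),

and its null distribution is obtained by freely permuting sample labels
(equivalently, conjugating G by a permutation) and recomputing every
term's F with the hat matrices held fixed.  The reported p-value
(1 + #{F* >= F_obs}) / (1 + n_perm) includes the observed ordering, so
it is bounded below by 1/(n_perm + 1) and exact under exchangeability.

The dispersion test embeds the distances by principal coordinates,
measures each sample's distance to its group's spatial median (or
centroid), with the usual correction d^2 = d_+^2 - d_-^2 for negative
eigenvalues, and permutes group labels over those distances under a
one-way ANOVA F.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datasets import ValidationError

TERM_ORDER = ("genotype", "microbiome", "interaction")


def euclidean_distance_matrix(X) -> np.ndarray:
    """Pairwise Euclidean distances between the rows of X."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValidationError("distance matrix input contains missing values")
    return squareform(pdist(X, metric="euclidean"))


def _gower_center(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    A = -0.5 * D ** 2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    return J @ A @ J


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def _term_columns(meta: pd.DataFrame, term: str) -> np.ndarray:
    g = (meta["genotype"] == "ASO").to_numpy(float)
    m = (meta["microbiome"] == "SPF").to_numpy(float)
    if term == "genotype":
        return g[:, None]
    if term == "microbiome":
        return m[:, None]
    if term == "interaction":
        return (g * m)[:, None]
    raise ValidationError(f"unknown PERMANOVA term {term!r}")


@dataclass
class PermanovaResult:
    """Sequential-SS PERMANOVA decomposition with permutation p-values."""

    table: pd.DataFrame  # rows: terms, Residual, Total
    n_permutations: int
    seed: int

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p_perm"])


def permanova(
    D: np.ndarray,
    meta: pd.DataFrame,
    terms: tuple[str, ...] = TERM_ORDER,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational MANOVA on a distance matrix for the 2x2 design.

    Parameters
    ----------
    D
        Symmetric distance matrix aligned with the rows of ``meta``.
    meta
        Sample metadata with ``genotype`` and ``microbiome`` columns.
    terms
        Ordered model terms; sums of squares are sequential in this
        order.
    n_perm
        Number of random label permutations (>= 1).
    seed
        Seed of the permutation stream; results are deterministic
        given the seed.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-8):
        raise ValidationError("D must be a symmetric square matrix")
    if len(meta) != n:
        raise ValidationError("metadata length does not match D")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    for col in ("genotype", "microbiome"):
        counts = meta[col].value_counts()
        if len(counts) < 2 or counts.min() < 2:
            raise ValidationError(
                f"every {col} level must be represented at least twice")

    G = _gower_center(D)
    ss_total = float(np.trace(G))

    # incremental hat matrices: intercept, then one term at a time
    X = np.ones((n, 1))
    hats = [_hat(X)]
    dfs = []
    for term in terms:
        cols = _term_columns(meta, term)
        X = np.hstack([X, cols])
        H = _hat(X)
        dfs.append(int(round(np.trace(H) - np.trace(hats[-1]))))
        hats.append(H)
    if any(df < 1 for df in dfs):
        raise ValidationError("confounded design: a term adds no rank")
    H_full = hats[-1]
    df_resid = n - int(round(np.trace(H_full)))
    if df_resid < 1:
        raise ValidationError("confounded design: zero residual df")

    # projector differences; SS_term = sum(P_k * G) = tr(P_k G)
    projs = [hats[i + 1] - hats[i] for i in range(len(terms))]
    resid_proj = np.eye(n) - H_full

    def f_stats(Gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss_terms = np.array([float(np.sum(P * Gmat)) for P in projs])
        ss_res = float(np.sum(resid_proj * Gmat))
        ms_res = ss_res / df_resid
        return (ss_terms / np.array(dfs)) / ms_res, ss_res

    f_obs, ss_res = f_stats(G)
    ss_terms = np.array([float(np.sum(P * G)) for P in projs])

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms), dtype=int)
    for _ in range(n_perm):
        idx = rng.permutation(n)
        Gp = G[np.ix_(idx, idx)]
        f_perm, _ = f_stats(Gp)
        exceed += f_perm >= f_obs
    p = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for i, term in enumerate(terms):
        rows.append((term, dfs[i], ss_terms[i], ss_terms[i] / ss_total,
                     f_obs[i], p[i]))
    rows.append(("Residual", df_resid, ss_res, ss_res / ss_total,
                 np.nan, np.nan))
    rows.append(("Total", n - 1, ss_total, 1.0, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["term", "df", "SS", "R2",
                                        "pseudo_F", "p_perm"]).set_index("term")
    return PermanovaResult(table=table, n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Dispersion homogeneity (betadisper-style)


def pcoa_embedding(D: np.ndarray, tol: float = 1e-8):
    """Principal-coordinates embedding split into real and imaginary parts.

    Returns (coords_pos, coords_neg): coordinates on axes with positive
    and negative eigenvalues respectively (scaled by sqrt(|eigenvalue|)).
    For a Euclidean distance matrix coords_neg is empty.
    """
    G = _gower_center(np.asarray(D, dtype=float))
    vals, vecs = np.linalg.eigh((G + G.T) / 2.0)
    scale = max(abs(vals).max(), 1.0)
    pos = vals > tol * scale
    neg = vals < -tol * scale
    cp = vecs[:, pos] * np.sqrt(vals[pos])
    cn = vecs[:, neg] * np.sqrt(-vals[neg])
    return cp, cn


def _spatial_median(Y: np.ndarray, max_iter: int = 500, tol: float = 1e-12
                    ) -> np.ndarray:
    """Weiszfeld iteration for the geometric (spatial) median of rows."""
    if Y.shape[0] == 0 or Y.shape[1] == 0:
        return np.zeros(Y.shape[1])
    med = Y.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(Y - med, axis=1)
        if np.any(d < 1e-300):
            # median coincides with a data point; it is optimal there
            return Y[np.argmin(d)].copy()
        w = 1.0 / d
        new = (w[:, None] * Y).sum(axis=0) / w.sum()
        if np.linalg.norm(new - med) < tol * (1.0 + np.linalg.norm(med)):
            return new
        med = new
    return med


@dataclass
class DispersionResult:
    F: float
    p_perm: float
    distances: pd.Series
    group_centers: dict
    n_permutations: int


def dispersion_test(
    D: np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    center: str = "median",
) -> DispersionResult:
    """Permutation test for homogeneity of multivariate group dispersions.

    Each sample's dispersion is its PCoA-space distance to its group's
    spatial median (default) or centroid, with the negative-eigenvalue
    correction d^2 = d_+^2 - d_-^2 (clamped at 0).  Group labels are
    permuted over the observed distances under the one-way ANOVA F.
    """
    groups = pd.Series(list(groups))
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValidationError("dispersion test needs >= 2 groups")
    if counts.min() < 2:
        raise ValidationError("every group needs >= 2 members")
    if center not in ("median", "centroid"):
        raise ValidationError(f"unknown center {center!r}")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")

    cp, cn = pcoa_embedding(D)
    z = np.empty(len(groups))
    centers = {}
    for lvl in counts.index:
        idx = np.flatnonzero((groups == lvl).to_numpy())
        if center == "median":
            c_pos = _spatial_median(cp[idx])
            c_neg = _spatial_median(cn[idx]) if cn.shape[1] else np.zeros(0)
        else:
            c_pos = cp[idx].mean(axis=0)
            c_neg = cn[idx].mean(axis=0) if cn.shape[1] else np.zeros(0)
        centers[lvl] = (c_pos, c_neg)
        d2 = np.sum((cp[idx] - c_pos) ** 2, axis=1)
        if cn.shape[1]:
            d2 = d2 - np.sum((cn[idx] - c_neg) ** 2, axis=1)
        z[idx] = np.sqrt(np.clip(d2, 0.0, None))

    def anova_f(labels: np.ndarray) -> float:
        grand = z.mean()
        ss_b = ss_w = 0.0
        for lvl in counts.index:
            zi = z[labels == lvl]
            ss_b += len(zi) * (zi.mean() - grand) ** 2
            ss_w += float(np.sum((zi - zi.mean()) ** 2))
        df_b = len(counts) - 1
        df_w = len(z) - len(counts)
        if ss_w <= 0:
            return 0.0 if ss_b <= 0 else np.inf
        return (ss_b / df_b) / (ss_w / df_w)

    lab = groups.to_numpy()
    f_obs = anova_f(lab)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        exceed += anova_f(rng.permutation(lab)) >= f_obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    return DispersionResult(F=float(f_obs), p_perm=float(p),
                            distances=pd.Series(z, index=groups.index),
                            group_centers=centers, n_permutations=n_perm)


def permanova_all(
    datasets: dict, n_perm: int = 10_000, seed: int = 0
) -> pd.DataFrame:
    """Run PERMANOVA per sample type on log2 datasets; tidy output."""
    rows = []
    for st in sorted(datasets):
        ds = datasets[st]
        if not ds.log2_scale:
            raise ValidationError(f"{st}: PERMANOVA expects log2 data")
        D = euclidean_distance_matrix(ds.values.to_numpy(float))
        res = permanova(D, ds.meta, n_perm=n_perm, seed=seed)
        for term, row in res.table.iterrows():
            rows.append((st, term, row["df"], row["SS"], row["R2"],
                         row["pseudo_F"], row["p_perm"], n_perm, seed))
    return pd.DataFrame(rows, columns=["sample_type", "term", "df", "SS", "R2",
                                       "pseudo_F", "p_perm", "n_permutations",
                                       "seed"])
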