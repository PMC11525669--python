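"""PERMANOVA and dispersion test against independent oracles.

The key cross-checks: a closed-form one-factor pseudo-F from group
distance sums, exhaustive permutation enumeration at n = 6, and the R
vegan package (adonis2 / betadisper) run through Rscript on a fixture.
"""

import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import metaxis as mx
from metaxis.datasets import ValidationError
from metaxis.multivariate import pcoa_embedding

from conftest import balanced_meta


def _meta(genotype, microbiome=None):
    n = len(genotype)
    microbiome = microbiome if microbiome is not None \
        else ["SPF" if i % 2 else "GF" for i in range(n)]
    return pd.DataFrame({"genotype": list(genotype),
                         "microbiome": list(microbiome)})


def test_distance_examples():
    D = mx.euclidean_distance_matrix([[1.0, 2.0], [1.0, 2.0]])
    assert D[0, 1] == 0.0
    D = mx.euclidean_distance_matrix([[0.0, 0.0], [3.0, 4.0]])
    assert D[0, 1] == pytest.approx(5.0)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_distance_matches_double_loop(seed):
    X = np.random.default_rng(seed).normal(size=(6, 4))
    D = mx.euclidean_distance_matrix(X)
    for i in range(6):
        for j in range(6):
            d = np.sqrt(np.sum((X[i] - X[j]) ** 2))
            assert abs(D[i, j] - d) < 1e-12


def test_distance_rejects_missing_values():
    with pytest.raises(ValidationError):
        mx.euclidean_distance_matrix([[1.0, np.nan], [0.0, 0.0]])


def _one_factor_oracle_f(D, labels):
    """Closed-form one-factor pseudo-F from within/between distance sums."""
    n = len(labels)
    ss_total = np.sum(np.triu(D, 1) ** 2) / n
    ss_within = 0.0
    for lvl in set(labels):
        idx = [i for i, l in enumerate(labels) if l == lvl]
        sub = D[np.ix_(idx, idx)]
        ss_within += np.sum(np.triu(sub, 1) ** 2) / len(idx)
    a = len(set(labels))
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a)), ss_between, ss_total


def test_one_factor_ss_matches_classical_decomposition():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(10, 3))
    g = ["WT"] * 5 + ["ASO"] * 5
    D = mx.euclidean_distance_matrix(X)
    res = mx.permanova(D, _meta(g), terms=("genotype",), n_perm=9, seed=0)
    f_oracle, ss_b, ss_t = _one_factor_oracle_f(D, g)
    assert res.table.loc["genotype", "SS"] == pytest.approx(ss_b, rel=1e-9)
    assert res.table.loc["Total", "SS"] == pytest.approx(ss_t, rel=1e-9)
    assert res.table.loc["genotype", "pseudo_F"] == pytest.approx(f_oracle,
                                                                  rel=1e-9)


def test_ss_decomposition_sums_to_total():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(23, 8))
    meta = balanced_meta(6, seed=3).iloc[:23]
    D = mx.euclidean_distance_matrix(X)
    res = mx.permanova(D, meta, n_perm=9, seed=0)
    terms_ss = res.table.loc[["genotype", "microbiome", "interaction",
                              "Residual"], "SS"].sum()
    assert terms_ss == pytest.approx(res.table.loc["Total", "SS"], rel=1e-9)
    assert ((res.table["R2"].dropna() >= 0)
            & (res.table["R2"].dropna() <= 1)).all()


def test_pseudo_f_invariant_under_consistent_relabeling():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(16, 5))
    meta = balanced_meta(4, seed=4)
    D = mx.euclidean_distance_matrix(X)
    a = mx.permanova(D, meta, n_perm=49, seed=0)
    perm = rng.permutation(16)
    b = mx.permanova(D[np.ix_(perm, perm)],
                     meta.iloc[perm].reset_index(drop=True),
                     n_perm=49, seed=0)
    assert np.allclose(a.table["pseudo_F"].dropna(),
                       b.table["pseudo_F"].dropna())


def test_sampled_p_matches_exhaustive_enumeration_at_n6():
    """n = 6, one 2-level factor: the sampled permutation p agrees with
    the exact p over all 720 label orders within 2 Monte-Carlo SEs."""
    rng = np.random.default_rng(12)
    X = rng.normal(size=(6, 3))
    X[:3] += 1.0
    g = ["WT", "WT", "WT", "ASO", "ASO", "ASO"]
    D = mx.euclidean_distance_matrix(X)
    f_obs, _, _ = _one_factor_oracle_f(D, g)
    count = 0
    total = 0
    for perm in itertools.permutations(range(6)):
        labels = [g[i] for i in perm]
        f, _, _ = _one_factor_oracle_f(D, labels)
        count += f >= f_obs - 1e-12
        total += 1
    exact_p = count / total
    n_perm = 2000
    res = mx.permanova(D, _meta(g, microbiome=["SPF", "GF"] * 3),
                       terms=("genotype",), n_perm=n_perm, seed=5)
    sampled_p = res.p_value("genotype")
    mc_se = np.sqrt(exact_p * (1 - exact_p) / n_perm)
    assert abs(sampled_p - exact_p) <= 2 * mc_se + 1.0 / n_perm


def test_huge_shift_reaches_minimum_p():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(16, 4))
    meta = balanced_meta(4, seed=8)
    X[(meta["genotype"] == "ASO").to_numpy()] += 100.0
    D = mx.euclidean_distance_matrix(X)
    res = mx.permanova(D, meta, n_perm=499, seed=1)
    assert res.p_value("genotype") == pytest.approx(1.0 / 500.0)


def test_p_floor_and_ceiling():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(12, 4))
    meta = balanced_meta(3, seed=9)
    res = mx.permanova(mx.euclidean_distance_matrix(X), meta,
                       n_perm=99, seed=2)
    p = res.table["p_perm"].dropna()
    assert (p >= 1.0 / 100.0).all() and (p <= 1.0).all()


def test_permanova_input_validation():
    meta = balanced_meta(3)
    D = mx.euclidean_distance_matrix(np.random.default_rng(0).normal(size=(12, 3)))
    with pytest.raises(ValidationError):
        mx.permanova(D, meta, n_perm=0)
    with pytest.raises(ValidationError):
        mx.permanova(D[:6, :6], meta)
    solo = meta.copy()
    solo["genotype"] = "WT"
    with pytest.raises(ValidationError):
        mx.permanova(D, solo)


# ---------------------------------------------------------------------------
# dispersion test


def test_identical_group_geometry_gives_null_dispersion():
    rng = np.random.default_rng(10)
    A = rng.normal(size=(8, 3))
    X = np.vstack([A, A + 50.0])  # translated copy: same spread
    D = mx.euclidean_distance_matrix(X)
    res = mx.dispersion_test(D, ["a"] * 8 + ["b"] * 8, n_perm=199, seed=0)
    assert res.F == pytest.approx(0.0, abs=1e-8)
    assert res.p_perm > 0.9


def test_unequal_dispersion_detected():
    rng = np.random.default_rng(11)
    X = np.vstack([rng.normal(scale=0.1, size=(10, 4)),
                   rng.normal(scale=5.0, size=(10, 4))])
    D = mx.euclidean_distance_matrix(X)
    res = mx.dispersion_test(D, ["tight"] * 10 + ["wide"] * 10,
                             n_perm=999, seed=0)
    assert res.p_perm <= 0.01


def test_centroid_distances_match_brute_force():
    """With centroid centers and Euclidean input the PCoA-space distance
    to the group centroid equals the original-space distance."""
    rng = np.random.default_rng(13)
    X = rng.normal(size=(12, 5))
    groups = ["a"] * 6 + ["b"] * 6
    D = mx.euclidean_distance_matrix(X)
    res = mx.dispersion_test(D, groups, n_perm=9, seed=0, center="centroid")
    for lvl in ("a", "b"):
        idx = [i for i, g in enumerate(groups) if g == lvl]
        centroid = X[idx].mean(axis=0)
        brute = np.linalg.norm(X[idx] - centroid, axis=1)
        assert np.allclose(np.sort(res.distances.iloc[idx]),
                           np.sort(brute), atol=1e-9)


def test_pcoa_reproduces_euclidean_geometry():
    rng = np.random.default_rng(14)
    X = rng.normal(size=(9, 4))
    D = mx.euclidean_distance_matrix(X)
    cp, cn = pcoa_embedding(D)
    assert cn.shape[1] == 0
    D2 = mx.euclidean_distance_matrix(cp)
    assert np.allclose(D, D2, atol=1e-8)


def test_dispersion_needs_two_groups_of_two():
    D = mx.euclidean_distance_matrix(np.random.default_rng(0).normal(size=(4, 2)))
    with pytest.raises(ValidationError):
        mx.dispersion_test(D, ["a", "a", "a", "b"])


# ---------------------------------------------------------------------------
# cross-check against R vegan (adonis2 / betadisper)


def test_matches_vegan_adonis2_and_betadisper(tmp_path):
    rng = np.random.default_rng(5)
    n = 16
    meta = balanced_meta(4, seed=5)
    X = rng.normal(size=(n, 6))
    X[(meta["genotype"] == "ASO").to_numpy()] += 0.8
    D = mx.euclidean_distance_matrix(X)
    res = mx.permanova(D, meta, n_perm=99, seed=1)
    disp = mx.dispersion_test(D, meta["genotype"], n_perm=99, seed=1)

    np.savetxt(tmp_path / "X.csv", X, delimiter=",")
    meta[["genotype", "microbiome"]].to_csv(tmp_path / "meta.csv", index=False)
    script = f"""
suppressMessages(library(vegan))
X <- as.matrix(read.csv("{tmp_path}/X.csv", header=FALSE))
meta <- read.csv("{tmp_path}/meta.csv")
D <- dist(X)
a <- adonis2(D ~ genotype + microbiome + genotype:microbiome, data=meta,
             permutations=99, by="terms")
cat("SS:", paste(a$SumOfSqs, collapse=","), "\\n")
cat("F:", paste(a$F[1:3], collapse=","), "\\n")
bd <- betadisper(D, meta$genotype, type="median")
cat("DIST:", paste(bd$distances, collapse=","), "\\n")
"""
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True).stdout
    lines = {l.split(":")[0]: l.split(":", 1)[1] for l in out.splitlines()
             if ":" in l}
    ss = np.array([float(v) for v in lines["SS"].split(",")])
    f = np.array([float(v) for v in lines["F"].split(",")])
    dists = np.array([float(v) for v in lines["DIST"].split(",")])

    mine_ss = res.table.loc[["genotype", "microbiome", "interaction",
                             "Residual", "Total"], "SS"].to_numpy()
    mine_f = res.table.loc[["genotype", "microbiome", "interaction"],
                           "pseudo_F"].to_numpy()
    assert np.allclose(mine_ss, ss, rtol=1e-6)
    assert np.allclose(mine_f, f, rtol=1e-6)
    assert np.allclose(disp.distances.to_numpy(), dists, atol=2e-4)
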