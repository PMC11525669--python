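"""Plasma-anchored cross-tissue Spearman correlation network.

For every metabolite retained (after QC) in both plasma and another
sample type, samples are paired by animal and the Spearman rank
correlation between the two tissues' levels is computed.  Edges with
rho strictly above the threshold (0.75 by default, one-sided: positive
concordance) and enough paired animals form a bipartite
metabolite-tissue network; a metabolite's connectivity degree is the
number of tissues it is strongly coupled to through plasma.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ConcentrationDataset, ValidationError


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation (midranks for ties).

    Returns NaN (the undefined sentinel) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValidationError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def _by_animal(ds: ConcentrationDataset) -> pd.DataFrame:
    """Value matrix re-indexed by animal_id (one sample per animal)."""
    out = ds.values.copy()
    out.index = pd.Index(ds.meta["animal_id"], name="animal_id")
    return out


def plasma_anchor_correlations(
    datasets: dict[str, ConcentrationDataset],
    threshold: float = 0.75,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Correlate every metabolite's level in each tissue with its plasma level.

    Pairs are formed by animal (pairwise-complete over shared animals).
    An edge passes iff rho > threshold strictly and n_pairs >= min_pairs.
    Metabolites constant in either tissue yield an undefined rho and are
    excluded.  Columns: metabolite_id, sample_type, rho, n_pairs, passes.
    """
    if "plasma" not in datasets:
        raise ValidationError("plasma dataset required as the anchor")
    plasma = _by_animal(datasets["plasma"])
    rows = []
    for st in sorted(datasets):
        if st == "plasma":
            continue
        tissue = _by_animal(datasets[st])
        shared_animals = plasma.index.intersection(tissue.index)
        if len(shared_animals) == 0:
            raise ValidationError(
                f"{st}: no animals overlap with the plasma dataset")
        shared_mets = plasma.columns.intersection(tissue.columns)
        for mid in shared_mets:
            a = plasma.loc[shared_animals, mid].to_numpy(float)
            b = tissue.loc[shared_animals, mid].to_numpy(float)
            ok = ~(np.isnan(a) | np.isnan(b))
            n_pairs = int(ok.sum())
            if n_pairs < 3:
                continue
            rho = spearman_rho(a[ok], b[ok])
            if np.isnan(rho):
                continue
            rows.append((mid, st, rho, n_pairs,
                         bool(rho > threshold and n_pairs >= min_pairs)))
    return pd.DataFrame(rows, columns=["metabolite_id", "sample_type",
                                       "rho", "n_pairs", "passes"])


def connectivity_ranking(edges: pd.DataFrame) -> pd.DataFrame:
    """Rank metabolites by how many tissues they connect to via plasma.

    degree = number of distinct sample types with a passing edge; ties
    are broken by the metabolite's maximum rho, then lexicographically.
    Metabolites with no passing edge are omitted.
    """
    passing = edges[edges["passes"]]
    if passing.empty:
        return pd.DataFrame(columns=["metabolite_id", "degree",
                                     "linked_types", "max_rho"])
    grp = passing.groupby("metabolite_id")
    out = pd.DataFrame({
        "metabolite_id": grp.size().index,
        "degree": grp["sample_type"].nunique().to_numpy(),
        "linked_types": grp["sample_type"]
            .apply(lambda s: ";".join(sorted(set(s)))).to_numpy(),
        "max_rho": grp["rho"].max().to_numpy(),
    })
    out = out.sort_values(["degree", "max_rho", "metabolite_id"],
                          ascending=[False, False, True], kind="mergesort")
    return out.reset_index(drop=True)


def to_networkx(edges: pd.DataFrame):
    """Bipartite metabolite-tissue graph of the passing edges."""
    import networkx as nx

    g = nx.Graph()
    passing = edges[edges["passes"]]
    for row in passing.itertuples(index=False):
        g.add_node(row.metabolite_id, kind="metabolite")
        g.add_node(f"tissue:{row.sample_type}", kind="tissue")
        g.add_edge(row.metabolite_id, f"tissue:{row.sample_type}",
                   rho=float(row.rho), n_pairs=int(row.n_pairs))
    return g


def graph_tables(edges: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge lists of the passing network for external tools."""
    passing = edges[edges["passes"]].reset_index(drop=True)
    nodes = pd.concat([
        pd.DataFrame({"node": sorted(passing["metabolite_id"].unique()),
                      "kind": "metabolite"}),
        pd.DataFrame({"node": sorted(passing["sample_type"].unique()),
                      "kind": "tissue"}),
    ], ignore_index=True)
    edge_list = passing.rename(columns={"metabolite_id": "source",
                                        "sample_type": "target"})
    return nodes, edge_list[["source", "target", "rho", "n_pairs"]]
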