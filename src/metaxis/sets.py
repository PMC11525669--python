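"""Class-level aggregation and cross-tissue set intersections.

Significant-metabolite sets (one per sample type and model term) are
summarized two ways: averaged within biochemical classes (the lollipop /
stacked-bar summaries), and intersected across sample types with UpSet
"distinct" semantics, where every metabolite is assigned to exactly the
combination of sample types whose sets contain it.  A region overlap
(e.g. gut vs brain) is the intersection of the two regions' unions.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .datasets import BRAIN_SAMPLE_TYPES, GUT_SAMPLE_TYPES, ValidationError
from .models import TERM_EFFECT_COLUMN

__all__ = [
    "class_aggregate",
    "exclusive_intersections",
    "inclusive_intersections",
    "region_overlap",
    "membership_matrix",
    "intersection_table",
    "volcano_table",
    "top_interaction",
    "GUT_SAMPLE_TYPES",
    "BRAIN_SAMPLE_TYPES",
]


def class_aggregate(
    results: pd.DataFrame,
    sets: dict[tuple[str, str], set[str]],
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Average effect size of significant metabolites per biochemical class.

    For each (sample_type, term) set, members are grouped by class and
    the arithmetic mean of their log2 effect estimates (the term's
    conditional contrast, or the interaction coefficient) is reported
    with a direction: enriched (> 0), depleted (< 0) or balanced (== 0).
    Classes with no significant member are omitted.  An unannotated
    member is a hard error.
    """
    if "biochemical_class" not in annotations.columns:
        raise ValidationError("annotations lack a biochemical_class column")
    cls = annotations["biochemical_class"]
    rows = []
    for (st, term), members in sorted(sets.items()):
        if not members:
            continue
        col = TERM_EFFECT_COLUMN[term]
        sub = results[(results["sample_type"] == st)
                      & results["metabolite_id"].isin(members)]
        missing = set(sub["metabolite_id"]) - set(cls.index)
        if missing:
            raise ValidationError(
                f"metabolite(s) without class annotation: {sorted(missing)}")
        eff = sub.set_index("metabolite_id")[col]
        for c, grp in eff.groupby(cls.loc[eff.index]):
            mean = float(grp.mean())
            direction = ("enriched" if mean > 0
                         else "depleted" if mean < 0 else "balanced")
            rows.append((st, term, c, len(grp), mean, direction))
    return pd.DataFrame(rows, columns=["sample_type", "term",
                                       "biochemical_class", "n_members",
                                       "mean_effect", "direction"])


def exclusive_intersections(
    sets: dict[str, set[str]]
) -> dict[frozenset[str], set[str]]:
    """UpSet 'distinct' intersections over one term's per-sample-type sets.

    Each metabolite lands in exactly one combination: the set of sample
    types whose significance sets contain it.  Empty combinations are
    omitted, so the result partitions the union of all sets.
    """
    if not sets:
        raise ValidationError("need at least one significance set")
    out: dict[frozenset[str], set[str]] = {}
    universe = set().union(*sets.values())
    for m in universe:
        combo = frozenset(st for st, members in sets.items() if m in members)
        out.setdefault(combo, set()).add(m)
    return out


def inclusive_intersections(
    sets: dict[str, set[str]]
) -> dict[frozenset[str], set[str]]:
    """UpSet 'intersect' mode: every non-empty plain intersection over
    each combination of sample types (not a partition)."""
    if not sets:
        raise ValidationError("need at least one significance set")
    names = sorted(sets)
    out: dict[frozenset[str], set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inter = set.intersection(*(sets[c] for c in combo))
            if inter:
                out[frozenset(combo)] = inter
    return out


def region_overlap(
    sets: dict[tuple[str, str], set[str]],
    term: str,
    region_a: frozenset[str] | set[str],
    region_b: frozenset[str] | set[str],
) -> set[str]:
    """Metabolites significant for ``term`` somewhere in region A and
    somewhere in region B (regions must be disjoint sample-type sets)."""
    region_a, region_b = set(region_a), set(region_b)
    if region_a & region_b:
        raise ValidationError(
            f"regions overlap: {sorted(region_a & region_b)}")
    union_a = set().union(*(sets.get((st, term), set()) for st in region_a)) \
        if region_a else set()
    union_b = set().union(*(sets.get((st, term), set()) for st in region_b)) \
        if region_b else set()
    return union_a & union_b


def membership_matrix(sets: dict[str, set[str]]) -> pd.DataFrame:
    """UpSet-ready boolean matrix (rows = metabolites, cols = sample types)."""
    universe = sorted(set().union(*sets.values())) if sets else []
    cols = sorted(sets)
    data = {c: [m in sets[c] for m in universe] for c in cols}
    return pd.DataFrame(data, index=pd.Index(universe, name="metabolite_id"))


def intersection_table(parts: dict[frozenset[str], set[str]]) -> pd.DataFrame:
    """Tidy export of an intersection map, largest combinations first."""
    rows = [("|".join(sorted(combo)), len(members),
             ";".join(sorted(members)))
            for combo, members in parts.items()]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["sample_types", "n_metabolites",
                                       "metabolites"])


def volcano_table(results: pd.DataFrame, term: str) -> pd.DataFrame:
    """Per-metabolite effect estimate vs -log10 p for one term."""
    from .models import TERM_P_COLUMN
    if term not in TERM_P_COLUMN:
        raise ValidationError(f"unknown term {term!r}")
    p = results[TERM_P_COLUMN[term]].astype(float)
    out = pd.DataFrame({
        "metabolite_id": results["metabolite_id"],
        "sample_type": results["sample_type"],
        "estimate": results[TERM_EFFECT_COLUMN[term]].astype(float),
        "p": p,
        "neg_log10_p": -np.log10(p.clip(lower=np.finfo(float).tiny)),
    })
    return out.reset_index(drop=True)


def top_interaction(results: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """The k metabolites with the most significant interaction effect,
    ordered by ascending interaction p (ties broken by metabolite id)."""
    ordered = results.sort_values(["p_beta_GxM", "metabolite_id"],
                                  kind="mergesort")
    return ordered.head(k)[["metabolite_id", "sample_type", "beta_GxM",
                            "p_beta_GxM"]].reset_index(drop=True)
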