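"""Quality control: LOD-prevalence filtering, LOD/2 imputation, log2.

Filtering operates within a *material type* (plasma, GI tissue, gut
content, brain tissue), pooling its member sample types: a metabolite is
kept iff strictly more than 30% (by default) of its SPF measurements in
that material type lie strictly above the LOD.  Retention decided on SPF
animals is then applied to all samples (SPF and GF) of the material
type.  Censored cells are imputed at LOD/2 before log2 transformation.
No batch correction is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import (
    ConcentrationDataset,
    MATERIAL_TYPES,
    ValidationError,
    assign_material_type,
)

__all__ = [
    "assign_material_type",
    "lod_prevalence_report",
    "filter_by_lod_prevalence",
    "impute_lod",
    "log2_transform",
    "qc_pipeline",
]


def _above_lod_mask(ds: ConcentrationDataset) -> pd.DataFrame:
    """Boolean matrix: measurement strictly above its LOD.

    A censored flag marks <=LOD by construction.  Uncensored values are
    additionally compared against the annotated LOD when one is present
    (value == LOD does not count as above); with no LOD on record an
    uncensored measurement counts as above.
    """
    above = ~ds.censored
    if ds.annotations is not None and "lod" in ds.annotations.columns:
        lod = ds.annotations["lod"].reindex(ds.values.columns)
        has_lod = lod.notna()
        gt = ds.values.gt(lod, axis=1)
        above = above & (gt | ~has_lod)
    return above


def lod_prevalence_report(
    datasets: dict[str, ConcentrationDataset], threshold: float = 0.30
) -> pd.DataFrame:
    """Per (metabolite, material type): SPF above-LOD fraction and the
    retention verdict under the strict >threshold rule."""
    rows = []
    for material, members in MATERIAL_TYPES.items():
        present = [st for st in datasets if st in members]
        if not present:
            continue
        above_parts, n_spf = [], 0
        for st in present:
            ds = datasets[st]
            spf = ds.meta.index[ds.meta["microbiome"] == "SPF"]
            n_spf += len(spf)
            above_parts.append(_above_lod_mask(ds).loc[spf])
        if n_spf == 0:
            raise ValidationError(
                f"material type {material!r} has no SPF samples; "
                "LOD-prevalence filter is undefined")
        above = pd.concat(above_parts, axis=0)
        frac = above.mean(axis=0)
        for mid, f in frac.items():
            rows.append((mid, material, int(above[mid].sum()), len(above),
                         float(f), bool(f > threshold)))
    return pd.DataFrame(rows, columns=[
        "metabolite_id", "material_type", "n_above_lod", "n_spf_measurements",
        "spf_above_lod_fraction", "retained"])


def filter_by_lod_prevalence(
    datasets: dict[str, ConcentrationDataset], threshold: float = 0.30
) -> tuple[dict[str, ConcentrationDataset], pd.DataFrame]:
    """Drop metabolites at or below the SPF above-LOD prevalence threshold.

    Returns the filtered datasets (every sample type restricted to the
    metabolites retained for its material type) and the retention report.
    """
    if not 0 <= threshold < 1:
        raise ValidationError("threshold must be in [0, 1)")
    report = lod_prevalence_report(datasets, threshold)
    retained = {
        material: set(sub.loc[sub["retained"], "metabolite_id"])
        for material, sub in report.groupby("material_type")
    }
    out = {
        st: ds.subset_metabolites(retained.get(ds.material_type, set()))
        for st, ds in datasets.items()
    }
    return out, report


def impute_lod(ds: ConcentrationDataset) -> ConcentrationDataset:
    """Replace censored cells by LOD/2; censored flags are kept for audit.

    Every censored cell must have an annotated LOD; a missing LOD is a
    hard error naming the cell.
    """
    if ds.log2_scale:
        raise ValidationError("impute_lod expects concentrations in uM")
    if ds.annotations is None or "lod" not in ds.annotations.columns:
        raise ValidationError(
            f"{ds.sample_type}: no LOD annotations; cannot impute")
    out = ds.copy()
    lod = out.annotations["lod"].reindex(out.values.columns)
    cens = out.censored.to_numpy(bool)
    needs = cens.any(axis=0)
    missing = out.values.columns[needs & lod.isna().to_numpy()]
    if len(missing):
        mid = missing[0]
        sid = out.censored.index[out.censored[mid]][0]
        raise ValidationError(
            f"{ds.sample_type}: censored cell (sample {sid!r}, metabolite "
            f"{mid!r}) has no LOD on record")
    vals = out.values.to_numpy(float)
    fill = np.broadcast_to((lod / 2.0).to_numpy(float), vals.shape)
    out.values = pd.DataFrame(np.where(cens, fill, vals),
                              index=out.values.index,
                              columns=out.values.columns)
    return out


def log2_transform(ds: ConcentrationDataset) -> ConcentrationDataset:
    """Elementwise log2 of the concentration matrix (metadata untouched)."""
    if ds.log2_scale:
        raise ValidationError(f"{ds.sample_type}: already log2-transformed")
    vals = ds.values.to_numpy(float)
    if np.any(vals[~np.isnan(vals)] <= 0):
        i, j = np.argwhere(np.nan_to_num(vals, nan=1.0) <= 0)[0]
        raise ValidationError(
            f"{ds.sample_type}: non-positive value at sample "
            f"{ds.values.index[i]!r}, metabolite {ds.values.columns[j]!r}; "
            "impute before transforming")
    out = ds.copy()
    out.values = np.log2(ds.values)
    out.log2_scale = True
    return out


def qc_pipeline(
    datasets: dict[str, ConcentrationDataset], threshold: float = 0.30
) -> tuple[dict[str, ConcentrationDataset], pd.DataFrame]:
    """Filter -> impute -> log2 for every sample type.

    Returns the analysis-ready log2 datasets and the retention report.
    """
    filtered, report = filter_by_lod_prevalence(datasets, threshold)
    out = {st: log2_transform(impute_lod(ds)) for st, ds in filtered.items()}
    return out, report
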