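"""Core containers and study constants.

The experimental unit is a mouse (animal) in a 2x2 genotype x microbiome
design: wild-type (WT) or alpha-synuclein-overexpressing (ASO) animals,
raised specific-pathogen-free (SPF, conventional microbiome) or germ-free
(GF).  From each animal up to ten sample types are profiled on a targeted
metabolomics panel; concentrations are in micromolar and are left-censored
at a per-metabolite lower limit of detection (LOD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "ASO")
MICROBIOMES = ("SPF", "GF")

#: The ten profiled sample types.
SAMPLE_TYPES = (
    "plasma",
    "duodenal_contents",
    "cecal_contents",
    "colonic_contents",
    "duodenum",
    "colon",
    "brainstem",
    "cortex",
    "substantia_nigra",
    "striatum",
)

#: QC grouping: LOD-prevalence filtering is applied within these material
#: types, pooling their member sample types.
MATERIAL_TYPES: dict[str, frozenset[str]] = {
    "plasma": frozenset({"plasma"}),
    "gi_tissue": frozenset({"duodenum", "colon"}),
    "gut_content": frozenset(
        {"duodenal_contents", "cecal_contents", "colonic_contents"}
    ),
    "brain_tissue": frozenset(
        {"brainstem", "cortex", "substantia_nigra", "striatum"}
    ),
}

#: Sample types counted as "gut" / "brain" for cross-region overlaps.
GUT_SAMPLE_TYPES = frozenset(
    {"duodenum", "colon", "duodenal_contents", "cecal_contents", "colonic_contents"}
)
BRAIN_SAMPLE_TYPES = frozenset(
    {"brainstem", "cortex", "substantia_nigra", "striatum"}
)

META_COLUMNS = ("sample_id", "animal_id", "genotype", "microbiome",
                "sample_type", "body_weight")


class ValidationError(ValueError):
    """A dataset or metadata table violates a structural invariant."""


def assign_material_type(sample_type: str) -> str:
    """Map a sample type to its QC material type.

    plasma -> plasma; duodenum/colon -> gi_tissue; the three luminal
    contents -> gut_content; the four brain regions -> brain_tissue.
    """
    for name, members in MATERIAL_TYPES.items():
        if sample_type in members:
            return name
    raise ValidationError(f"unknown sample type: {sample_type!r}")


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table and return it indexed by sample_id.

    Enforces: required columns, unique sample ids, one sample per
    (animal, sample type), known factor levels, positive body weight.
    """
    if meta.index.name == "sample_id":
        meta = meta.reset_index() if "sample_id" not in meta.columns \
            else meta.reset_index(drop=True)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    dup = meta["sample_id"][meta["sample_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicated sample_id: {sorted(dup)}")
    pair_dup = meta[meta.duplicated(subset=["animal_id", "sample_type"], keep=False)]
    if len(pair_dup):
        raise ValidationError(
            "duplicated (animal_id, sample_type): "
            f"{sorted(map(tuple, pair_dup[['animal_id', 'sample_type']].values))}"
        )
    for col, levels in (("genotype", GENOTYPES), ("microbiome", MICROBIOMES),
                        ("sample_type", SAMPLE_TYPES)):
        bad = set(meta[col]) - set(levels)
        if bad:
            raise ValidationError(f"unknown {col} level(s): {sorted(bad)}")
    bw = pd.to_numeric(meta["body_weight"], errors="coerce")
    if bw.isna().any() or (bw <= 0).any():
        offenders = meta.loc[bw.isna() | (bw <= 0), "sample_id"].tolist()
        raise ValidationError(f"non-positive body_weight for samples {offenders}")
    out = meta.copy()
    out["body_weight"] = bw
    return out.set_index("sample_id", drop=False)


@dataclass
class ConcentrationDataset:
    """One sample type's concentration matrix with censoring information.

    Parameters
    ----------
    sample_type
        One of :data:`SAMPLE_TYPES`.
    values
        samples x metabolites matrix of concentrations in uM.  Censored
        cells read from disk hold NaN; synthetic datasets may keep the
        pre-censoring value there for auditing, but downstream analysis
        must only consume it through LOD/2 imputation.
    censored
        Boolean matrix, same shape/labels as ``values``; True marks a
        below-LOD measurement.
    meta
        Per-sample metadata (indexed by sample_id), aligned with the rows
        of ``values``.
    annotations
        Per-metabolite table with at least ``biochemical_class`` and
        ``lod`` (the LOD for this dataset's material type, uM); indexed by
        metabolite_id, aligned with the columns of ``values``.  May be
        None until annotations are attached.
    log2_scale
        True once :func:`metaxis.qc.log2_transform` has been applied.
    """

    sample_type: str
    values: pd.DataFrame
    censored: pd.DataFrame
    meta: pd.DataFrame
    annotations: pd.DataFrame | None = None
    log2_scale: bool = field(default=False)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def material_type(self) -> str:
        return assign_material_type(self.sample_type)

    @property
    def metabolites(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def validate(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValidationError(f"unknown sample type: {self.sample_type!r}")
        if self.values.shape != self.censored.shape:
            raise ValidationError("values and censored shapes differ")
        if not self.values.index.equals(self.censored.index) or \
           not self.values.columns.equals(self.censored.columns):
            raise ValidationError("values and censored labels differ")
        self.meta = validate_meta(self.meta)
        if not self.values.index.equals(self.meta.index):
            raise ValidationError("values rows do not match metadata sample ids")
        if (self.meta["sample_type"] != self.sample_type).any():
            bad = self.meta.loc[self.meta["sample_type"] != self.sample_type,
                                "sample_id"].tolist()
            raise ValidationError(
                f"samples {bad} have sample_type != {self.sample_type!r}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValidationError(f"duplicated metabolite column(s): {dups}")
        uncensored = self.values.to_numpy(dtype=float)[~self.censored.to_numpy(bool)]
        if not self.log2_scale and np.any(uncensored[~np.isnan(uncensored)] < 0):
            raise ValidationError("negative concentration in uncensored cells")
        if self.annotations is not None:
            ann = self.annotations
            if ann.index.name != "metabolite_id":
                if "metabolite_id" in ann.columns:
                    ann = ann.set_index("metabolite_id")
                    self.annotations = ann
                else:
                    raise ValidationError("annotations lack metabolite_id")
            if ann.index.duplicated().any():
                dups = ann.index[ann.index.duplicated()].tolist()
                raise ValidationError(f"duplicated annotation row(s): {dups}")
            missing = self.values.columns.difference(ann.index)
            if len(missing):
                raise ValidationError(
                    f"metabolites without annotation: {sorted(missing)}")
            if "lod" in ann.columns:
                lod = ann.loc[self.values.columns, "lod"]
                if ((lod <= 0) & lod.notna()).any():
                    bad = lod.index[(lod <= 0) & lod.notna()].tolist()
                    raise ValidationError(f"non-positive LOD for {bad}")

    def subset_metabolites(self, keep) -> "ConcentrationDataset":
        """Return a copy restricted to the given metabolite ids (order kept)."""
        keep = [m for m in self.values.columns if m in set(keep)]
        ann = None
        if self.annotations is not None:
            ann = self.annotations.loc[self.annotations.index.intersection(
                pd.Index(keep))].copy()
            ann.index.name = self.annotations.index.name
        return ConcentrationDataset(
            sample_type=self.sample_type,
            values=self.values[keep].copy(),
            censored=self.censored[keep].copy(),
            meta=self.meta.copy(),
            annotations=ann,
            log2_scale=self.log2_scale,
        )

    def copy(self) -> "ConcentrationDataset":
        return ConcentrationDataset(
            sample_type=self.sample_type,
            values=self.values.copy(),
            censored=self.censored.copy(),
            meta=self.meta.copy(),
            annotations=None if self.annotations is None else self.annotations.copy(),
            log2_scale=self.log2_scale,
        )
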