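"""Reading and writing the pipeline's tabular artifacts.

All files are comma-separated UTF-8 text with a decimal point.  The wide
concentration table has one row per sample (first column ``sample_id``)
and one column per metabolite; below-LOD cells carry the literal token
``<LOD`` (case-insensitive on read).  Floats are rendered with 12
significant digits so that write -> read -> write is byte-stable.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ConcentrationDataset, ValidationError, validate_meta

LOD_TOKEN = "<LOD"

ANNOTATION_COLUMNS = ("metabolite_id", "biochemical_class", "material_type", "lod")


def _fmt(x) -> str:
    if isinstance(x, (float, np.floating)):
        if np.isnan(x):
            return ""
        return format(float(x), ".12g")
    if isinstance(x, (bool, np.bool_)):
        return "True" if x else "False"
    if x is None:
        return ""
    return str(x)


def _write_frame(df: pd.DataFrame, path) -> None:
    buf = _io.StringIO()
    buf.write(",".join(map(str, df.columns)) + "\n")
    for row in df.itertuples(index=False):
        buf.write(",".join(_fmt(v) for v in row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_sample_metadata(path) -> pd.DataFrame:
    """Read and validate the shared sample-metadata CSV."""
    meta = pd.read_csv(path, dtype={"sample_id": str, "animal_id": str})
    return validate_meta(meta)


def write_sample_metadata(meta: pd.DataFrame, path) -> None:
    cols = ["sample_id", "animal_id", "genotype", "microbiome",
            "sample_type", "body_weight"]
    _write_frame(meta.reset_index(drop=True)[cols], path)


def read_annotations(path) -> pd.DataFrame:
    """Read the metabolite annotation CSV (one LOD row per metabolite x
    material type); returns a long-format frame."""
    ann = pd.read_csv(path, dtype={"metabolite_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValidationError(f"annotation file missing columns: {missing}")
    if ann.duplicated(subset=["metabolite_id", "material_type"]).any():
        dups = ann.loc[ann.duplicated(subset=["metabolite_id", "material_type"]),
                       "metabolite_id"].tolist()
        raise ValidationError(f"duplicated (metabolite, material_type) rows: {dups}")
    if (ann["lod"] <= 0).any():
        bad = ann.loc[ann["lod"] <= 0, "metabolite_id"].tolist()
        raise ValidationError(f"non-positive LOD for {bad}")
    return ann


def write_annotations(ann: pd.DataFrame, path) -> None:
    _write_frame(ann.reset_index(drop=True)[list(ANNOTATION_COLUMNS)], path)


def annotations_for_material(ann_long: pd.DataFrame, material_type: str) -> pd.DataFrame:
    """Slice the long annotation table down to one material type, indexed
    by metabolite_id with columns biochemical_class and lod."""
    sub = ann_long[ann_long["material_type"] == material_type]
    return sub.set_index("metabolite_id")[["biochemical_class", "lod"]].copy()


def read_concentration_table(path, meta_path, annotations_path=None,
                             log2_scale: bool = False) -> ConcentrationDataset:
    """Read one sample type's wide concentration CSV.

    The header row names the metabolites; the first column is
    ``sample_id``.  Cells equal to ``<LOD`` (any case) are flagged
    censored and hold NaN.  Every sample id must appear in the metadata
    file, and all rows must belong to a single sample type.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
    if not header or header[0] != "sample_id":
        raise ValidationError(
            f"{path}: first column must be 'sample_id', got "
            f"{header[0] if header else None!r}")
    seen: set[str] = set()
    for m in header[1:]:
        if m in seen:
            raise ValidationError(f"{path}: duplicated metabolite column {m!r}")
        seen.add(m)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw.columns = header  # undo pandas' dedup mangling, keep names verbatim
    met_cols = header[1:]
    sample_ids = raw["sample_id"].tolist()

    meta_all = read_sample_metadata(meta_path)
    missing = [s for s in sample_ids if s not in meta_all.index]
    if missing:
        raise ValidationError(
            f"{path}: sample(s) missing from metadata: {missing}")
    meta = meta_all.loc[sample_ids].copy()
    sample_types = meta["sample_type"].unique()
    if len(sample_types) != 1:
        raise ValidationError(
            f"{path}: rows span multiple sample types {sorted(sample_types)}")
    sample_type = sample_types[0]

    n, p = len(sample_ids), len(met_cols)
    values = np.full((n, p), np.nan)
    censored = np.zeros((n, p), dtype=bool)
    for j, m in enumerate(met_cols):
        col = raw[m]
        for i, cell in enumerate(col):
            token = cell.strip()
            if token.upper() == LOD_TOKEN.upper():
                censored[i, j] = True
                continue
            try:
                values[i, j] = float(token)
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric cell at row {i + 2} (sample "
                    f"{sample_ids[i]!r}), column {m!r}: {cell!r}") from None

    ann = None
    if annotations_path is not None:
        from .datasets import assign_material_type
        ann_long = read_annotations(annotations_path)
        ann = annotations_for_material(ann_long, assign_material_type(sample_type))

    return ConcentrationDataset(
        sample_type=sample_type,
        values=pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"),
                            columns=met_cols),
        censored=pd.DataFrame(censored, index=pd.Index(sample_ids, name="sample_id"),
                              columns=met_cols),
        meta=meta,
        annotations=ann,
        log2_scale=log2_scale,
    )


def write_concentration_table(ds: ConcentrationDataset, path) -> None:
    """Write the wide concentration CSV.

    Raw (uM-scale) datasets render censored cells as the ``<LOD`` token,
    so a below-LOD measurement never leaks a number to disk.  Log2-scale
    datasets are analysis-ready (already imputed) and are written dense,
    values included.
    """
    use_token = not ds.log2_scale
    buf = _io.StringIO()
    buf.write(",".join(["sample_id"] + list(map(str, ds.values.columns))) + "\n")
    vals = ds.values.to_numpy(dtype=float)
    cens = ds.censored.to_numpy(dtype=bool)
    for i, sid in enumerate(ds.values.index):
        cells = [str(sid)]
        for j in range(vals.shape[1]):
            cells.append(LOD_TOKEN if (use_token and cens[i, j])
                         else _fmt(vals[i, j]))
        buf.write(",".join(cells) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def write_results_table(results: pd.DataFrame, path) -> None:
    """Write a tidy results table (model fits, edges, class summaries,
    intersections...) as CSV with a stable column order and 12-significant-
    digit floats.  Two writes of the same object are byte-identical."""
    if not isinstance(results, pd.DataFrame):
        raise TypeError("results must be a pandas DataFrame")
    _write_frame(results.reset_index(drop=True), path)


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
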