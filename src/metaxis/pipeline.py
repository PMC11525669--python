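"""End-to-end orchestration: simulate -> qc -> model -> permanova -> sets
-> network, with per-stage seed substreams and a checksum manifest.

Every run writes its outputs under one directory, plus a
``manifest.json`` recording the configuration hash, the global seed, the
per-stage substream seeds and a sha256 checksum per file — rerunning
with the same configuration reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io, qc, sets as sets_mod, simulate
from .datasets import BRAIN_SAMPLE_TYPES, GUT_SAMPLE_TYPES, ValidationError, \
    assign_material_type
from .models import classify_significance, fit_dataset
from .multivariate import permanova_all
from .network import connectivity_ranking, graph_tables, \
    plasma_anchor_correlations

log = logging.getLogger("metaxis")

STAGES = ("simulate", "qc", "model", "permanova", "sets", "network")


@dataclass
class PipelineConfig:
    """All tunable constants of a run (defaults follow the analysis plan:
    alpha 0.05, LOD prevalence 0.30, rho threshold 0.75, 10,000
    permutations)."""

    outdir: str = "metaxis_run"
    seed: int | None = None
    alpha: float = 0.05
    lod_threshold: float = 0.30
    rho_threshold: float = 0.75
    min_pairs: int = 5
    n_permutations: int = 10_000
    significance_mode: str = "strict"
    n_metabolites: int = 630

    def validate(self) -> None:
        if self.seed is None:
            raise ValidationError("seed must be set explicitly")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 <= self.lod_threshold < 1:
            raise ValidationError("lod_threshold must be in [0, 1)")
        if not -1 < self.rho_threshold < 1:
            raise ValidationError("rho_threshold must be in (-1, 1)")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.significance_mode not in ("strict", "inclusive"):
            raise ValidationError("significance_mode must be strict|inclusive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage substream seed (< 2**31) from the global
    seed by hashing the stage name."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages on a synthetic study; returns the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        io.write_results_table(df, path)
        written.append(path)

    # -- simulate ----------------------------------------------------------
    sim_seed = stage_seed(config.seed, "simulate")
    datasets, scenario = simulate.simulate_study(
        seed=sim_seed, n_metabolites=config.n_metabolites)
    meta = pd.concat([ds.meta for ds in datasets.values()],
                     ignore_index=True)
    meta_path = outdir / "sample_metadata.csv"
    io.write_sample_metadata(meta, meta_path)
    written.append(meta_path)
    ann_rows = []
    for st, ds in datasets.items():
        material = assign_material_type(st)
        if not any(r[2] == material for r in ann_rows):
            for mid, row in ds.annotations.iterrows():
                ann_rows.append((mid, row["biochemical_class"], material,
                                 row["lod"]))
    ann_long = pd.DataFrame(ann_rows, columns=io.ANNOTATION_COLUMNS)
    ann_path = outdir / "metabolite_annotations.csv"
    io.write_annotations(ann_long, ann_path)
    written.append(ann_path)
    for st, ds in datasets.items():
        path = outdir / f"concentrations_{st}.csv"
        io.write_concentration_table(ds, path)
        written.append(path)
    log.info("simulate: %d sample types, %d samples, %d metabolites",
             len(datasets), len(meta), config.n_metabolites)

    # -- qc ----------------------------------------------------------------
    log2_datasets, report = qc.qc_pipeline(datasets, config.lod_threshold)
    emit(report, "qc_retention.csv")
    n_in = sum(ds.values.size for ds in datasets.values())
    n_out = sum(ds.values.size for ds in log2_datasets.values())
    log.info("qc: %d cells in, %d cells retained", n_in, n_out)

    # -- model -------------------------------------------------------------
    results = pd.concat([fit_dataset(ds) for ds in log2_datasets.values()],
                        ignore_index=True)
    emit(results, "model_results.csv")
    log.info("model: %d fits", len(results))

    # -- permanova ---------------------------------------------------------
    perm = permanova_all(log2_datasets, n_perm=config.n_permutations,
                         seed=stage_seed(config.seed, "permanova"))
    emit(perm, "permanova.csv")
    log.info("permanova: %d sample types x %d permutations",
             len(log2_datasets), config.n_permutations)

    # -- sets --------------------------------------------------------------
    sig = classify_significance(results, alpha=config.alpha,
                                mode=config.significance_mode)
    cls = ann_long.drop_duplicates("metabolite_id").set_index("metabolite_id")
    summary = sets_mod.class_aggregate(results, sig, cls)
    emit(summary, "class_summary.csv")
    for term in ("genotype", "microbiome", "interaction"):
        per_type = {st: members for (st, t), members in sig.items()
                    if t == term and members}
        if per_type:
            parts = sets_mod.exclusive_intersections(per_type)
            emit(sets_mod.intersection_table(parts),
                 f"intersections_{term}.csv")
            emit(sets_mod.membership_matrix(per_type).reset_index(),
                 f"upset_membership_{term}.csv")
    overlap = sets_mod.region_overlap(sig, "interaction",
                                      GUT_SAMPLE_TYPES, BRAIN_SAMPLE_TYPES)
    emit(pd.DataFrame({"metabolite_id": sorted(overlap)}),
         "gut_brain_interaction_overlap.csv")
    emit(sets_mod.volcano_table(results, "interaction"),
         "volcano_interaction.csv")
    log.info("sets: %d significant sets, gut-brain overlap %d",
             sum(bool(v) for v in sig.values()), len(overlap))

    # -- network -----------------------------------------------------------
    edges = plasma_anchor_correlations(log2_datasets,
                                       threshold=config.rho_threshold,
                                       min_pairs=config.min_pairs)
    emit(edges, "correlation_edges.csv")
    ranking = connectivity_ranking(edges)
    emit(ranking, "connectivity.csv")
    nodes, edge_list = graph_tables(edges)
    emit(nodes, "network_nodes.csv")
    emit(edge_list, "network_edges.csv")
    log.info("network: %d edges, %d passing", len(edges),
             int(edges["passes"].sum()))

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "files": {p.name: _sha256(p) for p in written},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
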