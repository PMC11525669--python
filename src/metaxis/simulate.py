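"""Synthetic multi-tissue metabolomics data with known ground truth.

The generator is the inverse of the analysis model: for each metabolite
and sample type, log2 concentration is

    baseline + bG*[ASO] + bM*[SPF] + bI*[ASO & SPF]
             + bW*(body weight - mean body weight)
             + loading * animal_factor + Normal(0, sigma)

where the animal factor is a latent Normal(0, factor_sd) draw shared by
all of one animal's tissues — the mechanism by which a molecule that
circulates from gut to brain produces strong cross-tissue rank
correlations.  Concentrations are stored as 2**log2 in uM, then
left-censored at a per-metabolite, per-material-type LOD placed at a
chosen quantile of the simulated values.

The default study design is a 2x2 genotype x microbiome layout with
n = 5 WT-SPF, 6 ASO-SPF, 6 WT-GF and 6 ASO-GF animals, ten sample types,
and a 630-metabolite panel spanning 26 biochemical classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import (
    ConcentrationDataset,
    MATERIAL_TYPES,
    SAMPLE_TYPES,
    ValidationError,
    assign_material_type,
)

DEFAULT_GROUP_SIZES = {
    ("WT", "SPF"): 5,
    ("ASO", "SPF"): 6,
    ("WT", "GF"): 6,
    ("ASO", "GF"): 6,
}

# 4-month mouse body weights (g): modest ASO deficit, slight GF elevation.
DEFAULT_BODY_WEIGHT = {
    ("WT", "SPF"): (30.0, 2.0),
    ("ASO", "SPF"): (28.0, 2.0),
    ("WT", "GF"): (31.0, 2.0),
    ("ASO", "GF"): (29.0, 2.0),
}

#: The 26 biochemical classes of the targeted panel.
BIOCHEMICAL_CLASSES = (
    "alkaloids", "amine oxides", "amino acids", "amino acid related",
    "bile acids", "biogenic amines", "carboxylic acids", "cresols",
    "fatty acids", "hormones", "indoles and derivatives",
    "nucleobases and related", "vitamins and cofactors", "acylcarnitines",
    "lysophosphatidylcholines", "phosphatidylcholines", "sphingomyelins",
    "ceramides", "dihydroceramides", "hexosylceramides",
    "dihexosylceramides", "trihexosylceramides", "cholesteryl esters",
    "diglycerides", "triglycerides", "hexoses",
)


@dataclass
class EffectSpec:
    """Generative coefficients for one (metabolite, sample type) cell.

    All betas are in log2-uM units (bW per gram); sigma is the residual
    SD on the log2 scale.
    """

    metabolite_id: str
    sample_type: str
    baseline: float
    beta_genotype: float = 0.0
    beta_microbiome: float = 0.0
    beta_interaction: float = 0.0
    beta_bodyweight: float = 0.0
    sigma: float = 0.5
    biochemical_class: str = "amino acids"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError(f"{self.metabolite_id}: sigma must be >= 0")
        if self.sample_type not in SAMPLE_TYPES:
            raise ValidationError(
                f"{self.metabolite_id}: unknown sample type {self.sample_type!r}")


@dataclass
class LatentFactorSpec:
    """Animal-level latent factor planting cross-tissue correlation.

    Each animal draws one factor value ~ Normal(0, factor_sd); the
    metabolite's log2 level in sample type ``t`` gains
    ``loading[t] * factor``.
    """

    metabolite_id: str
    loading: dict[str, float]
    factor_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.factor_sd <= 0:
            raise ValidationError(f"{self.metabolite_id}: factor_sd must be > 0")
        nonzero = [t for t, w in self.loading.items() if w != 0]
        if len(nonzero) < 2:
            raise ValidationError(
                f"{self.metabolite_id}: latent factor needs >= 2 sample types "
                "with nonzero loading")
        unknown = set(self.loading) - set(SAMPLE_TYPES)
        if unknown:
            raise ValidationError(
                f"{self.metabolite_id}: unknown sample types {sorted(unknown)}")


@dataclass
class DesignSpec:
    """Study layout: group sizes, sampled sites, body-weight distributions."""

    group_sizes: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    sample_types: tuple[str, ...] = SAMPLE_TYPES
    body_weight: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BODY_WEIGHT))
    lod_quantile: float = 0.10
    brain_dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValidationError("all group sizes must be >= 2")
        if not 0 <= self.lod_quantile < 1:
            raise ValidationError("lod_quantile must be in [0, 1)")
        if not 0 <= self.brain_dropout < 1:
            raise ValidationError("brain_dropout must be in [0, 1)")
        unknown = set(self.sample_types) - set(SAMPLE_TYPES)
        if unknown:
            raise ValidationError(f"unknown sample types {sorted(unknown)}")


def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """Realize the design: one metadata row per (animal, sample type).

    Body weights are drawn per group from a normal truncated at zero
    (redrawn if non-positive).  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for (genotype, microbiome), n in spec.group_sizes.items():
        mean, sd = spec.body_weight[(genotype, microbiome)]
        for k in range(n):
            animal = f"{genotype}-{microbiome}-{k + 1:02d}"
            bw = rng.normal(mean, sd)
            while bw <= 0:
                bw = rng.normal(mean, sd)
            for st in spec.sample_types:
                if spec.brain_dropout and assign_material_type(st) == "brain_tissue":
                    if rng.random() < spec.brain_dropout:
                        continue
                rows.append((f"{animal}_{st}", animal, genotype, microbiome,
                             st, bw))
    return pd.DataFrame(rows, columns=["sample_id", "animal_id", "genotype",
                                       "microbiome", "sample_type",
                                       "body_weight"])


def simulate_concentrations(
    design: pd.DataFrame,
    effects: list[EffectSpec],
    factors: list[LatentFactorSpec] | None = None,
    seed: int = 0,
) -> dict[str, ConcentrationDataset]:
    """Simulate one ConcentrationDataset per sample type in the design.

    Every (metabolite, sample type) cell present in the design must have
    an EffectSpec; a missing cell is a hard error.  Censoring flags start
    all-False; apply :func:`apply_lod_censoring` afterwards.
    """
    factors = factors or []
    rng = np.random.default_rng(seed)
    lookup: dict[tuple[str, str], EffectSpec] = {}
    metabolites: list[str] = []
    for e in effects:
        key = (e.metabolite_id, e.sample_type)
        if key in lookup:
            raise ValidationError(f"duplicate EffectSpec for {key}")
        lookup[key] = e
        if e.metabolite_id not in metabolites:
            metabolites.append(e.metabolite_id)

    sample_types = [st for st in SAMPLE_TYPES
                    if st in set(design["sample_type"])]
    for st in sample_types:
        for m in metabolites:
            if (m, st) not in lookup:
                raise ValidationError(
                    f"missing EffectSpec for metabolite {m!r} in {st!r}")

    animals = design.drop_duplicates("animal_id").set_index("animal_id")
    bw_centered = animals["body_weight"] - animals["body_weight"].mean()
    # one factor draw per (factor, animal), shared across tissues
    factor_draws = {
        f.metabolite_id: pd.Series(
            rng.normal(0.0, f.factor_sd, size=len(animals)),
            index=animals.index)
        for f in factors
    }
    factor_by_metabolite = {f.metabolite_id: f for f in factors}

    out: dict[str, ConcentrationDataset] = {}
    for st in sample_types:
        sub = design[design["sample_type"] == st].copy()
        n = len(sub)
        g = (sub["genotype"] == "ASO").to_numpy(float)
        m_ = (sub["microbiome"] == "SPF").to_numpy(float)
        bw = bw_centered.loc[sub["animal_id"]].to_numpy(float)
        log2 = np.empty((n, len(metabolites)))
        classes = []
        for j, mid in enumerate(metabolites):
            e = lookup[(mid, st)]
            classes.append(e.biochemical_class)
            mu = (e.baseline + e.beta_genotype * g + e.beta_microbiome * m_
                  + e.beta_interaction * g * m_ + e.beta_bodyweight * bw)
            if mid in factor_by_metabolite:
                w = factor_by_metabolite[mid].loading.get(st, 0.0)
                if w:
                    mu = mu + w * factor_draws[mid].loc[sub["animal_id"]].to_numpy()
            noise = rng.normal(0.0, e.sigma, size=n) if e.sigma > 0 else 0.0
            log2[:, j] = mu + noise
        idx = pd.Index(sub["sample_id"], name="sample_id")
        cols = pd.Index(metabolites, name="metabolite_id")
        ann = pd.DataFrame({"biochemical_class": classes, "lod": np.nan},
                           index=cols)
        out[st] = ConcentrationDataset(
            sample_type=st,
            values=pd.DataFrame(np.exp2(log2), index=idx, columns=cols),
            censored=pd.DataFrame(False, index=idx, columns=cols),
            meta=sub,
            annotations=ann,
        )
    return out


def apply_lod_censoring(
    datasets: dict[str, ConcentrationDataset],
    lod_quantile,
) -> dict[str, ConcentrationDataset]:
    """Left-censor at a per-metabolite, per-material-type LOD.

    The LOD is placed at the ``lod_quantile`` quantile of the simulated
    values pooled over the material type's member sample types; values
    strictly below it are flagged censored.  The stored value is retained
    for auditing (it must only reach analysis via LOD/2 imputation).
    Annotations gain the LOD.  ``lod_quantile = 0`` censors nothing.

    ``lod_quantile`` may be a scalar (one quantile for everything), or a
    mapping ``{material_type: scalar | Series indexed by metabolite_id}``
    to emulate assays where detectability differs by metabolite and
    matrix.
    """
    out = {st: ds.copy() for st, ds in datasets.items()}
    for material, members in MATERIAL_TYPES.items():
        present = [st for st in out if st in members]
        if not present:
            continue
        pooled = pd.concat([out[st].values for st in present], axis=0)
        q = lod_quantile.get(material, 0.0) if isinstance(lod_quantile, dict) \
            else lod_quantile
        if np.isscalar(q):
            q = pd.Series(float(q), index=pooled.columns)
        else:
            q = pd.Series(q, dtype=float).reindex(pooled.columns).fillna(0.0)
        if ((q < 0) | (q >= 1)).any():
            raise ValidationError("lod_quantile values must be in [0, 1)")
        arr = pooled.to_numpy(float)
        lod = pd.Series(
            [np.quantile(arr[:, j], q.iloc[j]) for j in range(arr.shape[1])],
            index=pooled.columns)
        lod = lod.clip(lower=np.nextafter(0, 1))
        for st in present:
            ds = out[st]
            ds.censored = ds.values.lt(lod, axis=1)
            if ds.annotations is not None:
                ds.annotations = ds.annotations.copy()
                ds.annotations["lod"] = lod.reindex(ds.annotations.index)
    return out


# ---------------------------------------------------------------------------
# Default study-scale scenario


@dataclass
class Scenario:
    """A complete generative configuration plus its planted ground truth."""

    design: DesignSpec
    effects: list[EffectSpec]
    factors: list[LatentFactorSpec]
    #: optional per-material, per-metabolite censoring quantiles; falls
    #: back to ``design.lod_quantile`` when None
    lod_quantiles: dict | None = None
    #: metabolites planted with a genotype x microbiome interaction in at
    #: least one gut and one brain sample type
    gut_brain_interaction: tuple[str, ...] = ()
    #: metabolite planted as the most plasma-connected (latent factor)
    anchor_metabolite: str | None = None


def default_scenario(seed: int = 0, n_metabolites: int = 630) -> Scenario:
    """Build the study-scale scenario: a 630-metabolite panel over 26
    classes with sparse genotype/microbiome/interaction effects, three
    planted gut-and-brain interaction metabolites (taurine and two
    glycerides), and a TMAO-like amine oxide tied across plasma, gut and
    brain by an animal-level latent factor.

    The scenario is deterministic given ``seed``; ``n_metabolites`` may
    be reduced for quick runs (planted metabolites are always included).
    """
    if n_metabolites < 10:
        raise ValidationError("n_metabolites must be >= 10")
    rng = np.random.default_rng(seed)

    planted = {
        "TMAO": "amine oxides",
        "taurine": "amino acid related",
        "TG(16:0_40:7)": "triglycerides",
        "DG(14:1_18:1)": "diglycerides",
    }
    names = list(planted)
    classes = list(planted.values())
    for k in range(n_metabolites - len(planted)):
        cls = BIOCHEMICAL_CLASSES[k % len(BIOCHEMICAL_CLASSES)]
        names.append(f"met_{k + 1:04d}")
        classes.append(cls)

    effects: list[EffectSpec] = []
    gut_brain_sites = {
        "taurine": ("colon", "striatum"),
        "TG(16:0_40:7)": ("duodenum", "cortex"),
        "DG(14:1_18:1)": ("colonic_contents", "brainstem"),
    }
    for mid, cls in zip(names, classes):
        for st in SAMPLE_TYPES:
            baseline = rng.normal(4.0, 2.0)
            sigma = rng.uniform(0.3, 0.8)
            bG = bM = bI = 0.0
            bW = 0.0
            if mid == "TMAO":
                # microbially produced: strongly SPF-elevated everywhere
                bM = 2.5
                sigma = 0.4
            elif mid in gut_brain_sites:
                if st in gut_brain_sites[mid]:
                    bI = 2.0 if mid != "DG(14:1_18:1)" else -2.0
                    sigma = 0.5
            else:
                u = rng.random()
                scale = rng.uniform(0.6, 1.8) * rng.choice((-1.0, 1.0))
                if u < 0.08:
                    bG = scale
                elif u < 0.23:
                    bM = scale
                elif u < 0.28:
                    bI = scale
                if rng.random() < 0.10:
                    bW = rng.normal(0.0, 0.02)
            effects.append(EffectSpec(
                metabolite_id=mid, sample_type=st, baseline=baseline,
                beta_genotype=bG, beta_microbiome=bM, beta_interaction=bI,
                beta_bodyweight=bW, sigma=sigma, biochemical_class=cls))

    anchor_sites = ("duodenal_contents", "cecal_contents", "colonic_contents",
                    "duodenum", "colon", "cortex")
    factors = [LatentFactorSpec(
        metabolite_id="TMAO",
        loading={"plasma": 1.0, **{st: 1.0 for st in anchor_sites}},
        factor_sd=1.5,
    )]

    # Heterogeneous detectability: each metabolite is either well detected
    # (censoring quantile ~ U(0, 0.2)) or poorly detected (~ U(0.75, 0.95))
    # in a matrix; brain tissue has the largest poorly-detected share,
    # matching how lipid-rich neural matrices suppress ionization.
    poor_share = {"plasma": 0.12, "gi_tissue": 0.25,
                  "gut_content": 0.18, "brain_tissue": 0.50}
    mets = pd.Index(names, name="metabolite_id")
    lod_quantiles: dict[str, pd.Series] = {}
    for material, share in poor_share.items():
        poor = rng.random(len(mets)) < share
        q = np.where(poor, rng.uniform(0.75, 0.95, len(mets)),
                     rng.uniform(0.0, 0.20, len(mets)))
        q[:len(planted)] = 0.02  # planted metabolites stay well detected
        lod_quantiles[material] = pd.Series(q, index=mets)

    return Scenario(
        design=DesignSpec(seed=seed),
        effects=effects,
        factors=factors,
        lod_quantiles=lod_quantiles,
        gut_brain_interaction=tuple(gut_brain_sites),
        anchor_metabolite="TMAO",
    )


def simulate_study(
    seed: int = 0, n_metabolites: int = 630, scenario: Scenario | None = None
) -> tuple[dict[str, ConcentrationDataset], Scenario]:
    """Convenience wrapper: design -> concentrations -> LOD censoring."""
    scenario = scenario or default_scenario(seed, n_metabolites)
    design = generate_design(scenario.design)
    datasets = simulate_concentrations(design, scenario.effects,
                                       scenario.factors, seed=seed + 1)
    q = scenario.lod_quantiles if scenario.lod_quantiles is not None \
        else scenario.design.lod_quantile
    datasets = apply_lod_censoring(datasets, q)
    return datasets, scenario
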