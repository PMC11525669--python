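import numpy as np
import pandas as pd
import pytest

import metaxis as mx
from metaxis.datasets import ValidationError
from metaxis.simulate import DesignSpec, EffectSpec, LatentFactorSpec

from conftest import balanced_meta


def test_default_design_has_23_animals_and_230_samples(design_meta):
    assert design_meta["animal_id"].nunique() == 23
    assert len(design_meta) == 230
    counts = design_meta.drop_duplicates("animal_id") \
        .groupby(["genotype", "microbiome"]).size()
    assert counts[("WT", "SPF")] == 5
    assert counts[("ASO", "SPF")] == 6
    assert counts[("WT", "GF")] == 6
    assert counts[("ASO", "GF")] == 6


def test_single_sample_type_gives_one_sample_per_animal():
    meta = mx.generate_design(DesignSpec(sample_types=("plasma",), seed=1))
    assert len(meta) == meta["animal_id"].nunique() == 23


def test_design_is_deterministic_given_seed():
    a = mx.generate_design(DesignSpec(seed=5))
    b = mx.generate_design(DesignSpec(seed=5))
    c = mx.generate_design(DesignSpec(seed=6))
    assert a.equals(b)
    assert not a["body_weight"].equals(c["body_weight"])


def test_body_weights_positive(design_meta):
    assert (design_meta["body_weight"] > 0).all()


def test_zero_betas_zero_sigma_gives_constant_matrix(single_effect):
    meta = balanced_meta(3)
    ds = mx.simulate_concentrations(meta, single_effect(), seed=0)["plasma"]
    assert np.allclose(ds.values.to_numpy(), 2.0 ** 3.0)


def test_genotype_beta_of_2_gives_fourfold_raw_ratio(single_effect):
    meta = balanced_meta(3)
    effects = single_effect(beta_genotype=2.0)
    ds = mx.simulate_concentrations(meta, effects, seed=0)["plasma"]
    spf = ds.meta["microbiome"] == "SPF"
    aso = ds.meta["genotype"] == "ASO"
    ratio = ds.values.loc[(spf & aso).to_numpy(), "met"].mean() / \
        ds.values.loc[(spf & ~aso).to_numpy(), "met"].mean()
    assert ratio == pytest.approx(4.0)


def test_interaction_recovered_at_large_n():
    """OLS consistency: with 200 animals per cell the planted interaction
    coefficient is recovered within +-0.1."""
    meta = balanced_meta(200, seed=2)
    effects = [EffectSpec("met", "plasma", baseline=2.0, beta_genotype=0.3,
                          beta_microbiome=-0.4, beta_interaction=1.0,
                          sigma=0.5)]
    ds = mx.simulate_concentrations(meta, effects, seed=4)["plasma"]
    fit = mx.fit_metabolite_model(np.log2(ds.values["met"]), ds.meta)
    assert fit.coefficients["beta_GxM"] == pytest.approx(1.0, abs=0.1)


def test_simulation_deterministic_and_seed_sensitive(single_effect):
    meta = balanced_meta(3)
    effects = single_effect(sigma=0.5)
    a = mx.simulate_concentrations(meta, effects, seed=9)["plasma"]
    b = mx.simulate_concentrations(meta, effects, seed=9)["plasma"]
    c = mx.simulate_concentrations(meta, effects, seed=10)["plasma"]
    assert a.values.equals(b.values)
    assert not a.values.equals(c.values)


def test_missing_effect_spec_is_hard_error(single_effect):
    meta = balanced_meta(2)
    meta2 = meta.copy()
    meta2["sample_type"] = "colon"
    meta2["sample_id"] = meta2["sample_id"] + "_c"
    both = pd.concat([meta, meta2], ignore_index=True)
    with pytest.raises(ValidationError, match="colon"):
        mx.simulate_concentrations(both, single_effect("plasma"), seed=0)


def test_latent_factor_requires_two_loaded_sample_types():
    with pytest.raises(ValidationError):
        LatentFactorSpec("met", {"plasma": 1.0})


def test_lod_quantile_zero_censors_nothing(single_effect):
    meta = balanced_meta(4)
    ds = mx.simulate_concentrations(meta, single_effect(sigma=0.7), seed=1)
    out = mx.apply_lod_censoring(ds, 0.0)
    assert out["plasma"].censored.to_numpy().sum() == 0


def test_median_lod_censors_about_half():
    """lod_quantile = 0.5 on a continuous simulation censors a fraction
    in [0.35, 0.65] per metabolite (n = 69 gut-content measurements)."""
    spec = DesignSpec(sample_types=("duodenal_contents", "cecal_contents",
                                    "colonic_contents"), seed=2)
    meta = mx.generate_design(spec)
    effects = [EffectSpec("met", st, baseline=2.0, sigma=0.8)
               for st in spec.sample_types]
    ds = mx.simulate_concentrations(meta, effects, seed=3)
    out = mx.apply_lod_censoring(ds, 0.5)
    frac = np.mean([out[st].censored["met"].mean()
                    for st in spec.sample_types])
    assert 0.35 <= frac <= 0.65


def test_censoring_then_filtering_drops_exactly_low_prevalence(small_study):
    datasets, _ = small_study
    report = mx.lod_prevalence_report(datasets, threshold=0.30)
    _, filt_report = mx.filter_by_lod_prevalence(datasets, threshold=0.30)
    expected_drop = set(report.loc[report["spf_above_lod_fraction"] <= 0.30,
                                   ["metabolite_id", "material_type"]]
                        .itertuples(index=False))
    actual_drop = set(filt_report.loc[~filt_report["retained"],
                                      ["metabolite_id", "material_type"]]
                      .itertuples(index=False))
    assert expected_drop == actual_drop


def test_planted_factor_induces_strong_plasma_correlation():
    """A metabolite loading on plasma + 2 other sites with factor_sd >>
    sigma shows rho > 0.75 plasma-anchored edges to those sites."""
    spec = DesignSpec(sample_types=("plasma", "colon", "striatum"), seed=4)
    meta = mx.generate_design(spec)
    effects = [EffectSpec("met", st, baseline=2.0, sigma=0.3)
               for st in spec.sample_types]
    factors = [LatentFactorSpec("met", {st: 1.0 for st in spec.sample_types},
                                factor_sd=1.5)]
    ds = mx.simulate_concentrations(meta, effects, factors, seed=5)
    log2 = {st: mx.log2_transform(d) for st, d in ds.items()}
    edges = mx.plasma_anchor_correlations(log2)
    assert edges["passes"].all()
    assert set(edges["sample_type"]) == {"colon", "striatum"}


def test_group_size_below_two_rejected():
    with pytest.raises(ValidationError):
        DesignSpec(group_sizes={("WT", "SPF"): 1, ("ASO", "SPF"): 6,
                                ("WT", "GF"): 6, ("ASO", "GF"): 6})


def test_brain_dropout_removes_only_brain_samples():
    spec = DesignSpec(seed=8, brain_dropout=0.3)
    meta = mx.generate_design(spec)
    full = mx.generate_design(DesignSpec(seed=8))
    non_brain = meta[~meta["sample_type"].isin(mx.BRAIN_SAMPLE_TYPES)]
    assert len(non_brain) == 23 * 6
    assert len(meta) < len(full)
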