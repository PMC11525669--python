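import numpy as np
import pandas as pd
import pytest

import metaxis as mx
from metaxis.simulate import DesignSpec, EffectSpec


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study (40 metabolites, full design) shared by
    read-only tests."""
    return mx.simulate_study(seed=11, n_metabolites=40)


@pytest.fixture(scope="session")
def log2_study(small_study):
    datasets, _ = small_study
    log2, report = mx.qc_pipeline(datasets)
    return log2, report


@pytest.fixture()
def design_meta():
    return mx.generate_design(DesignSpec(seed=3))


def make_plasma_dataset(values, censored=None, lods=None, n_spf=None,
                        classes=None):
    """Hand-build a plasma ConcentrationDataset from a values matrix.

    Rows alternate SPF/GF unless n_spf is given (first n_spf rows SPF).
    """
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if n_spf is None:
        n_spf = n // 2
    mets = [f"m{j}" for j in range(p)]
    sample_ids = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "animal_id": [f"a{i}" for i in range(n)],
        "genotype": ["ASO" if i % 2 else "WT" for i in range(n)],
        "microbiome": ["SPF" if i < n_spf else "GF" for i in range(n)],
        "sample_type": "plasma",
        "body_weight": np.linspace(25, 32, n),
    })
    cens = np.zeros((n, p), dtype=bool) if censored is None \
        else np.asarray(censored, dtype=bool)
    ann = pd.DataFrame({
        "biochemical_class": classes if classes is not None
        else ["amino acids"] * p,
        "lod": lods if lods is not None else [1.0] * p,
    }, index=pd.Index(mets, name="metabolite_id"))
    return mx.ConcentrationDataset(
        sample_type="plasma",
        values=pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"),
                            columns=mets),
        censored=pd.DataFrame(cens, index=pd.Index(sample_ids, name="sample_id"),
                              columns=mets),
        meta=meta,
        annotations=ann,
    )


def balanced_meta(n_per_cell: int, sample_type: str = "plasma",
                  seed: int = 0) -> pd.DataFrame:
    """Metadata for a balanced 2x2 design with varying body weights."""
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for g in ("WT", "ASO"):
        for m in ("SPF", "GF"):
            for _ in range(n_per_cell):
                rows.append((f"s{i}", f"a{i}", g, m, sample_type,
                             float(rng.normal(29, 2))))
                i += 1
    return pd.DataFrame(rows, columns=["sample_id", "animal_id", "genotype",
                                       "microbiome", "sample_type",
                                       "body_weight"])


@pytest.fixture()
def single_effect():
    def _make(sample_type="plasma", **kw):
        kw.setdefault("baseline", 3.0)
        kw.setdefault("sigma", 0.0)
        return [EffectSpec(metabolite_id="met", sample_type=sample_type, **kw)]
    return _make
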