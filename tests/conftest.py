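import numpy as np
import pandas as pd
import pytest

from prsphewas.genio import GenotypeMatrix, VariantRecord, WeightSet
from prsphewas.synthetic_data import SimConfig, gen_annotation, gen_genotypes, gen_phenotypes, gen_weights


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_genotypes() -> GenotypeMatrix:
    variants = [
        VariantRecord("v1", "1", 100, "A", "G"),
        VariantRecord("v2", "1", 200, "C", "T"),
        VariantRecord("v3", "2", 300, "G", "C"),
    ]
    dosages = np.array(
        [
            [0.0, 1.0, 2.0],
            [1.0, np.nan, 0.0],
            [2.0, 1.0, 1.0],
            [1.0, 0.0, 2.0],
        ]
    )
    return GenotypeMatrix(samples=["s1", "s2", "s3", "s4"], variants=variants, dosages=dosages)


@pytest.fixture
def tiny_weights() -> WeightSet:
    return WeightSet(
        "toy",
        pd.DataFrame(
            {
                "variant_id": ["v1", "v2", "v3"],
                "chrom": ["1", "1", "2"],
                "pos": [100, 200, 300],
                "effect_allele": ["A", "C", "G"],
                "other_allele": ["G", "T", "C"],
                "weight": [0.5, -0.25, 1.0],
            }
        ),
    )


@pytest.fixture(scope="session")
def sim_bundle():
    """A mid-size deterministic simulation shared across test modules."""
    cfg = SimConfig(
        n_samples=800,
        n_variants=150,
        target_r2=0.05,
        weight_sparsity=0.3,
        missing_rate=0.01,
        ages=(16.0, 20.0, 24.0),
        n_null_phenotypes=6,
        planted_pathway="planted",
        seed=321,
    )
    genes, pathways = gen_annotation(cfg)
    g = gen_genotypes(cfg, genes)
    w = gen_weights(cfg, g, genes, pathways)
    pt, truth = gen_phenotypes(g, w, cfg)
    return {"cfg": cfg, "genes": genes, "pathways": pathways, "g": g, "w": w, "pt": pt, "truth": truth}
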