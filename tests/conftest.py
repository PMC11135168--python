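import numpy as np
import pytest

from radpath.io import DoseClass, ExpressionMatrix, GeneSetCollection, SampleAnnotation, assign_dose_class
from radpath.simulate import SyntheticConfig, default_responsive_ids, generate_dataset, generate_gene_sets


@pytest.fixture
def tiny_matrix():
    """4 genes x 6 samples with a clear shift in g1/g2 for the last 3 samples."""
    rng = np.random.default_rng(42)
    values = rng.normal(5.0, 1.0, size=(4, 6))
    values[0, 3:] += 3.0
    values[1, 3:] += 3.0
    return ExpressionMatrix(
        gene_ids=("g1", "g2", "g3", "g4"),
        sample_ids=tuple(f"s{i}" for i in range(6)),
        values=values,
    )


@pytest.fixture
def tiny_annotations():
    doses = [0.0, 0.0, 0.0, 0.05, 0.05, 0.05]
    return [
        assign_dose_class(SampleAnnotation(f"s{i}", f"d{i % 2}", dose))
        for i, dose in enumerate(doses)
    ]


@pytest.fixture
def tiny_gene_sets():
    gs = GeneSetCollection()
    gs.add("pwA", "responsive", ["g1", "g2"])
    gs.add("pwB", "background", ["g3", "g4"])
    return gs


def make_study(n_genes=400, n_pathways=20, n_low=2, n_high=2, effect_size=1.5,
               seed=0, **kwargs):
    """Synthetic study with planted low-/high-responsive pathways."""
    low, high = default_responsive_ids(n_pathways, n_low, n_high)
    cfg = SyntheticConfig(
        n_genes=n_genes, n_pathways=n_pathways, pathway_size_range=(10, 30),
        low_responsive_pathways=low, high_responsive_pathways=high,
        effect_size=effect_size, seed=seed, **kwargs,
    )
    gs = generate_gene_sets(cfg)
    m, ann, truth = generate_dataset(cfg, gs)
    return cfg, gs, m, ann, truth


@pytest.fixture
def small_study():
    return make_study()
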