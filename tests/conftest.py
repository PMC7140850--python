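import numpy as np
import pytest

from mediseq.features import Feature, FeatureModel
from mediseq.simulate import SimConfig, make_truth, simulate_genome, simulate_reads


@pytest.fixture
def small_config():
    """Tiny but complete simulation: fast enough for every unit test."""
    return SimConfig(
        seed=13,
        n_genes=30,
        n_pairs=3,
        frac_de=0.2,
        frac_down=0.0,  # tiny gene count: the scaled down-gene band is sparse
        true_log2fc=2.0,
        exon_length=150,
        expr_median=25.0,
        de_expression_range=(15.0, 60.0),
        mirna_frac=0.5,
        dup_rate=1.5,
    )


@pytest.fixture
def small_dataset(small_config):
    genome, annotation = simulate_genome(small_config)
    truth = make_truth(annotation, small_config)
    reads = simulate_reads(genome, annotation, truth, small_config)
    return genome, annotation, truth, reads


@pytest.fixture
def toy_model():
    """Hand-built feature model: one gene with an intronic miRNA on a
    400 nt contig (exon1 50-150, intron 150-250 with miRNA 180-220,
    exon2 250-350)."""
    features = [
        Feature("g1.exon1", "g1", "exon", "chrT", 50, 150),
        Feature("g1.intron1", "g1", "intron", "chrT", 150, 250),
        Feature("mir-g1", "mir-g1", "miRNA", "chrT", 180, 220),
        Feature("g1.exon2", "g1", "exon", "chrT", 250, 350),
    ]
    return FeatureModel(features, {"chrT": 400})


@pytest.fixture
def rng():
    return np.random.default_rng(0)
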