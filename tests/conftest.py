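import numpy as np
import pytest

from binquant.io import BestHit, Lineage
from binquant.simulate import SimConfig, generate_community


def make_hit(lineage="Bacteria;Terrabacteria;Firmicutes", gene="g1", ident=90.0,
             evalue=1e-30, cov=80.0, subject="s1"):
    return BestHit(gene_id=gene, subject_id=subject,
                   lineage=Lineage.from_string(lineage),
                   pct_identity=ident, evalue=evalue, query_coverage=cov)


@pytest.fixture(scope="session")
def clean_dataset(tmp_path_factory):
    """Noise-free default-size community: planted truth must be recovered exactly."""
    outdir = tmp_path_factory.mktemp("clean_sim")
    config = SimConfig(seed=11, taxonomy_noise=0.0, annotation_consistency=1.0)
    truth = generate_community(config, outdir)
    return config, outdir, truth


@pytest.fixture(scope="session")
def noisy_dataset(tmp_path_factory):
    """Default (noisy) community for statistical recovery checks."""
    outdir = tmp_path_factory.mktemp("noisy_sim")
    config = SimConfig(seed=23)
    truth = generate_community(config, outdir)
    return config, outdir, truth


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled community for loops over many seeds."""
    def factory(seed):
        return SimConfig(
            seed=seed, n_bins=12, genes_per_bin=(30, 45),
            otu_richness=60, otu_reads=4000, genes_per_class=4,
        )
    return factory


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
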