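import numpy as np
import pytest

from mosaicstage.core import Site, TissueSample, VariantObservation
from mosaicstage.selection import CodingModel
from mosaicstage.synthetic import CohortConfig, generate_gene_models, simulate_cohort


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig(n_individuals=10, seed=1)


@pytest.fixture(scope="session")
def small_cohort(default_config):
    return simulate_cohort(default_config)


@pytest.fixture(scope="session")
def gene_models():
    genes, pli, refs = generate_gene_models(CohortConfig(seed=0))
    return genes, pli, refs


@pytest.fixture(scope="session")
def coding_model(gene_models):
    genes, _, _ = gene_models
    return CodingModel(genes)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_tissue(individual, tissue_id, organ, observations=None, age=50.0, is_tumor=False):
    return TissueSample(
        individual=individual,
        tissue_id=tissue_id,
        organ=organ,
        age=age,
        is_tumor=is_tumor,
        observations=observations or {},
    )


def make_obs(site, tissue_id, depth, alt, f1r2=None):
    if f1r2 is None:
        f1r2 = alt // 2
    return VariantObservation(
        site=site,
        tissue_id=tissue_id,
        depth=depth,
        alt_count=alt,
        alt_f1r2=f1r2,
        alt_f2r1=alt - f1r2,
    )


@pytest.fixture()
def site():
    return Site("chr1", 1_500_000, "C", "T")
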