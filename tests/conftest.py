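import pytest

from cisprior import datasets
from cisprior.synthetic_data import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def reference_bundle():
    """Pipeline inputs derived from the bundled prioritized-SNP table."""
    leads, ld_pairs, annotations, gene_map = datasets.prioritized_input_bundle()
    return {
        "leads": leads,
        "ld_pairs": ld_pairs,
        "annotations": annotations,
        "gene_map": gene_map,
    }


@pytest.fixture(scope="session")
def disease_ld_tables():
    return datasets.load_disease_ld_tables()


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort reused by read-only tests."""
    return generate_cohort(CohortSpec(n_loci=40, proxies_per_locus_mean=10.0, seed=11))
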