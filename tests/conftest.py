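import warnings

import pytest

from txcontext.synthetic import case_fixtures, simulate_bundle, simulate_genome


@pytest.fixture(scope="session")
def fixtures():
    """Hand-crafted case-example fixtures (shared genome)."""
    return case_fixtures()


@pytest.fixture(scope="session")
def small_genome():
    """A 10-gene synthetic genome with planted divergence motifs."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_genome(n_genes=10, seed=1)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """A compact end-to-end input bundle on disk."""
    out = tmp_path_factory.mktemp("bundle")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        truth = simulate_bundle(
            out,
            seed=11,
            n_genes=60,
            n_variants=250,
            n_tissues=6,
            samples_per_tissue=12,
            planted_expression_fraction=0.2,
            n_pathways=8,
            n_diseases=4,
            network_nodes=600,
        )
    return out, truth
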