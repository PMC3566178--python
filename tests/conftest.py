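import pytest

from complexcat import GoDag, SyntheticConfig, make_bundle


@pytest.fixture(scope="session")
def chain_dag():
    """T is_a P is_a R, the single-path hand-propagation case."""
    return GoDag([("T", "P", "is_a"), ("P", "R", "is_a")])


@pytest.fixture(scope="session")
def diamond_dag():
    """T reaches the root R through two parents P1 and P2."""
    return GoDag(
        [
            ("T", "P1", "is_a"),
            ("T", "P2", "is_a"),
            ("P1", "R", "is_a"),
            ("P2", "R", "is_a"),
        ]
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic bundle shared by pipeline-level tests."""
    return make_bundle(
        SyntheticConfig(
            seed=7,
            n_terms=60,
            n_genes=250,
            n_true_complexes=25,
            n_drugs=60,
            n_ddis=60,
        )
    )
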