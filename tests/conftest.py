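import pytest

from virotriage import CommunitySpec, generate_community


@pytest.fixture(scope="session")
def small_spec():
    """A small paired community: 4 samples, 60+80 contigs, ARGs present."""
    return CommunitySpec(
        seed=7,
        n_samples=4,
        n_virome_contigs=60,
        n_microbiome_contigs=80,
        depth=150_000,
        arg_rate_bacterial=2.0,
        arg_rate_viral=0.5,
    )


@pytest.fixture(scope="session")
def small_community(small_spec):
    return generate_community(small_spec)
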