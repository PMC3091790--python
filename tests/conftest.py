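import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_pair_scenario():
    """The simulator's default two-genome scenario (100 orthologs at 40-90%
    identity, 20 unique genes each side, 3 rearrangement blocks) with its
    ortholog pairing — shared across tests because the all-vs-all alignment
    is the expensive step."""
    from usskit.screen import pair_orthologs
    from usskit.simulate import simulate_genome_pair

    (genes_a, prots_a), (genes_b, prots_b), truth = simulate_genome_pair(
        seed=20090901
    )
    pairs = pair_orthologs(genes_a, prots_a, genes_b, prots_b)
    return (genes_a, prots_a), (genes_b, prots_b), truth, pairs


@pytest.fixture(scope="session")
def planted_genome():
    """100-kb simulated genome with 50 forward + 50 reverse planted USS1
    cores, plus its truth table."""
    from usskit.simulate import simulate_genome

    return simulate_genome(
        length_bp=100_000, gc=0.45, n_forward=50, n_reverse=50,
        core="USS1", seed=42,
    )
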