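import pytest

from ribodevtyper import synthetic, synthetic_refs


@pytest.fixture(scope="session")
def curated_pairs():
    """The synthetic zebrafish-like 5.8S/18S/28S reference pairs."""
    return synthetic_refs.build_reference_pairs()


@pytest.fixture(scope="session")
def small_pair():
    """A small two-domain 18S-like pair with planted covariations and an indel."""
    return synthetic.make_type_pair(
        base_length=400,
        domain_spec=[("A", 1, 200), ("B", 201, 400)],
        per_domain_rates={"A": 0.03, "B": 0.08},
        n_covariations=2,
        indel_spec=[("ins", 120, "CTGA"), ("del", 320, 3)],
        seed=1234,
    )
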