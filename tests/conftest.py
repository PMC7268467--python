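import pytest

from pgxchain import (
    ChallengeContract,
    FastQueryContract,
    GeneratorConfig,
    Observation,
    Outcome,
)


@pytest.fixture
def example_observation() -> Observation:
    """The worked example used throughout the docs: CYP3A5 variant 52 with
    pegloticase, outcome unchanged, suspected relation and serious side
    effect both true."""
    return Observation(
        gene="CYP3A5",
        variant=52,
        drug="pegloticase",
        outcome=Outcome.UNCHANGED,
        suspected_relation=True,
        serious_side_effect=True,
    )


@pytest.fixture
def small_cfg() -> GeneratorConfig:
    """Tiny pools (5 genes x 4 variants x 3 drugs) so duplicates and query
    hits are frequent at desk scale."""
    return GeneratorConfig(
        n_observations=200, n_genes=5, n_variants=4, n_drugs=3, seed=11
    )


@pytest.fixture(params=["challenge", "fastquery"])
def any_contract(request):
    cls = {"challenge": ChallengeContract, "fastquery": FastQueryContract}[
        request.param
    ]
    return cls()
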