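import pytest

from fragsmiles import GeneratorConfig, gen_molecules, gen_reactions


@pytest.fixture(scope="session")
def small_corpus() -> list[str]:
    """60 generated molecules, mixed ring/stereo content."""
    return gen_molecules(GeneratorConfig(n=60, seed=42))


@pytest.fixture(scope="session")
def reaction_fixtures():
    """(records, ground-truth stereo tags) from the template generator."""
    return gen_reactions(GeneratorConfig(n=60, seed=7))
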