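import pytest

from multigate.fixtures import FixtureConfig, generate_toy_genome, generate_toy_kit
from multigate.grammar import load_overhang_tables
from multigate.seqcore import load_enzymes


@pytest.fixture(scope="session")
def enzymes():
    return load_enzymes()


@pytest.fixture(scope="session")
def tables():
    return load_overhang_tables()


@pytest.fixture(scope="session")
def config():
    return FixtureConfig(seed=17)


@pytest.fixture(scope="session")
def toy_genome(config):
    return generate_toy_genome(config)


@pytest.fixture(scope="session")
def toy_kit(config, toy_genome):
    return generate_toy_kit(config, toy_genome)


@pytest.fixture()
def spacer_chain(toy_kit):
    """Prebuilt spacer cassettes for an n-TU assembly (positions 1..n)."""

    def chain(n):
        pool = toy_kit.by_category("spacer")
        out = []
        for pos in range(1, n + 1):
            terminal = pos == n
            out.append(next(e for e in pool
                            if e.metadata["position"] == pos
                            and e.metadata["terminal"] == terminal))
        return out

    return chain
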