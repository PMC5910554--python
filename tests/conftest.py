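import random

import pytest

from pepdig import load_builtin_rules, make_fixture_db, random_proteome

STANDARD = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def ruleset():
    return load_builtin_rules()


@pytest.fixture(scope="session")
def trypsin(ruleset):
    return ruleset.get("trypsin")


@pytest.fixture(scope="session")
def fixture_db():
    return make_fixture_db(seed=42)


@pytest.fixture(scope="session")
def small_proteome():
    return random_proteome(60, length_mean=120, length_sd=30, seed=42)


@pytest.fixture()
def rng():
    return random.Random(20240901)


def random_sequence(rng, min_len=2, max_len=60, alphabet=STANDARD):
    n = rng.randint(min_len, max_len)
    return "".join(rng.choice(alphabet) for _ in range(n))
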