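import numpy as np
import pytest

from peplib.proteome_io import ProteinRecord
from peplib.synthetic_fixtures import default_spec, generate_evidence, generate_proteome

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def two_parent_proteome():
    """TESTR occurs in both proteins; flanks are unique."""
    return [
        ProteinRecord("P1", "first toy", "AAAKTESTRCCC"),
        ProteinRecord("P2", "second toy", "GGGKTESTRDDD"),
    ]


@pytest.fixture(scope="session")
def fixture_spec():
    return default_spec(seed=11)


@pytest.fixture(scope="session")
def fixture_proteome(fixture_spec):
    proteome, truth = generate_proteome(fixture_spec)
    return proteome, truth


@pytest.fixture(scope="session")
def fixture_evidence(fixture_spec, fixture_proteome):
    proteome, _ = fixture_proteome
    return generate_evidence(fixture_spec, proteome)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))
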