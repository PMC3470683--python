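import numpy as np
import pytest

from permutome import io as pio


@pytest.fixture(scope="session")
def table3_probes():
    """The two packaged probe cDNA sequences (arachin h1, desaturase)."""
    return pio.load_table3_probes()


@pytest.fixture(scope="session")
def table2_profiles():
    """The ten packaged fatty-acid composition profiles, keyed by treatment."""
    return {p.treatment: p for p in pio.load_table2_profiles()}


@pytest.fixture(scope="session")
def printed_metrics():
    return pio.load_printed_metrics()


@pytest.fixture(scope="session")
def manifest():
    return pio.load_manifest()


@pytest.fixture(scope="session")
def derived_states():
    return pio.load_derived_states()


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
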