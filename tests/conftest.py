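import pytest

from markerkit.io import load_enzyme_table
from markerkit.simulate import SimSpec, generate

SMALL_SSRS = (
    ("AG", 7), ("AC", 6), ("AT", 8), ("AAG", 5), ("ATC", 6),
    ("AAC", 5), ("AAAG", 5), ("AAAAG", 5), ("AAGGCC", 5), ("AG", 9),
)


@pytest.fixture(scope="session")
def enzymes():
    return load_enzyme_table()


@pytest.fixture(scope="session")
def enzyme_map(enzymes):
    return {e.name: e for e in enzymes}


@pytest.fixture(scope="session")
def small_spec():
    return SimSpec(
        seed=11,
        n_transcripts=40,
        min_length=1500,
        max_length=2500,
        planted_ssrs=SMALL_SSRS,
        planted_caps=("EcoRI", "SacI", "AluI", "HincII", "DdeI"),
    )


@pytest.fixture(scope="session")
def small_panel(small_spec):
    return generate(small_spec)
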