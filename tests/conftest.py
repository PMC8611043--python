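import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def trio_pedigree():
    """Father, mother, child; child affected."""
    from eoefam.pedigree import AFFECTED, Individual, Pedigree

    return Pedigree(
        "T1",
        [
            Individual("T1_FA", sex="male"),
            Individual("T1_MO", sex="female"),
            Individual("T1_C", father_id="T1_FA", mother_id="T1_MO", affection=AFFECTED),
        ],
    )
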