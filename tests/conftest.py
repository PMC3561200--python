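import pytest

from irgdose import StrategyAssignment, pralimap_programme


@pytest.fixture(scope="session")
def pralimap():
    """The 24-setting x 3-strategy study configuration, 2 periods."""
    return pralimap_programme()


@pytest.fixture()
def toy_assignment():
    """Three settings, two interventions: intervention 1 active in settings
    1-2, intervention 2 active in setting 3 (6 IRGs: 3 active, 3 control)."""
    return StrategyAssignment.from_active_sets(
        settings=("s1", "s2", "s3"),
        interventions=("int1", "int2"),
        active={"int1": ["s1", "s2"], "int2": ["s3"]},
    )
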