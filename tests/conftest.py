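import pytest
from hypothesis import HealthCheck, settings

from arborsim.params import default_species_table, species_index, validate_composition

# reproducible property tests regardless of where the suite runs
settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def species_table():
    return default_species_table()


@pytest.fixture(scope="session")
def species_map(species_table):
    return species_index(species_table)


@pytest.fixture()
def base_composition():
    """The study site: 112 Zelkova, 70 Prunus, 0 Pinus, 26 other."""
    return validate_composition(
        {
            "zelkova_serrata": 112,
            "prunus_yedoensis": 70,
            "pinus_densiflora": 0,
            "other": 26,
        }
    )
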