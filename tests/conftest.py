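import pytest

from macroniche import (
    FIXTURE_NAMES,
    bundled_diet,
    bundled_food_profiles,
    mix_diet,
)


@pytest.fixture(scope="session")
def diets():
    return {name: bundled_diet(name) for name in FIXTURE_NAMES}


@pytest.fixture(scope="session")
def profiles():
    return {name: bundled_food_profiles(name) for name in FIXTURE_NAMES}


@pytest.fixture(scope="session")
def diet_points(diets, profiles):
    return {
        name: mix_diet(diets[name], profiles[name]) for name in FIXTURE_NAMES
    }
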