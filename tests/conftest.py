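import dataclasses

import pytest

from micronova.core import load_rni_table, load_thresholds
from micronova.synth import generate_items, load_generator_params


@pytest.fixture(scope="session")
def rni_female():
    return load_rni_table(sex="female")


@pytest.fixture(scope="session")
def rni_male():
    return load_rni_table(sex="male")


@pytest.fixture(scope="session")
def thresholds():
    return load_thresholds()


@pytest.fixture(scope="session")
def default_params():
    return load_generator_params()


@pytest.fixture(scope="session")
def databank(default_params):
    """Default synthetic databank at the reference scale (2980 items, seed 1)."""
    return generate_items(default_params, seed=1)


def resize_groups(params, sizes: dict[str, int], zero_energy: int | None = None):
    """Copy of generator params with new group sizes (helper for big/small runs)."""
    groups = {}
    for name, gp in params.groups.items():
        changes: dict = {"n": sizes.get(name, gp.n)}
        if zero_energy is not None:
            changes["zero_energy"] = zero_energy
        groups[name] = dataclasses.replace(gp, **changes)
    return dataclasses.replace(params, groups=groups)
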