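import numpy as np
import pytest

from rangeshift.grids import EnvGrid, EnvStack, GridSpec
from rangeshift.synthetic import ScenarioParams, VirtualSpecies, make_env_scenario


@pytest.fixture(scope="session")
def small_spec() -> GridSpec:
    """An 8x8 half-degree grid used by the brute-force oracles."""
    return GridSpec(50.0, 54.0, 0.0, 4.0, 0.5)


@pytest.fixture(scope="session")
def noise_free_scenario():
    """Deterministic shelf-sea baseline/future stacks with zero SST noise."""
    return make_env_scenario(ScenarioParams(noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def virtual_species() -> VirtualSpecies:
    """A species whose preferred SST band sits mid-gradient in the scenario."""
    return VirtualSpecies(
        name="virt_test",
        true_envelope={"sst": (6.5, 8.0, 10.5, 12.0), "sbt": (6.0, 7.5, 10.0, 11.5)},
    )


def stack_from_arrays(spec: GridSpec, label: str = "1985", **fields) -> EnvStack:
    """Build an EnvStack from plain 2-D arrays (test helper)."""
    layers = {
        name: EnvGrid(spec=spec, variable=name, values=np.asarray(vals, dtype=float))
        for name, vals in fields.items()
    }
    return EnvStack(period_label=label, layers=layers)
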