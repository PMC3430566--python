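import pytest

from gemflux.synth import SyntheticSpec, make_toy_phototroph, toy_conditions


@pytest.fixture(scope="session")
def toy():
    """The toy phototroph and its analytic ground truth."""
    return make_toy_phototroph(0)


@pytest.fixture(scope="session")
def trophic_conditions():
    return toy_conditions()


@pytest.fixture(scope="session")
def small_specs():
    """Small random-network specs (≤8 reactions) for oracle comparisons."""
    specs = []
    for seed in range(6):
        specs.append(SyntheticSpec(seed=seed, n_metabolites=5, n_reactions=6, gpr_style="simple"))
        specs.append(
            SyntheticSpec(
                seed=seed + 100,
                n_metabolites=5,
                n_reactions=7,
                features=frozenset({"parallel_paths"}),
            )
        )
    return specs
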