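import pytest

import twignet as tn


@pytest.fixture(scope="session")
def design():
    return tn.wild_apple_design()


@pytest.fixture(scope="session")
def low_noise_params():
    return tn.GeneratorParams().with_noise(0.02, 0.02, 0.05)


@pytest.fixture(scope="session")
def twig_table(design, low_noise_params):
    return tn.simulate_experiment(design, low_noise_params, seed=20)


@pytest.fixture(scope="session")
def plot_table(twig_table):
    return tn.aggregate_plots(twig_table)
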