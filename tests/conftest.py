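import pytest

from mixtox import load_library, paper_like_scenario, simulate_depletion


@pytest.fixture(scope="session")
def library():
    return load_library()


@pytest.fixture(scope="session")
def scenario():
    return paper_like_scenario("1uM", seed=11)


@pytest.fixture(scope="session")
def suspension_timecourse(scenario):
    design = scenario.designs["suspension"]
    return simulate_depletion(design, scenario.true_k["suspension"], scenario.mixture_level_um)
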