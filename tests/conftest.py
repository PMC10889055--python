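import pytest

from caism.synthetic_data import (
    answer_key, default_scenario, make_annotator, make_genome, make_haplotypes,
)


@pytest.fixture(scope="session")
def scenario():
    return default_scenario(seed=7)


@pytest.fixture(scope="session")
def genome(scenario):
    return make_genome(scenario)


@pytest.fixture(scope="session")
def annot(scenario):
    return make_annotator(scenario)


@pytest.fixture(scope="session")
def haplotypes(scenario):
    return make_haplotypes(scenario)


@pytest.fixture(scope="session")
def key(scenario):
    return answer_key(scenario)


@pytest.fixture(scope="session")
def variants_by_id(scenario):
    return {v.id: v for v in scenario.variants}


@pytest.fixture(scope="session")
def scenario_dir(tmp_path_factory, scenario):
    """All scenario inputs written to disk once per session."""
    from caism.synthetic_data import write_scenario

    return write_scenario(scenario, tmp_path_factory.mktemp("sim"))
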