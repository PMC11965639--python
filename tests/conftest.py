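import pytest

from recip.pipeline import RunConfig, RunContext
from recip.synthetic_data import ScenarioParams, generate_scenario


@pytest.fixture(scope="session")
def scenario(tmp_path_factory):
    """A default synthetic study, generated once per session."""
    out = tmp_path_factory.mktemp("scenario")
    files, truth = generate_scenario(ScenarioParams(seed=7), out)
    return files, truth


@pytest.fixture(scope="session")
def scenario_ctx(scenario):
    """Loaded run context for the default scenario."""
    files, truth = scenario
    return RunContext(RunConfig.for_scenario_dir(files.out_dir)), truth
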