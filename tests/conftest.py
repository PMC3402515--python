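import logging

import pytest

from casenoncase import RunConfig, margins_fixture, run_primary, run_scenarios

logging.getLogger("casenoncase").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def fixture_ds():
    return margins_fixture()


@pytest.fixture(scope="session")
def primary_run(fixture_ds):
    cfg = RunConfig()
    return cfg, run_primary(cfg, fixture_ds)


@pytest.fixture(scope="session")
def scenario_results(fixture_ds, primary_run):
    cfg, primary = primary_run
    return {s.name: s for s in run_scenarios(cfg, primary, fixture_ds)}
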