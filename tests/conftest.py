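import pytest

from radsex import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def zw_run(tmp_path_factory):
    """The standard ZW demonstration cross, run once per session."""
    outdir = tmp_path_factory.mktemp("zw_run")
    return run_pipeline(RunConfig(seed=17, outdir=str(outdir)))


@pytest.fixture(scope="session")
def xy_run(tmp_path_factory):
    """The identical cross simulated under male heterogamety."""
    outdir = tmp_path_factory.mktemp("xy_run")
    return run_pipeline(RunConfig(seed=17, outdir=str(outdir), sex_system="XY"))
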