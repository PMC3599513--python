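import pytest

from lineagescan.cohort import CohortConfig, classify_cohort, generate_cohort
from lineagescan.pipeline import RunConfig, make_demo, run_pipeline


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (planted-homolog self-test enabled)."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def cohort_calls(default_cohort):
    """Conservation calls from the homology cascade on the default cohort."""
    return classify_cohort(default_cohort)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """A written demo workspace and the report of a full pipeline run."""
    workdir = tmp_path_factory.mktemp("demo")
    cfg_path = make_demo(1, workdir)
    report = run_pipeline(RunConfig.from_yaml(cfg_path))
    return workdir, report
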