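import hypothesis
import pytest

from eestoich.synth import GeneratorConfig, generate_cohort, write_fixture

hypothesis.settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=50
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """The 30-site two-region survey under default calibration, seed 0."""
    return generate_cohort(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A complete on-disk fixture (samples, OTU tables, configs), seed 0."""
    out = tmp_path_factory.mktemp("fixture")
    write_fixture(GeneratorConfig(seed=0), out)
    return out
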