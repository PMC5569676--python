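import pytest
from hypothesis import settings

from intramir import simulate

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """The default synthetic study: toy genome, reads, expression, truth."""
    out = tmp_path_factory.mktemp("study")
    manifest = simulate.generate(simulate.FixtureSpec(seed=7), str(out))
    return out, manifest


@pytest.fixture(scope="session")
def study_files(study):
    out, manifest = study
    return {k: str(out / v) for k, v in manifest["files"].items()}


@pytest.fixture(scope="session")
def study_manifest(study):
    return study[1]
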