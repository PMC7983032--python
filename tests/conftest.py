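import pytest

from crosstalk_kb import build_knowledgebase, generate_knowledgebase

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A complete synthetic knowledge base plus its ground-truth manifest."""
    base = tmp_path_factory.mktemp("kbfix")
    manifest = generate_knowledgebase(FIXTURE_SEED, base)
    return base, manifest


@pytest.fixture(scope="session")
def kb(fixture_dir):
    base, _ = fixture_dir
    return build_knowledgebase(base)


@pytest.fixture(scope="session")
def manifest(fixture_dir):
    return fixture_dir[1]
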