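import pytest

import fermbalance as fb


@pytest.fixture(scope="session")
def registry():
    return fb.default_registry()


@pytest.fixture(scope="session")
def cultures():
    return fb.builtin_cultures()


@pytest.fixture(scope="session")
def nets(cultures):
    return {cid: fb.net_changes(ds) for cid, ds in cultures.items()}


@pytest.fixture(scope="session")
def rhamnose_pathway(registry):
    return fb.builtin_pathway("rhamnose", registry)


@pytest.fixture(scope="session")
def glucose_pathway(registry):
    return fb.builtin_pathway("glucose", registry)
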