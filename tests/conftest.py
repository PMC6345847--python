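import importlib.util
import pathlib

import numpy as np
import pytest

REPO_ROOT = pathlib.Path(__file__).resolve().parents[1]


@pytest.fixture(scope="session")
def acceptance_module():
    """The acceptance script, importable so tests reuse its experiments."""
    spec = importlib.util.spec_from_file_location(
        "acceptance_script", REPO_ROOT / "scripts" / "acceptance.py"
    )
    module = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(module)
    return module


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
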