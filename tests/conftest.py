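import copy
from pathlib import Path

import pytest
import yaml

from clarid.codebook import (
    bundled_codebook_path,
    load_codebook,
    load_icd10,
)

DATA_DIR = Path(__file__).resolve().parents[1] / "src" / "clarid" / "data"


@pytest.fixture(scope="session")
def cb():
    return load_codebook()


@pytest.fixture(scope="session")
def icd10():
    return load_icd10()


@pytest.fixture(scope="session")
def codebook_doc():
    """The bundled codebook as a raw dict, for mutation-based tests."""
    return yaml.safe_load(bundled_codebook_path().read_text(encoding="utf-8"))


@pytest.fixture
def write_codebook(tmp_path):
    """Write a (possibly mutated) codebook dict to a temp YAML file."""

    def _write(doc, name="codebook.yaml"):
        path = tmp_path / name
        path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
        return path

    return _write


@pytest.fixture
def mutate(codebook_doc):
    """Deep-copy the bundled codebook and apply an in-place mutation."""

    def _mutate(fn):
        doc = copy.deepcopy(codebook_doc)
        fn(doc)
        return doc

    return _mutate
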