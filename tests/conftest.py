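import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from phenolox import resources


@pytest.fixture(scope="session")
def templates():
    return resources.load_templates()


@pytest.fixture(scope="session")
def co_profile():
    return resources.load_co_profile()


@pytest.fixture(scope="session")
def lacaao_profile():
    return resources.load_lacaao_profile()


@pytest.fixture()
def fasta_writer(tmp_path):
    def write(name, entries):
        path = tmp_path / name
        with path.open("w") as fh:
            for header, seq in entries:
                fh.write(f">{header}\n{seq}\n")
        return path

    return write
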