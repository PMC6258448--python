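import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from smurf import Region, SnvRecord


@pytest.fixture
def tiny_regions():
    return [
        Region("chr1", 100, 200),
        Region("chr1", 500, 900),
        Region("chr2", 50, 300),
    ]


@pytest.fixture
def tiny_snvs():
    return [
        SnvRecord("chr1", 150, "S1"),
        SnvRecord("chr1", 160, "S1"),
        SnvRecord("chr1", 150, "S2"),
        SnvRecord("chr1", 600, "S2"),
        SnvRecord("chr2", 299, "S3"),
        SnvRecord("chr2", 300, "S3"),  # half-open: outside chr2:50-300
    ]


def write_lines(path: Path, rows) -> Path:
    path.write_text("".join("\t".join(str(f) for f in row) + "\n" for row in rows))
    return path


@pytest.fixture
def bed_writer(tmp_path):
    def _write(name, rows):
        return write_lines(tmp_path / name, rows)

    return _write
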