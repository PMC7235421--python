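import textwrap

import pytest

from cellanno.formats_io import DEGRecord, DEGTable
from cellanno.marker_database import MarkerDatabase


@pytest.fixture
def write_text(tmp_path):
    def _write(name: str, content: str):
        path = tmp_path / name
        path.write_text(textwrap.dedent(content).lstrip("\n"))
        return path

    return _write


@pytest.fixture
def small_deg_table() -> DEGTable:
    return DEGTable.from_records(
        [
            DEGRecord("G1", "1", 1.2, 0.01),
            DEGRecord("G2", "1", 0.5, 0.01),
            DEGRecord("G3", "1", 2.0, 0.2),
            DEGRecord("G1", "2", 2.5, 0.001),
            DEGRecord("G4", "2", 1.8, 0.03),
        ]
    )


@pytest.fixture
def tcell_db() -> MarkerDatabase:
    return MarkerDatabase(
        name="user",
        entries={
            ("T cell", "CD3E"): 2,
            ("T cell", "CD3D"): 1,
            ("B cell", "CD19"): 4,
        },
    )
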