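import numpy as np
import pandas as pd
import pytest

from deltacc.io import ExpressionMatrix, SampleSheet


@pytest.fixture
def sheet6():
    """Two samples per condition, sheet order Pre, In, Post."""
    rows = []
    for cond in ("Pre", "In", "Post"):
        for rep in (1, 2):
            rows.append(
                {
                    "sample_id": f"{cond}{rep}",
                    "subject_id": f"A{rep}",
                    "condition": cond,
                    "replicate": rep,
                }
            )
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture
def matrix6(sheet6):
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        rng.normal(8, 1, size=(4, 6)),
        index=["P1", "P2", "P3", "P4"],
        columns=sheet6.sample_ids,
    )
    return ExpressionMatrix(data)


@pytest.fixture
def write_profile(tmp_path):
    """Write a probe×sample TSV and return its path."""

    def _write(name, probes, columns):
        df = pd.DataFrame(columns, index=pd.Index(probes, name="probe_id"))
        path = tmp_path / name
        df.to_csv(path, sep="\t")
        return path

    return _write
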