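import numpy as np
import pandas as pd
import pytest

from evlink.panel import ProteinPanel
from evlink.pba import EVProfileMatrix


@pytest.fixture
def small_panel() -> ProteinPanel:
    return ProteinPanel(proteins=("P1", "P2", "P3", "P4"), markers=("P1", "P2"))


def make_matrix(counts, panel: ProteinPanel, sample_id: str = "s1") -> EVProfileMatrix:
    counts = np.asarray(counts, dtype=np.int64)
    tags = np.array([f"e{i + 1}" for i in range(counts.shape[0])], dtype=object)
    return EVProfileMatrix(sample_id, counts, tags, panel)


def make_read_table(rows) -> pd.DataFrame:
    """rows: iterable of (sample_id, ev_tag, protein_tag, read_count)."""
    return pd.DataFrame(rows, columns=["sample_id", "ev_tag", "protein_tag", "read_count"])
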