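"""Single-EV profile matrices from proximity-barcoding-assay read tables.

Each sequencing read links an EV tag (the identity of one vesicle) to a
protein tag (one antibody target) within a sample. Aggregating reads over
(EV tag, protein) pairs yields a per-sample EV x protein count matrix whose
rows are single vesicles; summaries of that matrix (singleton fraction,
proteins-per-EV histogram, per-marker carriage fractions) describe the
vesicle population.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .panel import ProteinPanel

READ_TABLE_COLUMNS = ("sample_id", "ev_tag", "protein_tag", "read_count")


class EmptyInputError(ValueError):
    """Raised when an operation receives no usable rows/EVs."""


def read_pba_table(path: str) -> pd.DataFrame:
    """Read a tab-separated PBA read table (sample_id, ev_tag, protein_tag, read_count)."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "ev_tag": str, "protein_tag": str, "read_count": np.int64},
    )
    missing = set(READ_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"read table missing columns: {sorted(missing)}")
    return df[list(READ_TABLE_COLUMNS)]


def write_pba_table(table: pd.DataFrame, path: str) -> None:
    table[list(READ_TABLE_COLUMNS)].to_csv(path, sep="\t", index=False)


@dataclass
class EVProfileMatrix:
    """Per-sample EV x protein read-count matrix.

    ``counts[i, j]`` is the number of reads supporting protein ``j`` on the
    vesicle with tag ``ev_tags[i]``. Columns follow the panel order. Rows are
    guaranteed non-empty (every retained EV has at least one read).
    """

    sample_id: str
    counts: np.ndarray  # (m, n) non-negative integers
    ev_tags: np.ndarray  # (m,) str
    panel: ProteinPanel

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.ev_tags = np.asarray(self.ev_tags, dtype=object)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D")
        if self.counts.shape != (len(self.ev_tags), len(self.panel)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.ev_tags)} EV tags x {len(self.panel)} panel proteins"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_evs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.counts.shape[1]

    def proteins_per_ev(self) -> np.ndarray:
        """Number of distinct proteins detected on each EV."""
        return (self.counts > 0).sum(axis=1)

    def drop_empty_rows(self) -> "EVProfileMatrix":
        keep = self.counts.sum(axis=1) > 0
        return EVProfileMatrix(self.sample_id, self.counts[keep], self.ev_tags[keep], self.panel)

    def to_read_table(self) -> pd.DataFrame:
        """Emit back to read-table rows (one row per nonzero cell)."""
        rows, cols = np.nonzero(self.counts)
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "ev_tag": self.ev_tags[rows],
                "protein_tag": np.asarray(self.panel.proteins, dtype=object)[cols],
                "read_count": self.counts[rows, cols],
            }
        )

    def write_mtx(self, prefix: str) -> None:
        """Write sparse counts as ``<prefix>.mtx`` plus row/column label files."""
        scipy.io.mmwrite(f"{prefix}.mtx", scipy.sparse.csr_matrix(self.counts))
        pd.Series(self.ev_tags).to_csv(f"{prefix}.rows.tsv", sep="\t", index=False, header=False)
        pd.Series(self.panel.proteins).to_csv(
            f"{prefix}.cols.tsv", sep="\t", index=False, header=False
        )

    @classmethod
    def read_mtx(cls, prefix: str, panel: ProteinPanel, sample_id: str) -> "EVProfileMatrix":
        counts = np.asarray(scipy.io.mmread(f"{prefix}.mtx").todense()).astype(np.int64)
        ev_tags = pd.read_csv(f"{prefix}.rows.tsv", sep="\t", header=None)[0].astype(str).to_numpy()
        cols = tuple(pd.read_csv(f"{prefix}.cols.tsv", sep="\t", header=None)[0].astype(str))
        if cols != panel.proteins:
            raise ValueError("column labels do not match panel order")
        return cls(sample_id, counts, ev_tags, panel)


def parse_reads(table: pd.DataFrame, panel: ProteinPanel, sample_id: str) -> EVProfileMatrix:
    """Aggregate a read table into the EV x protein count matrix for one sample.

    Duplicate (ev_tag, protein_tag) rows are summed; EVs whose total read count
    is zero are excluded. Every protein tag must belong to the panel.
    """
    sub = table[table["sample_id"] == sample_id]
    if sub.empty:
        raise EmptyInputError(f"no reads for sample {sample_id!r}")
    unknown = set(sub["protein_tag"]) - set(panel.proteins)
    if unknown:
        raise ValueError(f"unknown protein tag(s) not in panel: {sorted(unknown)}")
    agg = sub.groupby(["ev_tag", "protein_tag"], sort=True)["read_count"].sum()
    ev_tags = agg.index.get_level_values(0).unique().to_numpy(dtype=object)
    ev_index = {t: i for i, t in enumerate(ev_tags)}
    col_index = panel.index
    counts = np.zeros((len(ev_tags), len(panel)), dtype=np.int64)
    rows = [ev_index[t] for t in agg.index.get_level_values(0)]
    cols = [col_index[p] for p in agg.index.get_level_values(1)]
    counts[rows, cols] = agg.to_numpy()
    return EVProfileMatrix(sample_id, counts, ev_tags, panel).drop_empty_rows()


def normalize_reads(matrix: EVProfileMatrix) -> np.ndarray:
    """Per-sample read proportions: each count divided by the sample's total reads.

    The returned float matrix sums to 1 over all cells, making read-based
    protein levels comparable across samples sequenced to different depths.
    """
    total = matrix.counts.sum()
    if total == 0:
        raise EmptyInputError("cannot normalize an all-zero matrix")
    return matrix.counts / total


@dataclass(frozen=True)
class ProfileSummary:
    """Population summary of a single-EV profile matrix."""

    total_evs: int
    singleton_fraction: float
    proteins_per_ev_histogram: dict[int, int]
    per_protein_ev_fraction: dict[str, float]
    per_pair_ev_fraction: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        assert 0.0 <= self.singleton_fraction <= 1.0
        assert sum(self.proteins_per_ev_histogram.values()) == self.total_evs


def summarize_profile(
    matrix: EVProfileMatrix, pair_proteins: tuple[str, ...] | None = None
) -> ProfileSummary:
    """Summarize the EV population: singleton fraction, proteins-per-EV histogram,
    and the fraction of EVs carrying each protein / each protein pair.

    Carriage uses "at least" membership: an EV carrying {A, B, C} counts toward
    A, B, C and every pair among them. ``pair_proteins`` restricts which pairwise
    fractions are tabulated (default: the panel's prioritized markers, to keep
    the pair table small).
    """
    if matrix.n_evs == 0:
        raise EmptyInputError("empty matrix")
    support = matrix.counts > 0
    k = support.sum(axis=1)
    m = matrix.n_evs
    hist_vals, hist_counts = np.unique(k, return_counts=True)
    histogram = {int(v): int(c) for v, c in zip(hist_vals, hist_counts)}
    per_protein = {
        p: float(support[:, j].mean()) for j, p in enumerate(matrix.panel.proteins)
    }
    if pair_proteins is None:
        pair_proteins = matrix.panel.markers
    col = matrix.panel.index
    per_pair = {
        (a, b): float((support[:, col[a]] & support[:, col[b]]).mean())
        for a, b in combinations(sorted(pair_proteins), 2)
    }
    return ProfileSummary(
        total_evs=m,
        singleton_fraction=float((k == 1).sum() / m),
        proteins_per_ev_histogram=histogram,
        per_protein_ev_fraction=per_protein,
        per_pair_ev_fraction=per_pair,
    )
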