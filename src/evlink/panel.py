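"""Antibody panel definitions.

A panel is the fixed set of surface proteins targeted by the assay; a small
subset of it may be flagged as trait-prioritized markers (e.g. proteins whose
coding genes associate with adiposity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

DEFAULT_PANEL_SIZE = 113
DEFAULT_N_MARKERS = 12


@dataclass(frozen=True)
class ProteinPanel:
    """The set of assayed surface proteins and its prioritized-marker subset.

    Parameters
    ----------
    proteins
        Unique protein identifiers, in canonical column order.
    markers
        Prioritized marker identifiers; must be a subset of ``proteins``.
    """

    proteins: tuple[str, ...]
    markers: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(set(self.proteins)) != len(self.proteins):
            raise ValueError("panel protein ids must be unique")
        unknown = set(self.markers) - set(self.proteins)
        if unknown:
            raise ValueError(f"markers not in panel: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.proteins)

    def __contains__(self, protein: str) -> bool:
        return protein in self.index

    @property
    def index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.proteins)}

    @classmethod
    def default(
        cls,
        size: int = DEFAULT_PANEL_SIZE,
        n_markers: int = DEFAULT_N_MARKERS,
    ) -> "ProteinPanel":
        """Generic panel ``P001..P<size>`` with the first ``n_markers`` prioritized."""
        if not 0 <= n_markers <= size:
            raise ValueError("n_markers must be in [0, size]")
        proteins = tuple(f"P{i + 1:03d}" for i in range(size))
        return cls(proteins=proteins, markers=proteins[:n_markers])

    @classmethod
    def from_table(cls, path: str) -> "ProteinPanel":
        """Load a panel from a TSV with columns ``protein_id`` and ``is_marker``."""
        df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
        markers = tuple(df.loc[df["is_marker"].astype(bool), "protein_id"])
        return cls(proteins=tuple(df["protein_id"]), markers=markers)

    def to_table(self, path: str) -> None:
        pd.DataFrame(
            {
                "protein_id": self.proteins,
                "is_marker": [int(p in set(self.markers)) for p in self.proteins],
            }
        ).to_csv(path, sep="\t", index=False)
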