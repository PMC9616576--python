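"""Marker-specific EV phenotypes.

An "EV type" is the sub-population of vesicles carrying a given set of one or
two surface markers. With 12 prioritized markers this gives 12 single-marker
types plus C(12,2) = 66 marker-pair types = 78 phenotypes; pairing each marker
against the whole panel instead gives |M|*(n-|M|) + C(|M|,2) pair phenotypes.
The abundance of a type in a sample is the proportion of QC-passed vesicles
that qualify.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panel import ProteinPanel
from .pba import EVProfileMatrix

LABEL_PREFIX = "EV_"
LABEL_JOIN = " & "


@dataclass(frozen=True)
class EVTypeDefinition:
    """A marker set of size 1 or 2 with its matching rule.

    ``at_least`` (default) counts vesicles carrying every marker in the set,
    possibly among others; ``exact`` requires the vesicle's detected proteins
    to equal the set.
    """

    marker_set: frozenset[str]
    match_mode: str = "at_least"
    label: str = field(init=False)

    def __post_init__(self) -> None:
        if len(self.marker_set) not in (1, 2):
            raise ValueError("marker_set must contain 1 or 2 proteins")
        if self.match_mode not in ("at_least", "exact"):
            raise ValueError("match_mode must be 'at_least' or 'exact'")
        object.__setattr__(
            self, "label", LABEL_PREFIX + LABEL_JOIN.join(sorted(self.marker_set))
        )

    @classmethod
    def from_label(cls, label: str, match_mode: str = "at_least") -> "EVTypeDefinition":
        body = label.removeprefix(LABEL_PREFIX)
        return cls(frozenset(body.split(LABEL_JOIN)), match_mode=match_mode)


def enumerate_ev_types(
    markers: Iterable[str],
    panel: ProteinPanel,
    scheme: str = "marker_pairs_only",
    match_mode: str = "at_least",
) -> list[EVTypeDefinition]:
    """Enumerate EV-type definitions from a marker subset.

    ``marker_pairs_only``: every marker singleton plus every unordered pair of
    markers (|M| + C(|M|, 2) types; 12 markers -> 78). ``marker_vs_panel``:
    every unordered panel pair containing at least one marker
    (|M|*(n-|M|) + C(|M|, 2) types), as used for the pairwise GWAS screen.
    Output order is canonical: singletons alphabetically, then pairs
    lexicographically.
    """
    markers = sorted(set(markers))
    unknown = set(markers) - set(panel.proteins)
    if unknown:
        raise ValueError(f"markers not in panel: {sorted(unknown)}")
    defs: list[EVTypeDefinition] = []
    if scheme == "marker_pairs_only":
        defs += [EVTypeDefinition(frozenset({m}), match_mode) for m in markers]
        defs += [
            EVTypeDefinition(frozenset(pair), match_mode)
            for pair in combinations(markers, 2)
        ]
    elif scheme == "marker_vs_panel":
        marker_set = set(markers)
        others = sorted(set(panel.proteins) - marker_set)
        defs += [
            EVTypeDefinition(frozenset({m, o}), match_mode)
            for m in markers
            for o in others
        ]
        defs += [
            EVTypeDefinition(frozenset(pair), match_mode)
            for pair in combinations(markers, 2)
        ]
        defs.sort(key=lambda d: d.label)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return defs


def expected_type_count(n_markers: int, panel_size: int | None = None) -> int:
    """Closed-form type counts: |M| + C(|M|,2), or |M|(n-|M|) + C(|M|,2) if a
    panel size is given (pairs-vs-panel scheme)."""
    if panel_size is None:
        return n_markers + comb(n_markers, 2)
    return n_markers * (panel_size - n_markers) + comb(n_markers, 2)


@dataclass(frozen=True)
class EVTypeAbundance:
    """Normalized abundance of one EV type in one sample."""

    sample_id: str
    type: EVTypeDefinition
    raw_count: int
    abundance: float
    n_evs_total: int

    def __post_init__(self) -> None:
        assert 0 <= self.raw_count <= self.n_evs_total
        assert 0.0 <= self.abundance <= 1.0


def _qualifying_rows(matrix: EVProfileMatrix, ev_type: EVTypeDefinition) -> np.ndarray:
    col = matrix.panel.index
    try:
        idx = [col[m] for m in ev_type.marker_set]
    except KeyError as exc:
        raise ValueError(f"marker {exc.args[0]!r} not in panel") from None
    support = matrix.counts > 0
    has_all = support[:, idx].all(axis=1)
    if ev_type.match_mode == "at_least":
        return has_all
    return has_all & (support.sum(axis=1) == len(idx))


def quantify_ev_type(matrix: EVProfileMatrix, ev_type: EVTypeDefinition) -> EVTypeAbundance:
    """Count qualifying vesicles and normalize by the sample's QC-passed EV total.

    The abundance is a vesicle proportion (not read-weighted), so a sample's
    78 type abundances are directly comparable across samples.
    """
    qualifying = int(_qualifying_rows(matrix, ev_type).sum())
    return EVTypeAbundance(
        sample_id=matrix.sample_id,
        type=ev_type,
        raw_count=qualifying,
        abundance=qualifying / matrix.n_evs if matrix.n_evs else 0.0,
        n_evs_total=matrix.n_evs,
    )


def total_protein_level(matrix: EVProfileMatrix, protein: str) -> float:
    """Overall level of one protein: its read share of the sample's total reads."""
    col = matrix.panel.index
    if protein not in col:
        raise ValueError(f"protein {protein!r} not in panel")
    total = matrix.counts.sum()
    if total == 0:
        raise ValueError("matrix has no reads")
    return float(matrix.counts[:, col[protein]].sum() / total)


def build_phenotype_table(
    samples: Sequence[EVProfileMatrix], types: Sequence[EVTypeDefinition]
) -> pd.DataFrame:
    """Samples x EV-types abundance table (rows = sample ids, columns = type labels).

    A sample with zero qualifying vesicles for a type gets a 0 entry, not a
    missing value. Duplicate sample ids are rejected.
    """
    ids = [m.sample_id for m in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in phenotype table input")
    panels = {id(m.panel) for m in samples}
    if panels and len({m.panel.proteins for m in samples}) != 1:
        raise ValueError("samples do not share a panel")
    data = {
        t.label: [quantify_ev_type(m, t).abundance for m in samples] for t in types
    }
    return pd.DataFrame(data, index=pd.Index(ids, name="sample_id"))


def write_phenotype_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t")


def read_phenotype_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
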