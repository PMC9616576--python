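"""Background-noise removal for single-EV count matrices.

Random ligation of tags produces spurious (EV, protein) read pairs. The QC
procedure is: (1) drop vesicles reporting more than a plausible number of
distinct proteins; (2) compute the independence-expected count for every cell,
E[i, j] = rowsum_i * colsum_j / grand_total, and the Pearson residual
chi = (D - E) / sqrt(E); (3) keep only cells whose residual reaches the upper
quantile of the residual distribution — cells consistent with random row/column
mixing are reset to zero — then drop vesicles left with no reads.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .pba import EmptyInputError, EVProfileMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChiFilterConfig:
    """Settings for the chi-residual background filter.

    Parameters
    ----------
    max_proteins_per_ev
        Vesicles with strictly more distinct proteins than this are discarded
        before the residual filter (default 5).
    quantile
        Residual quantile q in (0, 1]; cells at or above the q-quantile are
        treated as real signal (default 0.95, i.e. keep the top 5%).
    quantile_population
        Whether the quantile is taken over nonzero cells of D only (default;
        structural zeros would otherwise dominate a sparse matrix) or all cells.
    """

    max_proteins_per_ev: int = 5
    quantile: float = 0.95
    quantile_population: str = "nonzero_cells"

    def __post_init__(self) -> None:
        if self.max_proteins_per_ev < 1:
            raise ValueError("max_proteins_per_ev must be >= 1")
        if not 0.0 < self.quantile <= 1.0:
            raise ValueError("quantile must be in (0, 1]")
        if self.quantile_population not in ("nonzero_cells", "all_cells"):
            raise ValueError("quantile_population must be 'nonzero_cells' or 'all_cells'")


def filter_max_proteins(
    matrix: EVProfileMatrix, config: ChiFilterConfig | None = None
) -> EVProfileMatrix:
    """Remove EVs carrying strictly more distinct proteins than the cap.

    An EV with exactly ``max_proteins_per_ev`` proteins is retained.
    """
    config = config or ChiFilterConfig()
    if matrix.n_evs == 0:
        raise EmptyInputError("empty matrix")
    keep = matrix.proteins_per_ev() <= config.max_proteins_per_ev
    if not keep.any():
        raise EmptyInputError(
            f"all {matrix.n_evs} EVs exceed max_proteins_per_ev={config.max_proteins_per_ev}"
        )
    return EVProfileMatrix(
        matrix.sample_id, matrix.counts[keep], matrix.ev_tags[keep], matrix.panel
    )


def expected_matrix(matrix: EVProfileMatrix) -> np.ndarray:
    """Independence-expected counts: E[i, j] = rowsum_i * colsum_j / N.

    This is the usual contingency-table expectation; sum(E) equals sum(D)
    exactly (up to float rounding).
    """
    D = matrix.counts
    N = D.sum()
    if N == 0:
        raise EmptyInputError("zero grand total")
    return np.outer(D.sum(axis=1), D.sum(axis=0)) / N


def chi_matrix(D: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Element-wise Pearson residuals (D - E) / sqrt(E); cells with E = 0 map to 0."""
    D = np.asarray(D, dtype=float)
    E = np.asarray(E, dtype=float)
    if D.shape != E.shape:
        raise ValueError(f"shape mismatch: D {D.shape} vs E {E.shape}")
    chi = np.zeros_like(E)
    ok = E > 0
    chi[ok] = (D[ok] - E[ok]) / np.sqrt(E[ok])
    return chi


def threshold_chi(
    matrix: EVProfileMatrix,
    chi: np.ndarray,
    config: ChiFilterConfig | None = None,
    cutoff: float | None = None,
) -> tuple[EVProfileMatrix, float]:
    """Zero out cells whose residual falls below the configured quantile.

    Cells with chi >= cutoff keep their original read count; all other cells
    are reset to 0, and vesicles left with no reads are dropped. Returns the
    filtered matrix and the realized cutoff. Passing ``cutoff`` overrides the
    quantile computation (useful for re-applying a previous threshold).
    """
    config = config or ChiFilterConfig()
    if chi.shape != matrix.counts.shape:
        raise ValueError("chi shape does not match matrix")
    if cutoff is None:
        if config.quantile_population == "nonzero_cells":
            pool = chi[matrix.counts > 0]
        else:
            pool = chi.ravel()
        if pool.size == 0:
            raise EmptyInputError("no cells to threshold")
        if np.ptp(pool) == 0:
            warnings.warn(
                "degenerate residual distribution (all chi equal); retaining all cells",
                RuntimeWarning,
                stacklevel=2,
            )
            cutoff = float(pool[0])
        else:
            cutoff = float(np.quantile(pool, config.quantile))
    new_counts = np.where(chi >= cutoff, matrix.counts, 0)
    out = EVProfileMatrix(
        matrix.sample_id, new_counts, matrix.ev_tags, matrix.panel
    ).drop_empty_rows()
    logger.info(
        "chi threshold sample=%s cutoff=%.4f EVs %d -> %d",
        matrix.sample_id,
        cutoff,
        matrix.n_evs,
        out.n_evs,
    )
    return out, cutoff


@dataclass(frozen=True)
class DenoiseReport:
    """Result of the full QC chain with bookkeeping for the run manifest."""

    matrix: EVProfileMatrix
    cutoff: float
    n_evs_input: int
    n_evs_after_protein_filter: int
    n_evs_output: int
    surviving_cell_fraction: float  # among nonzero cells of the filtered input


def denoise_matrix(matrix: EVProfileMatrix, config: ChiFilterConfig | None = None) -> DenoiseReport:
    """Run the QC chain: protein-count cap, then residual thresholding.

    The quantile is computed per sample (per matrix), not pooled across samples.
    """
    config = config or ChiFilterConfig()
    filtered = filter_max_proteins(matrix, config)
    E = expected_matrix(filtered)
    chi = chi_matrix(filtered.counts, E)
    out, cutoff = threshold_chi(filtered, chi, config)
    nonzero_before = int((filtered.counts > 0).sum())
    nonzero_after = int((out.counts > 0).sum())
    return DenoiseReport(
        matrix=out,
        cutoff=cutoff,
        n_evs_input=matrix.n_evs,
        n_evs_after_protein_filter=filtered.n_evs,
        n_evs_output=out.n_evs,
        surviving_cell_fraction=nonzero_after / nonzero_before if nonzero_before else 0.0,
    )
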