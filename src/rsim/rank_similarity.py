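"""Per-taxon differential-abundance-level statistics from pairwise rank similarity.

For each taxon j the statistic M_j is the median over all taxa j'
(self included) of the Spearman rank correlation r_{j,j'} between the
two taxa's count vectors across samples.  Counts of non-differentially
abundant taxa are all approximately proportional to the per-sample
sampling fraction, so their mutual rank correlations sit near 1; a
differentially abundant taxon decorrelates from that majority and its
median drops below 1.  Zeros are ranked like any other value (mid-ranks
for ties), which is what makes the statistic usable on sparse tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data_model import CountMatrix
from .errors import InputError

__all__ = ["RankStats", "spearman", "rank_correlation_matrix", "median_rank_statistics"]

# Above this taxon count the full d x d correlation matrix is built in
# row blocks to cap peak memory; results are identical.
_BLOCK_THRESHOLD = 20_000
_BLOCK_ROWS = 2_048


@dataclass(frozen=True)
class RankStats:
    """Per-taxon medians of pairwise Spearman correlations, aligned to labels."""

    m_values: np.ndarray
    taxon_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.m_values, dtype=np.float64)
        object.__setattr__(self, "m_values", m)
        object.__setattr__(self, "taxon_ids", tuple(self.taxon_ids))
        if m.shape != (len(self.taxon_ids),):
            raise InputError("m_values length does not match taxon ids")
        if np.any(m < -1 - 1e-12) or np.any(m > 1 + 1e-12):
            raise InputError("rank statistics must lie in [-1, 1]")


def _check_not_constant(x: np.ndarray, name: str) -> None:
    if np.all(x == x[0]):
        raise InputError(
            f"{name} is constant; Spearman correlation undefined "
            "(run filter_taxa first)"
        )


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive the average of the ranks they span.  Requires at least
    three observations and non-constant inputs.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise InputError("need at least 3 observations")
    _check_not_constant(x, "x")
    _check_not_constant(y, "y")
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def _centered_ranks(counts: np.ndarray) -> np.ndarray:
    """Row-wise mid-ranks, centered and L2-normalized (constant rows rejected)."""
    if np.any(np.all(counts == counts[:, :1], axis=1)):
        raise InputError(
            "constant taxon present; run filter_taxa before rank statistics"
        )
    ranks = rankdata(counts, axis=1).astype(np.float64)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1, keepdims=True))
    return ranks / norms


def rank_correlation_matrix(counts: np.ndarray) -> np.ndarray:
    """Full d x d Spearman correlation matrix of the rows of ``counts``.

    Computed as a rank transform followed by one matrix product, so the
    cost is O(d^2 n) plus the O(d n log n) ranking.
    """
    z = _centered_ranks(np.asarray(counts, dtype=np.float64))
    corr = z @ z.T
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return corr


def _row_medians_blocked(z: np.ndarray) -> np.ndarray:
    d = z.shape[0]
    out = np.empty(d)
    for start in range(0, d, _BLOCK_ROWS):
        stop = min(start + _BLOCK_ROWS, d)
        block = z[start:stop] @ z.T
        np.clip(block, -1.0, 1.0, out=block)
        block[np.arange(start, stop) - start, np.arange(start, stop)] = 1.0
        out[start:stop] = np.median(block, axis=1)
    return out


def median_rank_statistics(cm: CountMatrix) -> RankStats:
    """M_j = median over j' = 1..d (self included) of r_{j,j'}.

    The median of an even-length multiset is the mean of its two central
    values.  Requires at least 3 samples and at least 3 non-constant taxa.
    """
    if cm.n_samples < 3:
        raise InputError("need at least 3 samples for rank statistics")
    if cm.n_taxa < 3:
        raise InputError("need at least 3 taxa for median rank statistics")
    if cm.n_taxa > _BLOCK_THRESHOLD:
        m = _row_medians_blocked(_centered_ranks(cm.counts))
    else:
        m = np.median(rank_correlation_matrix(cm.counts), axis=1)
    return RankStats(m, cm.taxon_ids)
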