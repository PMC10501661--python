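"""Empirical-Bayes classification of taxa into the reference set (Step 2).

The per-taxon statistics M_j are modelled as draws from the mixture

    F(t) = pi0 * F0(t) + (1 - pi0) * F1(t),

where F0 is the distribution of M_j for non-differentially abundant
taxa and pi0 their proportion.  The misclassification rate of a
threshold rule {M_j > T} is

    P(DA | M_j > T) = 1 - pi0 * (1 - F0(T)) / (1 - F(T)),

so only F, F0 and pi0 need estimating:

* F by the empirical CDF of all M_j;
* F0 by resampling: taxa with M_j > gamma form a high-confidence
  non-DA candidate pool, and medians recomputed on random subsamples
  of that pool approximate draws from F0;
* pi0 by least squares on the right tail, using
  1 - F(t) ~ pi0 * (1 - F0(t)) for t > gamma.

The chosen threshold is the smallest T whose estimated
misclassification rate is at or below the user target eta; the
reference set is every taxon with M_j > T.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_model import CountMatrix
from .errors import ComputationError, InputError
from .rank_similarity import RankStats, median_rank_statistics, rank_correlation_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "EmpiricalCDF",
    "ReferenceModel",
    "empirical_cdf",
    "estimate_f0",
    "estimate_pi0",
    "choose_threshold",
    "fit_reference_model",
    "fit_reference_model_robust",
]

# Threshold grid points are nudged below each observed M value so that
# the strict rule {M_j > T} keeps that value's taxa in the set.
_GRID_EPS = 1e-12
_PI0_FLOOR = 1e-6


class EmpiricalCDF:
    """Right-continuous step function F(t) = (# stored values <= t) / count."""

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=np.float64).ravel()
        if values.size == 0:
            raise InputError("empirical CDF needs at least one value")
        if not np.all(np.isfinite(values)):
            raise InputError("empirical CDF values must be finite")
        self.support_points = np.sort(values)

    @property
    def n(self) -> int:
        return self.support_points.size

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        idx = np.searchsorted(self.support_points, t, side="right")
        out = idx / self.n
        return float(out) if np.isscalar(t) else out

    def __repr__(self) -> str:  # pragma: no cover
        return f"EmpiricalCDF(n={self.n}, range=[{self.support_points[0]:.4g}, {self.support_points[-1]:.4g}])"


def empirical_cdf(values: np.ndarray) -> EmpiricalCDF:
    """Empirical distribution function of a sample of reals."""
    return EmpiricalCDF(values)


def estimate_f0(
    cm: CountMatrix,
    stats: RankStats,
    gamma: float = 0.8,
    n_resamples: int = 100,
    subsample_fraction: float = 0.5,
    seed: int = 0,
    *,
    corr: np.ndarray | None = None,
) -> EmpiricalCDF:
    """Estimate the null distribution F0 of M by resampling the candidate pool.

    Taxa with M_j > gamma form the candidate pool.  Each of
    ``n_resamples`` rounds draws ``ceil(subsample_fraction * pool)``
    taxa without replacement and recomputes every per-taxon median of
    pairwise Spearman correlations *within* the subsampled count
    sub-matrix; all resampled medians are pooled into one empirical CDF.

    Because a Spearman correlation between two taxa depends only on
    those two rows, the within-subsample correlations equal the
    corresponding entries of the full correlation matrix; when ``corr``
    is supplied the medians are read off its sub-blocks, which is
    mathematically identical to recomputing from counts.
    """
    if not 0 < subsample_fraction <= 1:
        raise InputError("subsample_fraction must lie in (0, 1]")
    if n_resamples < 1:
        raise InputError("n_resamples must be positive")
    candidates = np.flatnonzero(stats.m_values > gamma)
    if candidates.size < 10:
        raise InputError(
            f"only {candidates.size} taxa have M > gamma={gamma}; "
            "lower gamma or inspect the data"
        )
    k = int(np.ceil(subsample_fraction * candidates.size))
    if k < 5:
        raise InputError(
            f"subsample size {k} too small; raise subsample_fraction"
        )
    if corr is None:
        corr = rank_correlation_matrix(cm.counts)
    rng = np.random.default_rng(seed)
    pooled = np.empty(n_resamples * k)
    for b in range(n_resamples):
        sub = rng.choice(candidates, size=k, replace=False)
        block = corr[np.ix_(sub, sub)]
        pooled[b * k : (b + 1) * k] = np.median(block, axis=1)
    return EmpiricalCDF(pooled)


def estimate_pi0(
    stats: RankStats,
    f_hat: EmpiricalCDF,
    f0_hat: EmpiricalCDF,
    gamma: float = 0.8,
) -> float:
    """Least-squares estimate of the non-DA proportion pi0.

    Minimizes sum over {j : M_j > gamma} of
    (1 - F(M_j) - pi0 * (1 - F0(M_j)))^2, which has the closed form
    sum(a*b) / sum(b^2) with a = 1 - F(M_j), b = 1 - F0(M_j); the
    result is clipped to [1e-6, 1].
    """
    m = stats.m_values[stats.m_values > gamma]
    if m.size == 0:
        raise InputError(f"no taxa with M > gamma={gamma}")
    a = 1.0 - np.asarray(f_hat(m))
    b = 1.0 - np.asarray(f0_hat(m))
    denom = float(b @ b)
    if denom == 0.0:
        warnings.warn(
            "all candidate M values sit at the right edge of F0; pi0 set to 1",
            stacklevel=2,
        )
        return 1.0
    return float(np.clip((a @ b) / denom, _PI0_FLOOR, 1.0))


def choose_threshold(
    stats: RankStats,
    f_hat: EmpiricalCDF,
    f0_hat: EmpiricalCDF,
    pi0_hat: float,
    eta: float = 0.05,
) -> float:
    """Smallest threshold whose estimated misclassification rate is <= eta.

    The estimated rate e(T) = 1 - pi0 * (1 - F0(T)) / (1 - F(T)) is
    evaluated on the grid of sorted unique M values shifted down by a
    tiny epsilon (so the strict rule M_j > T retains each grid point's
    taxa), clamped to [0, 1].  The scan stops where 1 - F(T) reaches 0.
    """
    if not 0 < eta < 1:
        raise InputError("eta must lie in (0, 1)")
    grid = np.unique(stats.m_values) - _GRID_EPS
    for t in grid:
        survival = 1.0 - f_hat(t)
        if survival <= 0:
            break
        rate = 1.0 - pi0_hat * (1.0 - f0_hat(t)) / survival
        rate = min(max(rate, 0.0), 1.0)
        if rate <= eta:
            return float(t)
    raise ComputationError(
        f"misclassification target eta={eta} unattainable on this data; "
        "raise eta or gamma"
    )


@dataclass(frozen=True)
class ReferenceModel:
    """Fitted empirical-Bayes objects and the estimated reference set."""

    gamma: float
    eta: float
    f_hat: EmpiricalCDF
    f0_hat: EmpiricalCDF
    pi0_hat: float
    t_hat: float
    candidate_set: frozenset[str]
    reference_set: frozenset[str]
    stats: RankStats
    n_resamples: int
    subsample_fraction: float
    seed: int

    @property
    def misclassification_at_threshold(self) -> float:
        """Estimated misclassification rate e(T) at the fitted threshold."""
        survival = 1.0 - self.f_hat(self.t_hat)
        rate = 1.0 - self.pi0_hat * (1.0 - self.f0_hat(self.t_hat)) / survival
        return min(max(rate, 0.0), 1.0)

    def to_json(self, path: str | Path) -> None:
        """Serialize the fit; the pooled null medians make F0 reconstructable."""
        payload = {
            "gamma": self.gamma,
            "eta": self.eta,
            "pi0_hat": self.pi0_hat,
            "t_hat": self.t_hat,
            "n_resamples": self.n_resamples,
            "subsample_fraction": self.subsample_fraction,
            "seed": self.seed,
            "reference_set": sorted(self.reference_set),
            "candidate_set": sorted(self.candidate_set),
            "taxon_ids": list(self.stats.taxon_ids),
            "m_values": self.stats.m_values.tolist(),
            "null_medians": self.f0_hat.support_points.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceModel":
        payload = json.loads(Path(path).read_text())
        stats = RankStats(
            np.asarray(payload["m_values"]), tuple(payload["taxon_ids"])
        )
        return cls(
            gamma=payload["gamma"],
            eta=payload["eta"],
            f_hat=EmpiricalCDF(stats.m_values),
            f0_hat=EmpiricalCDF(np.asarray(payload["null_medians"])),
            pi0_hat=payload["pi0_hat"],
            t_hat=payload["t_hat"],
            candidate_set=frozenset(payload["candidate_set"]),
            reference_set=frozenset(payload["reference_set"]),
            stats=stats,
            n_resamples=payload["n_resamples"],
            subsample_fraction=payload["subsample_fraction"],
            seed=payload["seed"],
        )


def fit_reference_model(
    cm: CountMatrix,
    eta: float = 0.05,
    gamma: float = 0.8,
    n_resamples: int = 100,
    subsample_fraction: float = 0.5,
    seed: int = 0,
) -> ReferenceModel:
    """Run the full two-step reference-set estimation on a count matrix.

    Computes per-taxon rank-similarity medians, estimates F, F0 and
    pi0, chooses the misclassification-controlled threshold, and
    returns the fitted model whose ``reference_set`` is every taxon
    with M_j above the threshold.

    A smaller ``eta`` yields a purer but smaller reference set, suited
    to bias-sensitive analyses such as differential abundance testing;
    a larger ``eta`` yields a bigger, lower-variance set, suited to
    ordination.  ``gamma`` (default 0.8) only seeds the null-candidate
    pool and rarely needs changing at ASV/OTU resolution.
    """
    if cm.n_samples < 10:
        warnings.warn(
            f"only {cm.n_samples} samples; rank statistics will be noisy",
            stacklevel=2,
        )
    stats = median_rank_statistics(cm)
    corr = None if cm.n_taxa > 20_000 else rank_correlation_matrix(cm.counts)
    f_hat = empirical_cdf(stats.m_values)
    f0_hat = estimate_f0(
        cm, stats, gamma, n_resamples, subsample_fraction, seed, corr=corr
    )
    pi0_hat = estimate_pi0(stats, f_hat, f0_hat, gamma)
    if pi0_hat <= 0.5:
        warnings.warn(
            f"estimated non-DA proportion pi0={pi0_hat:.3f} <= 0.5; the "
            "majority-non-DA identifiability assumption looks violated",
            stacklevel=2,
        )
    t_hat = choose_threshold(stats, f_hat, f0_hat, pi0_hat, eta)
    in_ref = stats.m_values > t_hat
    reference = frozenset(t for t, k in zip(stats.taxon_ids, in_ref) if k)
    if not reference:
        raise ComputationError("fitted reference set is empty")
    candidates = frozenset(
        t for t, m in zip(stats.taxon_ids, stats.m_values) if m > gamma
    )
    logger.info(
        "reference model: pi0=%.3f T=%.4f |ref|=%d/%d",
        pi0_hat, t_hat, len(reference), cm.n_taxa,
    )
    return ReferenceModel(
        gamma=gamma,
        eta=eta,
        f_hat=f_hat,
        f0_hat=f0_hat,
        pi0_hat=pi0_hat,
        t_hat=t_hat,
        candidate_set=candidates,
        reference_set=reference,
        stats=stats,
        n_resamples=n_resamples,
        subsample_fraction=subsample_fraction,
        seed=seed,
    )


def fit_reference_model_robust(
    cm: CountMatrix,
    eta: float = 0.05,
    gammas: tuple[float, ...] = (0.8, 0.7, 0.6, 0.5),
    n_resamples: int = 100,
    subsample_fraction: float = 0.5,
    seed: int = 0,
) -> ReferenceModel:
    """Fit with a descending candidate-threshold cascade.

    On shallow or heavily rarefied data even clearly non-differential
    taxa can have medians below the recommended gamma = 0.8, leaving the
    null-candidate pool empty.  The candidate threshold only needs to
    sit at a level differentially abundant taxa cannot reach, and
    misclassification control is insensitive to it over a wide range, so
    this wrapper retries with the next smaller gamma whenever the pool
    is too small for resampling; any other failure propagates.
    """
    last: InputError | None = None
    for gamma in gammas:
        try:
            return fit_reference_model(
                cm, eta=eta, gamma=gamma, n_resamples=n_resamples,
                subsample_fraction=subsample_fraction, seed=seed,
            )
        except InputError as exc:
            logger.info("gamma=%.2f unusable (%s); trying smaller", gamma, exc)
            last = exc
    raise last
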