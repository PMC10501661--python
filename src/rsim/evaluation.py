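"""Downstream analyses used to judge normalization quality.

Covers the empirical misclassification rate of a fitted reference set,
per-taxon Welch t-tests and Pearson correlation tests with realized
false-discovery proportion and sensitivity against planted truth,
PERMANOVA on Euclidean distances of normalized values, and
classical-scaling PCoA coordinates (log-transformed by default, as is
usual for ordination).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from .data_model import CovariateTable, NormalizedMatrix
from .errors import InputError
from .reference_selection import ReferenceModel
from .synthetic_data import SimulationTruth

__all__ = [
    "misclassification_rate",
    "per_taxon_tests",
    "fdp_and_sensitivity",
    "permanova",
    "pcoa_coordinates",
    "log_transform_values",
]


def misclassification_rate(model: ReferenceModel, truth: SimulationTruth) -> float:
    """Fraction of the estimated reference set that is truly differentially abundant.

    |J0_hat intersect J1| / |J0_hat|.
    """
    ref = model.reference_set
    if not ref:
        raise InputError("estimated reference set is empty")
    unknown = ref - (truth.da_taxa | truth.nonda_taxa)
    if unknown:
        raise InputError(f"reference set taxa absent from truth: {sorted(unknown)[:5]}")
    return len(ref & truth.da_taxa) / len(ref)


def default_pseudocount(values: np.ndarray) -> float:
    """Half the smallest nonzero value of the matrix (1.0 if all zero)."""
    nz = values[values > 0]
    return float(nz.min() / 2) if nz.size else 1.0


def log_transform_values(
    values: np.ndarray, pseudo: float | None = None
) -> tuple[np.ndarray, float]:
    """log(x + pseudo); the pseudo-count used is returned for reporting."""
    if pseudo is None:
        pseudo = default_pseudocount(values)
    if pseudo <= 0:
        raise InputError("pseudo-count must be positive")
    return np.log(values + pseudo), pseudo


@dataclass(frozen=True)
class TaxonTestResult:
    """Per-taxon p-values with raw-threshold and BH-adjusted rejection sets."""

    taxon_ids: tuple[str, ...]
    p_values: np.ndarray
    statistics: np.ndarray
    rejections: frozenset[str]  # raw p <= alpha
    rejections_bh: frozenset[str]  # Benjamini-Hochberg at level alpha
    alpha: float
    test: str
    pseudo: float | None


def _bh_reject(p: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask."""
    m = p.size
    order = np.argsort(p)
    below = p[order] <= alpha * (np.arange(1, m + 1) / m)
    mask = np.zeros(m, dtype=bool)
    if below.any():
        mask[order[: np.max(np.flatnonzero(below)) + 1]] = True
    return mask


def per_taxon_tests(
    nm: NormalizedMatrix,
    covariate: CovariateTable,
    test: str = "t_test",
    alpha: float = 0.05,
    log_transform: bool = True,
    pseudo: float | None = None,
) -> TaxonTestResult:
    """Per-taxon association tests against a per-sample outcome.

    ``t_test`` runs a two-sided Welch (unequal-variance) two-sample
    t-test on a binary covariate; ``pearson`` a two-sided Pearson
    correlation test on a continuous one.  With ``log_transform`` (the
    default) the tests run on log(value + pseudo), the pseudo-count
    defaulting to half the smallest nonzero normalized value.
    """
    if test not in ("t_test", "pearson"):
        raise InputError(f"unknown test {test!r}")
    if not 0 < alpha < 1:
        raise InputError("alpha must lie in (0, 1)")
    pos = {s: k for k, s in enumerate(covariate.sample_ids)}
    missing = [s for s in nm.sample_ids if s not in pos]
    if missing:
        raise InputError(f"covariate missing samples: {missing[:5]}")
    y = covariate.values[[pos[s] for s in nm.sample_ids]]

    values = nm.values
    used_pseudo: float | None = None
    if log_transform:
        values, used_pseudo = log_transform_values(values, pseudo)

    if test == "t_test":
        levels = np.unique(y)
        if levels.size != 2:
            raise InputError("t_test requires a binary covariate")
        g0 = values[:, y == levels[0]]
        g1 = values[:, y == levels[1]]
        if g0.shape[1] < 2 or g1.shape[1] < 2:
            raise InputError("each group needs at least 2 samples")
        stat, p = sps.ttest_ind(g0, g1, axis=1, equal_var=False)
        # a taxon constant within and across groups: t = 0/0; report no evidence
        p = np.where(np.isnan(p), 1.0, p)
        stat = np.where(np.isnan(stat), 0.0, stat)
    else:
        if np.unique(y).size < 3:
            raise InputError("pearson requires a continuous covariate")
        n = y.size
        yc = y - y.mean()
        xc = values - values.mean(axis=1, keepdims=True)
        denom = np.sqrt((xc**2).sum(axis=1) * (yc @ yc))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, xc @ yc / denom, 0.0)
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * sps.t.sf(np.abs(t), df=n - 2)
        p = np.where(np.abs(r) >= 1.0, 0.0, p)
        stat = r

    raw_mask = p <= alpha
    bh_mask = _bh_reject(p, alpha)
    ids = nm.taxon_ids
    return TaxonTestResult(
        taxon_ids=ids,
        p_values=p,
        statistics=stat,
        rejections=frozenset(t_ for t_, k in zip(ids, raw_mask) if k),
        rejections_bh=frozenset(t_ for t_, k in zip(ids, bh_mask) if k),
        alpha=alpha,
        test=test,
        pseudo=used_pseudo,
    )


def fdp_and_sensitivity(
    rejections: frozenset[str] | set[str], truth: SimulationTruth
) -> tuple[float, float | None]:
    """Realized false-discovery proportion and sensitivity against truth.

    FDP = |rejections ∩ J0| / max(|rejections|, 1); sensitivity =
    |rejections ∩ J1| / |J1|, or None when no taxa are truly DA.
    """
    rejections = frozenset(rejections)
    known = truth.da_taxa | truth.nonda_taxa
    unknown = rejections - known
    if unknown:
        raise InputError(f"rejections contain unknown taxa: {sorted(unknown)[:5]}")
    fdp = len(rejections & truth.nonda_taxa) / max(len(rejections), 1)
    if len(truth.da_taxa) == 0:
        return fdp, None
    sensitivity = len(rejections & truth.da_taxa) / len(truth.da_taxa)
    return fdp, sensitivity


def _pseudo_f(sq_dist: np.ndarray, labels: np.ndarray) -> float:
    """Anderson's pseudo-F from a squared distance matrix and group labels."""
    n = labels.size
    ss_total = sq_dist[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        block = sq_dist[np.ix_(idx, idx)]
        ss_within += block[np.triu_indices(idx.size, k=1)].sum() / idx.size
    g = groups.size
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def permanova(
    nm: NormalizedMatrix,
    covariate: CovariateTable,
    n_permutations: int = 999,
    log_transform: bool = False,
    pseudo: float | None = None,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-group PERMANOVA on Euclidean distances of normalized values.

    Returns (pseudo_F, p).  When the number of distinct two-group label
    assignments is at most ``n_permutations`` the null distribution is
    enumerated exhaustively and p is the exact fraction of assignments
    with F >= observed; otherwise p uses the Monte-Carlo convention
    (1 + #{permuted F >= observed}) / (1 + n_permutations).

    The distance is computed on the normalized values directly by
    default.  A log(x + pseudo) transform is available but off: with a
    small pseudo-count it turns the depth-dependent zero pattern of
    sparse counts into a systematic location shift, which inflates the
    test whenever sequencing depth correlates with the grouping — the
    exact artifact normalization is meant to remove.
    """
    if n_permutations < 1:
        raise InputError("n_permutations must be >= 1")
    pos = {s: k for k, s in enumerate(covariate.sample_ids)}
    missing = [s for s in nm.sample_ids if s not in pos]
    if missing:
        raise InputError(f"covariate missing samples: {missing[:5]}")
    y = covariate.values[[pos[s] for s in nm.sample_ids]]
    levels = np.unique(y)
    if levels.size != 2:
        raise InputError("permanova here requires a binary covariate")
    labels = (y == levels[1]).astype(np.int64)
    n = labels.size
    n1 = int(labels.sum())
    if n1 < 2 or n - n1 < 2:
        raise InputError("each group needs at least 2 samples")

    values = nm.values
    if log_transform:
        values, _ = log_transform_values(values, pseudo)
    sq_dist = squareform(pdist(values.T, metric="sqeuclidean"))

    f_obs = _pseudo_f(sq_dist, labels)

    n_assignments = comb(n, n1)
    if n_assignments <= n_permutations:
        count = 0
        for members in combinations(range(n), n1):
            perm = np.zeros(n, dtype=np.int64)
            perm[list(members)] = 1
            if _pseudo_f(sq_dist, perm) >= f_obs - 1e-12:
                count += 1
        return f_obs, count / n_assignments

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if _pseudo_f(sq_dist, rng.permutation(labels)) >= f_obs - 1e-12:
            count += 1
    return f_obs, (1 + count) / (1 + n_permutations)


def pcoa_coordinates(
    nm: NormalizedMatrix,
    k: int = 2,
    log_transform: bool = True,
    pseudo: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Classical-scaling PCoA of Euclidean distances between samples.

    Gower-centers the squared distance matrix, eigendecomposes it, and
    returns up to ``k`` coordinate axes (eigenvectors scaled by the
    square roots of positive eigenvalues) together with the full sorted
    eigenvalue spectrum; axes with non-positive eigenvalues are dropped
    (Euclidean input yields none negative beyond round-off).
    """
    n = len(nm.sample_ids)
    if not 1 <= k <= n - 1:
        raise InputError(f"k must lie in [1, {n - 1}]")
    values = nm.values
    if log_transform:
        values, _ = log_transform_values(values, pseudo)
    sq = squareform(pdist(values.T, metric="sqeuclidean"))
    centering = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * centering @ sq @ centering
    eigvals, eigvecs = np.linalg.eigh(gower)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > max(eigvals.max(), 0) * 1e-12
    usable = min(k, int(positive.sum()))
    coords = eigvecs[:, :usable] * np.sqrt(eigvals[:usable])
    return coords, eigvals
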