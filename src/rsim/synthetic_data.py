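"""Multinomial count simulator with planted ground truth.

The generative model: every taxon j has a baseline absolute abundance
A_j drawn log-normally and shared across samples.  A minority of taxa
(the differentially abundant set J1) have their abundance multiplied by
``signal ** x_i``, where x_i is a per-sample latent variable — a binary
group label or a continuous Uniform(0, 1) draw.  Sample i's counts are
one multinomial draw of size N_i* (log-uniform sequencing depth) from
the sample's composition A_i. / sum_j A_ij.  The implied sampling
fraction is c_i = N_i* / sum_j A_ij, linking counts to absolute
abundance via N_ij ~ c_i * A_ij.

Every random choice flows from a single integer seed, and the planted
truth (abundances, sampling fractions, DA membership, latent values) is
returned alongside the counts so misclassification and recovery can be
scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_model import CountMatrix, CovariateTable
from .errors import InputError

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SIGNAL_PRESETS",
    "generate",
    "null_two_group",
]

# Fold-change presets for the differential-abundance signal strength.
SIGNAL_PRESETS = {"weak": 1.5, "moderate": 2.5, "strong": 4.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults give a strong-signal two-group study.

    ``prop_da`` must stay below 0.5: the method is only identifiable
    when more than half the taxa are non-differentially abundant.
    ``rarefy_group1`` subsamples group-1 samples after generation — an
    int is an absolute target depth, a float in (0, 1) a per-sample
    fraction of the realized depth.
    """

    d: int = 200
    n: int = 100
    prop_da: float = 0.1
    da_selection: str = "random"  # or "top_abundant"
    latent: str = "binary"  # "binary", "continuous", or "none"
    signal: float = 4.0
    group_balance: float = 0.5
    depth_range: tuple[float, float] = (2e3, 5e4)
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 2.0
    rarefy_group1: float | int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 3 or self.n < 3:
            raise InputError("need at least 3 taxa and 3 samples")
        if not 0.0 <= self.prop_da < 0.5:
            raise InputError(
                "prop_da must lie in [0, 0.5): more than half the taxa "
                "must be non-differentially abundant"
            )
        if self.signal < 1.0:
            raise InputError("signal must be >= 1 (a fold change)")
        if self.da_selection not in ("random", "top_abundant"):
            raise InputError(f"unknown da_selection {self.da_selection!r}")
        if self.latent not in ("binary", "continuous", "none"):
            raise InputError(f"unknown latent {self.latent!r}")
        if not 0.0 < self.group_balance < 1.0:
            raise InputError("group_balance must lie in (0, 1)")
        lo, hi = self.depth_range
        if lo <= 0 or hi < lo:
            raise InputError("depth_range must be positive and ordered")


@dataclass(frozen=True)
class SimulationTruth:
    """Planted ground truth for one simulated count matrix."""

    abundances: np.ndarray  # A_ij, taxa x samples
    sampling_fractions: np.ndarray  # c_i = realized depth / column abundance sum
    da_taxa: frozenset[str]
    nonda_taxa: frozenset[str]
    latent_values: np.ndarray
    group_labels: np.ndarray | None
    taxon_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "taxon_ids": list(self.taxon_ids),
            "sample_ids": list(self.sample_ids),
            "da_taxa": sorted(self.da_taxa),
            "nonda_taxa": sorted(self.nonda_taxa),
            "sampling_fractions": self.sampling_fractions.tolist(),
            "latent_values": self.latent_values.tolist(),
            "group_labels": None
            if self.group_labels is None
            else self.group_labels.astype(int).tolist(),
            "abundances": self.abundances.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        p = json.loads(Path(path).read_text())
        return cls(
            abundances=np.asarray(p["abundances"], dtype=np.float64),
            sampling_fractions=np.asarray(p["sampling_fractions"], dtype=np.float64),
            da_taxa=frozenset(p["da_taxa"]),
            nonda_taxa=frozenset(p["nonda_taxa"]),
            latent_values=np.asarray(p["latent_values"], dtype=np.float64),
            group_labels=None
            if p["group_labels"] is None
            else np.asarray(p["group_labels"], dtype=np.int64),
            taxon_ids=tuple(p["taxon_ids"]),
            sample_ids=tuple(p["sample_ids"]),
        )


def _rarefy_columns(
    counts: np.ndarray, columns: np.ndarray, target, rng: np.random.Generator
) -> np.ndarray:
    """Subsample selected columns without replacement; ints are absolute depths."""
    out = counts.copy()
    depths = counts.sum(axis=0)
    for i in columns:
        col = counts[:, i].astype(np.int64)
        depth_i = int(depths[i])
        if isinstance(target, float) and 0 < target < 1:
            goal = max(1, int(np.floor(target * depth_i)))
        else:
            goal = int(target)
        if goal > depth_i:
            raise InputError(
                f"rarefaction depth {goal} exceeds sample depth {depth_i}"
            )
        out[:, i] = rng.multivariate_hypergeometric(col, goal, method="marginals")
    return out


def generate(config: SimulationConfig) -> tuple[CountMatrix, SimulationTruth]:
    """Draw one count matrix and its planted truth from the model above."""
    rng = np.random.default_rng(config.seed)
    d, n = config.d, config.n
    taxon_ids = tuple(f"taxon_{j:04d}" for j in range(d))
    sample_ids = tuple(f"sample_{i:04d}" for i in range(n))

    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=d)

    n_da = int(round(config.prop_da * d))
    if config.da_selection == "random":
        da_idx = rng.choice(d, size=n_da, replace=False)
    else:
        da_idx = np.argsort(baseline)[::-1][:n_da]
    da_mask = np.zeros(d, dtype=bool)
    da_mask[da_idx] = True

    group_labels: np.ndarray | None = None
    if config.latent == "binary":
        n1 = int(round(config.group_balance * n))
        n1 = min(max(n1, 1), n - 1)
        perm = rng.permutation(n)
        group_labels = np.zeros(n, dtype=np.int64)
        group_labels[perm[:n1]] = 1
        latent = group_labels.astype(np.float64)
    elif config.latent == "continuous":
        latent = rng.uniform(0.0, 1.0, size=n)
    else:
        latent = np.zeros(n)

    abundances = np.tile(baseline[:, None], (1, n))
    abundances[da_mask, :] *= config.signal ** latent[None, :]

    lo, hi = config.depth_range
    depths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)).astype(np.int64)

    totals = abundances.sum(axis=0)
    counts = np.empty((d, n), dtype=np.float64)
    for i in range(n):
        counts[:, i] = rng.multinomial(depths[i], abundances[:, i] / totals[i])

    if config.rarefy_group1 is not None:
        if group_labels is None:
            raise InputError("rarefy_group1 requires a binary latent variable")
        cols = np.flatnonzero(group_labels == 1)
        counts = _rarefy_columns(counts, cols, config.rarefy_group1, rng)

    cm = CountMatrix(counts, taxon_ids, sample_ids)
    truth = SimulationTruth(
        abundances=abundances,
        sampling_fractions=cm.depths / totals,
        da_taxa=frozenset(taxon_ids[j] for j in np.flatnonzero(da_mask)),
        nonda_taxa=frozenset(taxon_ids[j] for j in np.flatnonzero(~da_mask)),
        latent_values=latent,
        group_labels=group_labels,
        taxon_ids=taxon_ids,
        sample_ids=sample_ids,
    )
    return cm, truth


def null_two_group(
    config: SimulationConfig,
) -> tuple[CountMatrix, CovariateTable, SimulationTruth]:
    """Null scenario: no DA taxa, random balanced groups, group 1 rarefied.

    Composition is identical in the two groups by construction, so any
    detected group association downstream is a false positive; the
    rarefaction makes sequencing depth a group-correlated confounder,
    the failure mode a good normalizer must absorb.
    """
    if config.prop_da != 0:
        raise InputError("null_two_group requires prop_da = 0")
    if config.rarefy_group1 is None:
        raise InputError("null_two_group requires rarefy_group1 to be set")
    if config.latent != "binary":
        raise InputError("null_two_group requires latent='binary'")
    cm, truth = generate(config)
    covariates = CovariateTable(cm.sample_ids, truth.group_labels.astype(np.float64))
    return cm, covariates, truth
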