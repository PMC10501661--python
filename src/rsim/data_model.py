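"""Core data containers and file I/O for taxa-by-samples count matrices.

The canonical in-memory orientation is taxa as rows and samples as
columns, the dominant OTU-table convention.  Counts are validated as
non-negative integers on construction but stored as 64-bit floats so
that downstream sums and products cannot overflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "CovariateTable",
    "NormalizedMatrix",
    "read_count_matrix",
    "write_normalized",
    "filter_taxa",
]


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise InputError(f"duplicate {what}: {dup[:5]}")


@dataclass(frozen=True)
class CountMatrix:
    """Observed sequencing counts N_ij with taxon and sample labels.

    Parameters
    ----------
    counts
        Non-negative integer-valued matrix, shape ``(d, n)`` for ``d``
        taxa and ``n`` samples.  Stored internally as float64.
    taxon_ids, sample_ids
        Unique row and column labels.
    """

    counts: np.ndarray
    taxon_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.float64)
        if counts.ndim != 2:
            raise InputError(f"counts must be 2-D, got shape {counts.shape}")
        if not np.all(np.isfinite(counts)):
            bad = np.argwhere(~np.isfinite(counts))[0]
            raise InputError(f"non-finite count at taxon row {bad[0]}, sample column {bad[1]}")
        if np.any(counts < 0):
            bad = np.argwhere(counts < 0)[0]
            raise InputError(
                f"negative count at taxon {self.taxon_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if np.any(counts != np.round(counts)):
            bad = np.argwhere(counts != np.round(counts))[0]
            raise InputError(
                f"non-integer count at taxon {self.taxon_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "taxon_ids", tuple(str(t) for t in self.taxon_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if len(self.taxon_ids) != counts.shape[0]:
            raise InputError(
                f"{len(self.taxon_ids)} taxon ids for {counts.shape[0]} rows"
            )
        if len(self.sample_ids) != counts.shape[1]:
            raise InputError(
                f"{len(self.sample_ids)} sample ids for {counts.shape[1]} columns"
            )
        _check_unique(self.taxon_ids, "taxon ids")
        _check_unique(self.sample_ids, "sample ids")

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def depths(self) -> np.ndarray:
        """Per-sample sequencing depths N_i* (column sums)."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.taxon_ids), columns=list(self.sample_ids)
        )

    def select_taxa(self, taxon_ids: Iterable[str]) -> "CountMatrix":
        """Row-subset by taxon id, preserving current order of the matrix."""
        wanted = set(taxon_ids)
        missing = wanted - set(self.taxon_ids)
        if missing:
            raise InputError(f"unknown taxon ids: {sorted(missing)[:5]}")
        idx = [k for k, t in enumerate(self.taxon_ids) if t in wanted]
        return CountMatrix(
            self.counts[idx, :],
            tuple(self.taxon_ids[k] for k in idx),
            self.sample_ids,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.taxon_ids == other.taxon_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class CovariateTable:
    """Per-sample outcome used in association / differential-abundance tests.

    ``values`` is numeric; a binary covariate must take exactly two
    distinct values (e.g. 0/1 group labels), a continuous one any reals.
    """

    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1:
            raise InputError("covariate values must be 1-D")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if len(self.sample_ids) != values.size:
            raise InputError("covariate length does not match sample ids")
        _check_unique(self.sample_ids, "sample ids")

    @property
    def is_binary(self) -> bool:
        return np.unique(self.values).size == 2

    def aligned_to(self, cm: CountMatrix) -> np.ndarray:
        """Covariate values reordered to match ``cm.sample_ids`` exactly."""
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        missing = [s for s in cm.sample_ids if s not in pos]
        if missing:
            raise InputError(f"covariate missing samples: {missing[:5]}")
        return self.values[[pos[s] for s in cm.sample_ids]]


@dataclass(frozen=True)
class NormalizedMatrix:
    """Rescaled counts plus the size factors and reference set behind them.

    ``values[j, i] = counts[j, i] / denominator_i`` where the per-sample
    denominator is proportional to ``size_factors[i]``; size factors are
    reported rescaled to geometric mean 1 (they are only defined up to a
    common multiplicative constant).
    """

    values: np.ndarray
    taxon_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    size_factors: np.ndarray
    reference_set: frozenset[str] | None = None
    method: str = "reference"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        sf = np.asarray(self.size_factors, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "size_factors", sf)
        object.__setattr__(self, "taxon_ids", tuple(str(t) for t in self.taxon_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if self.reference_set is not None:
            object.__setattr__(self, "reference_set", frozenset(self.reference_set))
        if values.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise InputError("normalized values shape does not match labels")
        if sf.shape != (len(self.sample_ids),):
            raise InputError("size factors length does not match samples")
        if np.any(sf <= 0) or not np.all(np.isfinite(sf)):
            raise InputError("size factors must be positive and finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.taxon_ids), columns=list(self.sample_ids)
        )


def read_count_matrix(
    path: str | Path,
    format: str | None = None,
    orientation: str = "taxa_by_samples",
) -> CountMatrix:
    """Read a labelled count table from TSV, CSV, or MatrixMarket triplet.

    For ``mtx`` input, companion label files ``<stem>.rows.txt`` and
    ``<stem>.cols.txt`` (one label per line) must sit next to the matrix
    file.  ``orientation`` names the layout *on disk*; the returned
    matrix is always taxa-by-samples.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(path.suffix, "tsv")
    if orientation not in ("taxa_by_samples", "samples_by_taxa"):
        raise InputError(f"unknown orientation {orientation!r}")

    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise InputError(f"empty table in {path}")
        try:
            mat = df.to_numpy(dtype=np.float64)
        except (TypeError, ValueError) as exc:
            raise InputError(f"non-numeric entries in {path}: {exc}") from exc
        row_ids = [str(x) for x in df.index]
        col_ids = [str(x) for x in df.columns]
    elif format == "mtx":
        from scipy.io import mmread

        mat = np.asarray(mmread(path).todense(), dtype=np.float64)
        rows_file = path.with_suffix("").with_suffix(".rows.txt")
        cols_file = path.with_suffix("").with_suffix(".cols.txt")
        if not rows_file.exists() or not cols_file.exists():
            raise InputError(
                f"mtx input needs label files {rows_file.name} and {cols_file.name}"
            )
        row_ids = rows_file.read_text().split()
        col_ids = cols_file.read_text().split()
    else:
        raise InputError(f"unknown format {format!r}")

    if orientation == "samples_by_taxa":
        mat = mat.T
        row_ids, col_ids = col_ids, row_ids
    return CountMatrix(mat, tuple(row_ids), tuple(col_ids))


def read_covariates(path: str | Path) -> CovariateTable:
    """Read a two-column TSV: sample id, covariate value (header optional)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise InputError("covariate table must have two columns: sample id, value")
    first = df.iloc[0, 1]
    try:
        float(first)
    except (TypeError, ValueError):
        df = df.iloc[1:, :]  # header row present
    return CovariateTable(
        tuple(str(s) for s in df.iloc[:, 0]),
        df.iloc[:, 1].astype(float).to_numpy(),
    )


def write_normalized(nm: NormalizedMatrix, path: str | Path) -> None:
    """Write a normalized matrix as full-precision TSV plus companions.

    Writes three files: ``<path>`` with the values, ``<stem>.factors.tsv``
    with per-sample size factors, and ``<stem>.reference.txt`` listing the
    reference-set taxon ids one per line (empty file when the method has
    no reference set).
    """
    if len(nm.taxon_ids) == 0:
        raise InputError("refusing to write an empty matrix (0 taxa)")
    path = Path(path)
    nm.to_frame().to_csv(path, sep="\t", float_format="%.15g")
    sf = pd.DataFrame(
        {"sample_id": list(nm.sample_ids), "size_factor": nm.size_factors}
    )
    sf.to_csv(path.with_suffix("").with_suffix(".factors.tsv"), sep="\t", index=False,
              float_format="%.15g")
    ref_path = path.with_suffix("").with_suffix(".reference.txt")
    ref = sorted(nm.reference_set) if nm.reference_set else []
    ref_path.write_text("".join(f"{t}\n" for t in ref))


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    """Write counts as an integer-valued TSV (taxa as rows)."""
    path = Path(path)
    df = cm.to_frame().astype(np.int64)
    df.to_csv(path, sep="\t")


def filter_taxa(cm: CountMatrix, min_prevalence: float = 0.0) -> CountMatrix:
    """Drop low-prevalence and constant taxa.

    A taxon is kept when its prevalence (fraction of samples with a
    positive count) is at least ``min_prevalence`` AND its counts are
    not constant across samples.  Constant taxa — all-zero ones
    included — are always removed because a rank correlation is
    undefined for a zero-variance vector.
    """
    if not 0.0 <= min_prevalence <= 1.0:
        raise InputError("min_prevalence must lie in [0, 1]")
    prevalence = (cm.counts > 0).mean(axis=1)
    constant = np.all(cm.counts == cm.counts[:, :1], axis=1)
    keep = (prevalence >= min_prevalence) & ~constant
    dropped = [t for t, k in zip(cm.taxon_ids, keep) if not k]
    if dropped:
        logger.info("filter_taxa dropped %d taxa: %s%s", len(dropped),
                    dropped[:10], "..." if len(dropped) > 10 else "")
    if not keep.any():
        raise InputError("no taxa survive filtering")
    return CountMatrix(
        cm.counts[keep, :],
        tuple(t for t, k in zip(cm.taxon_ids, keep) if k),
        cm.sample_ids,
    )
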