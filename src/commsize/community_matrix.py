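"""Taxon-by-sample count matrices.

The unit of analysis throughout the package is a matrix of non-negative
integer abundance counts with one row per collected sample and one column
per taxon.  "Sample size" always means the total number of individuals
counted in one sample (one row sum), never the number of samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CommunityMatrix",
    "SampleSummary",
    "MatrixValidationError",
    "read_matrix",
    "write_matrix",
    "pielou_evenness",
    "summarize",
    "drop_empty",
]


class MatrixValidationError(ValueError):
    """Raised when a count matrix violates the community-matrix contract."""


@dataclass(frozen=True)
class CommunityMatrix:
    """Samples x taxa non-negative integer counts with unique labels.

    Rows are samples, columns are taxa (the canonical orientation: each
    collected sample is one row).  Construction validates shape, sign,
    integrality and label uniqueness.
    """

    counts: np.ndarray
    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise MatrixValidationError("counts must be a 2-D array")
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            raise MatrixValidationError(
                f"need at least 2 samples and 2 taxa, got shape {counts.shape}"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                bad = np.argwhere(np.mod(counts, 1) != 0)[0]
                raise MatrixValidationError(
                    f"non-integer count at sample row {bad[0]}, taxon column {bad[1]}"
                    " (fractional abundances cannot be subsampled without replacement)"
                )
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            bad = np.argwhere(counts < 0)[0]
            raise MatrixValidationError(
                f"negative count at sample row {bad[0]}, taxon column {bad[1]}"
            )
        counts = np.ascontiguousarray(counts, dtype=np.int64)
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        sample_ids = tuple(str(s) for s in self.sample_ids)
        taxon_ids = tuple(str(t) for t in self.taxon_ids)
        if len(sample_ids) != counts.shape[0]:
            raise MatrixValidationError("sample_ids length does not match row count")
        if len(taxon_ids) != counts.shape[1]:
            raise MatrixValidationError("taxon_ids length does not match column count")
        if len(set(sample_ids)) != len(sample_ids):
            raise MatrixValidationError("duplicate sample_ids")
        if len(set(taxon_ids)) != len(taxon_ids):
            raise MatrixValidationError("duplicate taxon_ids")
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "taxon_ids", taxon_ids)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_totals(self) -> np.ndarray:
        """Per-sample size: total individuals counted in each row."""
        return self.counts.sum(axis=1)

    @property
    def empty_sample_ids(self) -> tuple[str, ...]:
        """Ids of samples whose row sum is zero."""
        totals = self.sample_totals
        return tuple(s for s, t in zip(self.sample_ids, totals) if t == 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.sample_ids), columns=list(self.taxon_ids)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CommunityMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.taxon_ids == other.taxon_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class SampleSummary:
    """Per-sample sizes and evenness plus their dataset-level summaries.

    ``evenness_per_sample`` holds Pielou's J for each sample; samples with a
    single taxon have undefined J (``None``) and are excluded from
    ``mean_evenness``.
    """

    sample_size_per_sample: tuple[int, ...]
    median_sample_size: float
    evenness_per_sample: tuple[float | None, ...]
    mean_evenness: float
    richness_per_sample: tuple[int, ...] = field(default=())

    def to_frame(self, sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
        n = len(self.sample_size_per_sample)
        idx = list(sample_ids) if sample_ids is not None else list(range(n))
        return pd.DataFrame(
            {
                "n_individuals": self.sample_size_per_sample,
                "richness": self.richness_per_sample,
                "pielou_j": [np.nan if j is None else j for j in self.evenness_per_sample],
            },
            index=idx,
        )


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","


def read_matrix(
    path: str | Path,
    orientation: str = "samples-as-rows",
    delimiter: str | None = None,
) -> CommunityMatrix:
    """Read a delimited taxon-by-sample count matrix.

    The first row holds column labels and the first column row labels.
    ``orientation`` states what the file's rows are; a taxa-as-rows file is
    transposed into the canonical samples-as-rows layout.  The delimiter is
    inferred from the extension (.tsv/.txt/.tab are tab; otherwise comma)
    unless given explicitly.
    """
    path = Path(path)
    if orientation not in {"samples-as-rows", "taxa-as-rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter), index_col=0)
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        r, c = np.argwhere(body.isna().to_numpy())[0]
        raise MatrixValidationError(
            f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r} in {path}"
        )
    if orientation == "taxa-as-rows":
        body = body.T
    return CommunityMatrix(
        counts=body.to_numpy(),
        sample_ids=tuple(str(i) for i in body.index),
        taxon_ids=tuple(str(c) for c in body.columns),
    )


def write_matrix(
    matrix: CommunityMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    """Write a matrix in the same layout :func:`read_matrix` expects."""
    path = Path(path)
    matrix.to_frame().to_csv(path, sep=_delimiter_for(path, delimiter))


def pielou_evenness(counts: Sequence[int] | np.ndarray) -> float | None:
    """Pielou's evenness J = H'/ln S for one sample's counts.

    H' is Shannon entropy over the taxa present (count > 0) and S their
    number.  Returns ``None`` (undefined) when S = 1, since ln S = 0.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("empty sample")
    if c.size == 1:
        return None
    p = c / c.sum()
    h = -np.sum(p * np.log(p))
    return float(h / np.log(c.size))


def summarize(matrix: CommunityMatrix) -> SampleSummary:
    """Row sums, their median, per-sample Pielou J and the mean of defined J.

    The median uses the mean-of-middle-two convention for an even number of
    samples.  ``mean_evenness`` averages per-sample J over samples where it
    is defined; it is NaN if no sample has >= 2 taxa.
    """
    totals = matrix.sample_totals
    evenness = tuple(
        None if t == 0 else pielou_evenness(row)
        for t, row in zip(totals, matrix.counts)
    )
    defined = [j for j in evenness if j is not None]
    return SampleSummary(
        sample_size_per_sample=tuple(int(t) for t in totals),
        median_sample_size=float(np.median(totals)),
        evenness_per_sample=evenness,
        mean_evenness=float(np.mean(defined)) if defined else float("nan"),
        richness_per_sample=tuple(int(r) for r in (matrix.counts > 0).sum(axis=1)),
    )


def drop_empty(matrix: CommunityMatrix) -> CommunityMatrix:
    """Remove all-zero taxon columns; never remove sample rows.

    Row count must be preserved so that paired comparisons between a
    complete dataset and its subsamples stay sample-aligned.  An all-zero
    sample row is kept and flagged with a warning.
    """
    keep = matrix.counts.sum(axis=0) > 0
    if matrix.empty_sample_ids:
        warnings.warn(
            f"matrix contains all-zero sample rows: {matrix.empty_sample_ids}",
            stacklevel=2,
        )
    if keep.all():
        return matrix
    return CommunityMatrix(
        counts=matrix.counts[:, keep],
        sample_ids=matrix.sample_ids,
        taxon_ids=tuple(t for t, k in zip(matrix.taxon_ids, keep) if k),
    )
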