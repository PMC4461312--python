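"""Without-replacement subsampling of community matrices.

Emulates returning to the field and collecting fewer individuals: each
sample (matrix row) is reduced to a fixed proportion of its original
size by drawing individuals uniformly without replacement from the
counted pool — a multivariate hypergeometric draw over taxa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .community_matrix import CommunityMatrix, drop_empty

__all__ = [
    "SubsampleScheme",
    "subsample_counts",
    "subsample_matrix",
    "replicate_stream",
]

DEFAULT_PROPORTIONS = (0.50, 0.25, 0.10, 0.05, 0.025)


@dataclass(frozen=True)
class SubsampleScheme:
    """Proportions and replicate count for a subsampling experiment.

    Defaults follow the five-proportion protocol (50%, 25%, 10%, 5%,
    2.5%) with 1000 replicate subsampled matrices per proportion.
    """

    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.proportions:
            raise ValueError("need at least one proportion")
        if any(not (0 < p <= 1) for p in self.proportions):
            raise ValueError("proportions must lie in (0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        object.__setattr__(self, "proportions", tuple(float(p) for p in self.proportions))


def subsample_counts(
    counts: Sequence[int] | np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw k individuals without replacement from one sample's counts.

    Uniform draw from the pool of sum(counts) individuals labelled by
    taxon, i.e. a multivariate hypergeometric sample: the output sums to
    k and no component exceeds its input.
    """
    c = np.asarray(counts)
    if (c < 0).any():
        raise ValueError("negative counts")
    total = int(c.sum())
    if not 0 <= k <= total:
        raise ValueError(f"k={k} outside [0, {total}]")
    return rng.multivariate_hypergeometric(c.astype(np.int64), k)


def _target_size(total: int, proportion: float) -> int:
    # round half-up, floored at 1 so no sample is emptied; an already
    # empty sample stays empty
    if total == 0:
        return 0
    return min(total, max(1, int(np.floor(proportion * total + 0.5))))


def subsample_matrix(
    matrix: CommunityMatrix, proportion: float, rng: np.random.Generator
) -> CommunityMatrix:
    """Subsample every row independently to round(p * row_sum), min 1.

    Row count and order are preserved (required for paired comparison
    with the complete dataset); taxon columns that end up all-zero are
    dropped.
    """
    if not 0 < proportion <= 1:
        raise ValueError("proportion must lie in (0, 1]")
    rows = [
        subsample_counts(row, _target_size(int(row.sum()), proportion), rng)
        for row in matrix.counts
    ]
    sub = CommunityMatrix(
        counts=np.vstack(rows), sample_ids=matrix.sample_ids, taxon_ids=matrix.taxon_ids
    )
    return drop_empty(sub)


def replicate_stream(
    matrix: CommunityMatrix, scheme: SubsampleScheme
) -> Iterator[tuple[float, int, CommunityMatrix]]:
    """Yield (proportion, replicate_index, subsampled matrix) lazily.

    Each replicate's generator seeds from (scheme.seed, proportion
    index, replicate index), so any single replicate is reproducible
    without replaying the stream and execution order is immaterial.
    """
    for p_idx, proportion in enumerate(scheme.proportions):
        for rep in range(scheme.n_replicates):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(scheme.seed), p_idx, rep])
            )
            yield proportion, rep, subsample_matrix(matrix, proportion, rng)
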