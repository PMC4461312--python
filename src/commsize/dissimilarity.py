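"""Pairwise sample dissimilarities.

Bray-Curtis is the primary measure; Euclidean, city-block and Raup-Crick
are provided for the distance-measure parity pilot.  All measures operate
on raw counts — no standardisation or transformation is applied anywhere
by default (ordination is run untransformed), though a relative-abundance
flag exists for exploration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .community_matrix import CommunityMatrix

__all__ = [
    "DissimilarityMatrix",
    "bray_curtis",
    "alt_dissimilarity",
    "MEASURES",
]

MEASURES = ("bray_curtis", "euclidean", "cityblock", "raup_crick")


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Square symmetric matrix of pairwise sample dissimilarities."""

    values: np.ndarray
    labels: tuple[str, ...]
    measure: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        if (v < 0).any():
            raise ValueError("dissimilarities must be non-negative")
        v = 0.5 * (v + v.T)  # exact symmetry
        np.fill_diagonal(v, 0.0)
        v.setflags(write=False)
        object.__setattr__(self, "values", v)
        labels = tuple(str(s) for s in self.labels)
        if len(labels) != v.shape[0]:
            raise ValueError("label count does not match matrix dimension")
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        """Upper off-diagonal entries in scipy condensed order."""
        return squareform(self.values, checks=False)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.values, index=list(self.labels), columns=list(self.labels)
        ).to_csv(path)


def _maybe_relative(counts: np.ndarray, relative: bool) -> np.ndarray:
    x = counts.astype(float)
    if relative:
        totals = x.sum(axis=1, keepdims=True)
        x = np.divide(x, totals, out=np.zeros_like(x), where=totals > 0)
    return x


def bray_curtis(matrix: CommunityMatrix, relative: bool = False) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity d(x, y) = sum|x_i - y_i| / sum(x_i + y_i).

    0 means identical composition, 1 means no shared individuals.  A pair
    of all-zero samples has an undefined (0/0) dissimilarity and raises.
    """
    totals = matrix.sample_totals
    if (totals == 0).sum() >= 2:
        empties = matrix.empty_sample_ids
        raise ValueError(
            f"undefined dissimilarity (0/0) between all-zero samples {empties}"
        )
    x = _maybe_relative(matrix.counts, relative)
    d = squareform(pdist(x, metric="braycurtis"))
    return DissimilarityMatrix(values=d, labels=matrix.sample_ids, measure="bray_curtis")


def _raup_crick(
    presence: np.ndarray, n_null: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo Raup-Crick on presence/absence.

    Null model: each sample's richness is fixed and its taxa are drawn
    equiprobably from the taxon pool; the dissimilarity of a pair is the
    null probability of sharing at least as many taxa as observed.  Under
    this null the shared-taxon count is hypergeometric, which is what the
    randomisation draws.
    """
    n, t = presence.shape
    rich = presence.sum(axis=1)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = int(np.sum(presence[i] & presence[j]))
            null = rng.hypergeometric(rich[i], t - rich[i], rich[j], size=n_null)
            d[i, j] = d[j, i] = np.mean(null >= shared)
    return d


def alt_dissimilarity(
    matrix: CommunityMatrix,
    measure: str,
    n_null: int = 999,
    seed: int = 0,
    relative: bool = False,
) -> DissimilarityMatrix:
    """Alternative measures for the parity pilot.

    euclidean = sqrt(sum (x_i - y_i)^2); cityblock = sum |x_i - y_i|;
    raup_crick = presence/absence null-model probability (see
    :func:`_raup_crick`), estimated with ``n_null`` Monte-Carlo draws and
    deterministic given ``seed``.
    """
    if measure == "bray_curtis":
        return bray_curtis(matrix, relative=relative)
    if measure in {"euclidean", "cityblock"}:
        x = _maybe_relative(matrix.counts, relative)
        d = squareform(pdist(x, metric=measure))
    elif measure == "raup_crick":
        rng = np.random.default_rng(seed)
        d = _raup_crick(matrix.counts > 0, n_null=n_null, rng=rng)
    else:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    return DissimilarityMatrix(values=d, labels=matrix.sample_ids, measure=measure)
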