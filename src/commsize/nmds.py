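"""Two-dimensional non-metric multidimensional scaling (NMDS).

Kruskal's rank-based ordination: find a planar configuration whose
inter-point distances are, as nearly as possible, a monotone function of
the input dissimilarities.  Badness of fit is Kruskal stress-1,

    stress = sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 ),

where d are configuration distances and dhat the least-squares monotone
(isotonic) fit of d against the dissimilarity ranks.  Minimisation uses
iterative majorisation (SMACOF with monotone regression) from several
random starting configurations plus one classical-scaling start; the
lowest-stress solution is returned, centred and rotated to its principal
axes.  Tied dissimilarities are averaged within tie blocks before the
monotone fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .dissimilarity import DissimilarityMatrix

__all__ = ["Ordination", "isotonic_fit", "stress1", "nmds"]

_EPS = 1e-12


@dataclass(frozen=True)
class Ordination:
    """An NMDS solution: centred coordinates plus its Kruskal stress-1."""

    coords: np.ndarray
    stress: float
    converged: bool
    n_starts: int
    best_start: int

    def __post_init__(self) -> None:
        c = np.ascontiguousarray(self.coords, dtype=float)
        c.setflags(write=False)
        object.__setattr__(self, "coords", c)

    @property
    def n_samples(self) -> int:
        return self.coords.shape[0]

    def to_frame(self, sample_ids=None):
        """Coordinates as a DataFrame (columns axis1, axis2, ...)."""
        import pandas as pd

        idx = list(sample_ids) if sample_ids is not None else list(range(self.n_samples))
        cols = [f"axis{k + 1}" for k in range(self.coords.shape[1])]
        return pd.DataFrame(self.coords, index=idx, columns=cols)

    def to_csv(self, path, sample_ids=None) -> None:
        """Write coordinates as CSV with a trailing stress comment line."""
        df = self.to_frame(sample_ids)
        with open(path, "w") as fh:
            df.to_csv(fh)
            fh.write(f"# stress = {self.stress:.6g}, converged = {self.converged}\n")


def isotonic_fit(dissimilarities: np.ndarray, distances: np.ndarray) -> np.ndarray:
    """Least-squares non-decreasing fit of distances against dissimilarity order.

    Inputs must already be sorted by ascending dissimilarity.  Tied
    dissimilarities form blocks whose distances are averaged before
    pool-adjacent-violators, so the fitted value is constant within a tie
    block (the block-averaged tie treatment).
    """
    d = np.asarray(dissimilarities, dtype=float)
    y = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty input")
    if d.shape != y.shape:
        raise ValueError("dissimilarities and distances must have equal length")
    if np.any(np.diff(d) < 0):
        raise ValueError("dissimilarities must be sorted ascending")
    # collapse tie blocks to weighted means
    block_start = np.flatnonzero(np.r_[True, np.diff(d) > 0])
    if block_start.size == d.size:  # no ties: plain PAV
        return np.asarray(isotonic_regression(y).x, dtype=float)
    counts = np.diff(np.r_[block_start, d.size])
    sums = np.add.reduceat(y, block_start)
    fit_blocks = isotonic_regression(sums / counts, weights=counts).x
    return np.repeat(np.asarray(fit_blocks, dtype=float), counts)


def _condensed(D: DissimilarityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(D, DissimilarityMatrix):
        d = D.condensed()
    else:
        arr = np.asarray(D, dtype=float)
        d = squareform(arr, checks=False) if arr.ndim == 2 else arr
    # jitter exact-zero dissimilarities between distinct samples so they
    # still receive a rank without dividing by zero downstream
    d = d.copy()
    d[d == 0] = _EPS
    return d


def stress1(coords: np.ndarray, D: DissimilarityMatrix | np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix.

    A degenerate configuration with all points coincident has stress 1 by
    convention (a warning is emitted).
    """
    X = np.asarray(coords, dtype=float)
    d = _condensed(D)
    if X.shape[0] * (X.shape[0] - 1) // 2 != d.size:
        raise ValueError("coords row count does not match dissimilarity dimension")
    dist = pdist(X)
    if np.all(dist < _EPS):
        warnings.warn("degenerate configuration: all points coincident", stacklevel=2)
        return 1.0
    order = np.argsort(d, kind="stable")
    dhat = np.empty_like(dist)
    dhat[order] = isotonic_fit(d[order], dist[order])
    return float(np.sqrt(np.sum((dist - dhat) ** 2) / np.sum(dist**2)))


def _classical_scaling(d: np.ndarray, n: int, dims: int) -> np.ndarray:
    """Torgerson metric scaling used as a deterministic warm start."""
    from scipy.spatial.distance import squareform

    D2 = squareform(d, checks=False) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:dims]
    vals = np.clip(vals[idx], 0.0, None)
    X = vecs[:, idx] * np.sqrt(vals)
    if X.shape[1] < dims:
        X = np.hstack([X, np.zeros((n, dims - X.shape[1]))])
    return X


def _smacof_single(
    d: np.ndarray,
    order: np.ndarray,
    X: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, bool]:
    """Monotone-regression SMACOF from one starting configuration."""
    n = X.shape[0]
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        dist = np.maximum(pdist(X), _EPS)
        dhat = np.empty_like(dist)
        dhat[order] = isotonic_fit(d[order], dist[order])
        ss_dist = np.sum(dist**2)
        stress = float(np.sqrt(np.sum((dist - dhat) ** 2) / ss_dist))
        if prev - stress < tol * max(prev, _EPS):
            converged = True
            break
        prev = stress
        # Guttman transform with disparities rescaled to the distance scale
        disp = dhat * np.sqrt(ss_dist / max(np.sum(dhat**2), _EPS))
        ratio = squareform(disp / dist, checks=False)
        B = -ratio
        np.fill_diagonal(B, ratio.sum(axis=1))
        X = (B @ X) / n
    final_dist = np.maximum(pdist(X), _EPS)
    dhat = np.empty_like(final_dist)
    dhat[order] = isotonic_fit(d[order], final_dist[order])
    final_stress = float(
        np.sqrt(np.sum((final_dist - dhat) ** 2) / np.sum(final_dist**2))
    )
    return X, final_stress, converged


def _principal_orientation(X: np.ndarray) -> np.ndarray:
    """Centre and rotate to principal axes with a deterministic sign."""
    X = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    X = X @ Vt.T
    for k in range(X.shape[1]):
        pivot = np.flatnonzero(np.abs(X[:, k]) > _EPS)
        if pivot.size and X[pivot[0], k] < 0:
            X[:, k] = -X[:, k]
    return X


def nmds(
    D: DissimilarityMatrix | np.ndarray,
    dims: int = 2,
    n_starts: int = 20,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
    init: np.ndarray | None = None,
) -> Ordination:
    """NMDS by stress-1 minimisation over multiple starts.

    Runs monotone-regression SMACOF from a classical-scaling start,
    ``n_starts`` random Gaussian starts and, optionally, a caller-supplied
    warm start, returning the lowest-stress solution.  Deterministic for a
    given seed.  ``converged`` is False when no start met the relative
    stress-improvement tolerance within ``max_iter`` sweeps.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    d = _condensed(D)
    n = int(round((1 + np.sqrt(1 + 8 * d.size)) / 2))
    order = np.argsort(d, kind="stable")
    rng = np.random.default_rng(seed)

    starts: list[np.ndarray] = [_classical_scaling(d, n, dims)]
    if init is not None:
        init = np.asarray(init, dtype=float)
        if init.shape != (n, dims):
            raise ValueError("init shape does not match (n_samples, dims)")
        starts.append(init)
    scale = max(float(np.median(d)), _EPS)
    starts.extend(rng.normal(scale=scale, size=(n, dims)) for _ in range(n_starts))

    best: tuple[float, int, np.ndarray, bool] | None = None
    for k, X0 in enumerate(starts):
        X, stress, conv = _smacof_single(d, order, X0, max_iter=max_iter, tol=tol)
        if best is None or stress < best[0] - 1e-15:
            best = (stress, k, X, conv)
    assert best is not None
    stress, k, X, conv = best
    return Ordination(
        coords=_principal_orientation(X),
        stress=stress,
        converged=conv,
        n_starts=len(starts),
        best_start=k,
    )
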