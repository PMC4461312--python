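"""Comparison statistics between a subsample and its complete dataset.

Two permutation tests quantify how well a subsampled community matrix
reproduces the complete dataset's multivariate structure:

* the Mantel test — Pearson correlation R between the off-diagonal
  entries of the two Bray-Curtis dissimilarity matrices, with a null
  distribution from jointly permuting the rows and columns of the second
  matrix; and
* PROTEST — Procrustes superimposition of the two NMDS ordinations
  (translation, reflection, rotation and dilation), summarised as a
  concordance on [0, 1] with 1 = identical ordinations, with a null from
  permuting the sample order of the second configuration.

Both report one-tailed p-values with the observed-included convention
p = (#{permuted >= observed} + 1) / (n_permutations + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform

from .dissimilarity import DissimilarityMatrix

__all__ = [
    "MantelResult",
    "ProtestResult",
    "ProcrustesTransform",
    "mantel",
    "procrustes",
    "protest",
]


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    undefined: bool = False


@dataclass(frozen=True)
class ProtestResult:
    """PROTEST outcome.

    ``concordance`` is 1 minus the Procrustes sum of squared residuals
    normalised by the total centred sum of squares, so it lies in [0, 1]
    with 1 meaning the ordinations are identical up to a similarity
    transform.
    """

    concordance: float
    ss_residual: float
    p_value: float
    n_permutations: int


@dataclass(frozen=True)
class ProcrustesTransform:
    """Similarity transform y -> scale * y @ rotation + translation."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape[0] != R.shape[1] or not np.allclose(R.T @ R, np.eye(R.shape[0]), atol=1e-10):
            raise ValueError("rotation must be orthogonal")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))

    def apply(self, Y: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(Y, dtype=float) @ self.rotation + self.translation


def _offdiag(D: DissimilarityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(D, DissimilarityMatrix):
        return D.condensed()
    return squareform(np.asarray(D, dtype=float), checks=False)


def _as_square(D: DissimilarityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(D, DissimilarityMatrix):
        return D.values
    return np.asarray(D, dtype=float)


def mantel(
    D1: DissimilarityMatrix | np.ndarray,
    D2: DissimilarityMatrix | np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Mantel permutation test of correlation between two dissimilarity matrices.

    R is the Pearson correlation of the vectorised upper off-diagonal
    entries.  The null distribution jointly relabels the rows and columns
    of ``D2`` (a single random relabelling of samples per permutation);
    the p-value is one-tailed for positive association.  If either
    off-diagonal vector has zero variance, R is undefined and flagged.
    """
    A = _as_square(D1)
    B = _as_square(D2)
    if A.shape != B.shape:
        raise ValueError("dissimilarity matrices must have the same dimension")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    if (
        isinstance(D1, DissimilarityMatrix)
        and isinstance(D2, DissimilarityMatrix)
        and D1.labels != D2.labels
    ):
        raise ValueError("sample orderings differ between the two matrices")
    v1 = squareform(A, checks=False)
    v2 = squareform(B, checks=False)
    s1, s2 = v1.std(), v2.std()
    if s1 < 1e-15 or s2 < 1e-15:
        return MantelResult(r=float("nan"), p_value=float("nan"),
                            n_permutations=0, undefined=True)
    z1 = (v1 - v1.mean()) / s1
    z2 = (v2 - v2.mean()) / s2
    m = v1.size
    r_obs = float(np.dot(z1, z2) / m)

    # A joint row/column relabelling of D2 permutes its off-diagonal
    # multiset, so the permuted vector is a re-indexing of z2: precompute
    # the pair -> condensed-index map once and gather per permutation,
    # in blocks to bound memory.
    idx = squareform(np.arange(m), checks=False).astype(np.intp)
    iu0, iu1 = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)
    count = 0
    block = max(1, int(4_000_000 // m))
    done = 0
    while done < n_permutations:
        nb = min(block, n_permutations - done)
        perms = np.argsort(rng.random((nb, n)), axis=1)
        gathered = z2[idx[perms[:, iu0], perms[:, iu1]]]  # (nb, m)
        r_perm = gathered @ z1 / m
        count += int(np.sum(r_perm >= r_obs - 1e-12))
        done += nb
    p = (count + 1) / (n_permutations + 1)
    return MantelResult(r=r_obs, p_value=float(p), n_permutations=n_permutations)


def _centred(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    Xc = X - mu
    norm = float(np.sqrt(np.sum(Xc**2)))
    return Xc, mu, norm


def procrustes(
    X: np.ndarray,
    Y: np.ndarray,
    scaling: str = "symmetric",
) -> tuple[ProcrustesTransform, np.ndarray, float]:
    """Least-squares superimposition of configuration Y onto X.

    Both configurations are centred; the optimal orthogonal map
    (reflections permitted) comes from the SVD of the cross-product and
    the optimal dilation in closed form.  With ``scaling="symmetric"``
    (default) both configurations are first normalised to unit centred sum
    of squares, making the residual — and hence the PROTEST concordance —
    symmetric in X and Y; ``scaling="best-fit"`` scales raw Y onto raw X.

    Returns the transform (expressed in the original coordinates of Y),
    the fitted Y and the sum of squared residuals on the fitting scale.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("configurations must have the same shape")
    if scaling not in {"symmetric", "best-fit"}:
        raise ValueError(f"unknown scaling {scaling!r}")
    Xc, mu_x, norm_x = _centred(X)
    Yc, mu_y, norm_y = _centred(Y)
    if norm_x < 1e-15 or norm_y < 1e-15:
        raise ValueError("degenerate configuration: all points identical")
    if scaling == "symmetric":
        Xs, Ys = Xc / norm_x, Yc / norm_y
    else:
        Xs, Ys = Xc, Yc
    A = Ys.T @ Xs
    U, s, Vt = np.linalg.svd(A)
    R = U @ Vt
    c = float(s.sum() / np.sum(Ys**2))
    fitted_s = c * Ys @ R
    ss_residual = float(np.sum((Xs - fitted_s) ** 2))
    # transform mapping the ORIGINAL Y into the frame of the fit target
    if scaling == "symmetric":
        total_scale = c / norm_y
        target_mu = np.zeros(X.shape[1])  # fit target is normalised, centred X
    else:
        total_scale = c
        target_mu = mu_x
    transform = ProcrustesTransform(
        rotation=R,
        scale=total_scale,
        translation=target_mu - total_scale * mu_y @ R,
    )
    return transform, fitted_s, ss_residual


def _concordance_stat(Xs: np.ndarray, Ys: np.ndarray) -> float:
    # both unit-normalised and centred: ss = 1 - (sum of singular values)^2
    s = np.linalg.svd(Ys.T @ Xs, compute_uv=False)
    return float(min(s.sum() ** 2, 1.0))


def protest(
    X: np.ndarray,
    Y: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
) -> ProtestResult:
    """Procrustean randomisation test between two ordinations.

    The observed concordance is 1 minus the symmetric Procrustes residual
    (normalised by the total centred sum of squares, so it lies in
    [0, 1]).  The null permutes the row (sample) order of Y and re-runs
    the superimposition; p is one-tailed with the observed-included
    convention.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("configurations must have the same shape")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    Xc, _, norm_x = _centred(X)
    Yc, _, norm_y = _centred(Y)
    if norm_x < 1e-15 or norm_y < 1e-15:
        raise ValueError("degenerate configuration: all points identical")
    Xs, Ys = Xc / norm_x, Yc / norm_y
    obs = _concordance_stat(Xs, Ys)
    rng = np.random.default_rng(seed)
    # batched: row-permuting Y leaves it centred and unit-norm, so the
    # statistic is the squared nuclear norm of each permuted cross-product
    perms = np.argsort(rng.random((n_permutations, n)), axis=1)
    cross = np.einsum("pnk,nl->pkl", Ys[perms], Xs)
    svals = np.linalg.svd(cross, compute_uv=False)
    null = np.minimum(svals.sum(axis=1) ** 2, 1.0)
    count = int(np.sum(null >= obs - 1e-12))
    p = (count + 1) / (n_permutations + 1)
    return ProtestResult(
        concordance=obs,
        ss_residual=float(1.0 - obs),
        p_value=float(p),
        n_permutations=n_permutations,
    )
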