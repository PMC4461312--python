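"""Generators for the two families of created community datasets.

1. Gradient-simulated communities: each taxon has a Gaussian response
   curve along a one-dimensional environmental gradient (a coenocline)
   with a random optimum (mu), tolerance (sigma) and peak abundance (A).
   Samples are taken at random positions along the gradient and each
   count is the height of the response curve at that position, rounded
   to an integer.

2. Selected-abundance datasets: every sample holds exactly 200
   individuals distributed over a fixed number of taxa as a geometric
   rank-abundance series whose decay is solved numerically to hit a
   target Pielou evenness (low ~ 0.58, high ~ 0.79, or alternating for
   mixed datasets).  Samples within a dataset differ by rotating which
   taxa receive which abundance ranks, emulating distinct communities
   along a compositional gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .community_matrix import CommunityMatrix, drop_empty, pielou_evenness, summarize

__all__ = [
    "GradientSpec",
    "SelectedSpec",
    "ParamRanges",
    "GradientDesignRow",
    "DEFAULT_GRADIENT_DESIGN",
    "taxon_response",
    "simulate_gradient_dataset",
    "random_gradient_spec",
    "build_selected_dataset",
    "selected_design_suite",
    "generate_suite",
]

#: targets matching the realised mean evenness of the low/high classes
LOW_EVENNESS_J = 0.58
HIGH_EVENNESS_J = 0.79
PER_SAMPLE_TOTAL = 200


def _round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass(frozen=True)
class ParamRanges:
    """Sampling ranges for random Gaussian response-curve parameters.

    sigma bounds are fractions of the gradient length; peak bounds are
    absolute abundances.
    """

    sigma_lo: float = 0.05
    sigma_hi: float = 0.25
    peak_lo: float = 1.0
    peak_hi: float = 100.0

    def __post_init__(self) -> None:
        if not (0 < self.sigma_lo <= self.sigma_hi):
            raise ValueError("need 0 < sigma_lo <= sigma_hi")
        if not (0 < self.peak_lo <= self.peak_hi):
            raise ValueError("need 0 < peak_lo <= peak_hi")


@dataclass(frozen=True)
class GradientSpec:
    """Fully resolved parameters of one gradient-simulated dataset."""

    gradient_length: int
    n_taxa: int
    n_samples: int
    taxon_params: tuple[tuple[float, float, float], ...]  # (mu, sigma, peak)
    position_mode: str = "unique-integer"
    seed: int = 0
    #: fixed sampling positions; when set, no positions are drawn
    positions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.positions is not None and len(self.positions) != self.n_samples:
            raise ValueError("positions length must equal n_samples")
        if self.gradient_length < 2:
            raise ValueError("gradient_length must be >= 2")
        if len(self.taxon_params) != self.n_taxa:
            raise ValueError("taxon_params length must equal n_taxa")
        for mu, sigma, peak in self.taxon_params:
            if sigma <= 0 or peak <= 0:
                raise ValueError("sigma and peak must be positive")
            if not (1 <= mu <= self.gradient_length):
                raise ValueError("mu must lie within [1, gradient_length]")
        if self.position_mode not in {"unique-integer", "uniform-real"}:
            raise ValueError(f"unknown position_mode {self.position_mode!r}")
        if self.position_mode == "unique-integer" and self.n_samples > self.gradient_length:
            raise ValueError(
                "unique-integer positions need n_samples <= gradient_length; "
                "use position_mode='uniform-real' for denser sampling"
            )


def taxon_response(g: float, mu: float, sigma: float, peak: float) -> float:
    """Gaussian response curve height at gradient position ``g``.

    The curve is scaled so its maximum is ``peak`` at g = mu: the taxon
    is most abundant at its environmental optimum and declines towards
    the tails of its tolerance range.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(peak * math.exp(-((g - mu) ** 2) / (2.0 * sigma**2)))


def random_gradient_spec(
    n_samples: int,
    n_taxa: int,
    gradient_length: int,
    seed: int = 0,
    ranges: ParamRanges = ParamRanges(),
) -> GradientSpec:
    """Draw random response-curve parameters for one dataset.

    mu ~ U(1, G); sigma ~ U(sigma_lo*G, sigma_hi*G); peak ~ U(peak_lo,
    peak_hi).  Position mode is unique-integer when n_samples <= G,
    otherwise uniform-real (sampling positions cannot all be distinct
    integers on a shorter gradient).
    """
    rng = np.random.default_rng(seed)
    G = gradient_length
    mus = rng.uniform(1.0, G, size=n_taxa)
    sigmas = rng.uniform(ranges.sigma_lo * G, ranges.sigma_hi * G, size=n_taxa)
    peaks = rng.uniform(ranges.peak_lo, ranges.peak_hi, size=n_taxa)
    mode = "unique-integer" if n_samples <= G else "uniform-real"
    return GradientSpec(
        gradient_length=G,
        n_taxa=n_taxa,
        n_samples=n_samples,
        taxon_params=tuple(zip(mus.tolist(), sigmas.tolist(), peaks.tolist())),
        position_mode=mode,
        seed=seed,
    )


def simulate_gradient_dataset(spec: GradientSpec, max_retries: int = 100) -> CommunityMatrix:
    """Sample the gradient at random positions and read off rounded counts.

    Positions are distinct integers in [1, G] (unique-integer mode) or
    i.i.d. uniform reals (uniform-real mode).  Counts are the response
    heights rounded half-up; all-zero taxon columns are dropped.  If a
    draw leaves any sample empty or fewer than two taxa observed, the
    positions are redrawn from the same stream (rare with default
    parameter ranges) so every dataset is analysable.
    """
    rng = np.random.default_rng(spec.seed)
    params = np.asarray(spec.taxon_params, dtype=float)
    mu, sigma, peak = params[:, 0], params[:, 1], params[:, 2]
    for _ in range(max_retries):
        if spec.positions is not None:
            positions = np.asarray(spec.positions, dtype=float)
        elif spec.position_mode == "unique-integer":
            positions = rng.choice(
                np.arange(1, spec.gradient_length + 1), size=spec.n_samples, replace=False
            ).astype(float)
        else:
            positions = rng.uniform(1.0, spec.gradient_length, size=spec.n_samples)
        heights = peak[None, :] * np.exp(
            -((positions[:, None] - mu[None, :]) ** 2) / (2.0 * sigma[None, :] ** 2)
        )
        counts = _round_half_up(heights).astype(np.int64)
        if (counts.sum(axis=1) > 0).all() and (counts.sum(axis=0) > 0).sum() >= 2:
            matrix = CommunityMatrix(
                counts=counts,
                sample_ids=tuple(f"s{i + 1:03d}" for i in range(spec.n_samples)),
                taxon_ids=tuple(f"t{j + 1:03d}" for j in range(spec.n_taxa)),
            )
            return drop_empty(matrix)
    raise RuntimeError(
        "could not draw a dataset without empty samples; widen the parameter ranges"
    )


# ---------------------------------------------------------------------------
# selected-abundance datasets


@dataclass(frozen=True)
class SelectedSpec:
    """Design of one selected-abundance dataset (200 individuals/sample)."""

    n_samples: int
    richness: int
    evenness_class: str  # low | high | mixed
    per_sample_total: int = PER_SAMPLE_TOTAL
    target_j: float | None = None
    structure_id: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.evenness_class not in {"low", "high", "mixed"}:
            raise ValueError(f"unknown evenness_class {self.evenness_class!r}")
        if self.richness < 2 or self.richness > self.per_sample_total:
            raise ValueError("need 2 <= richness <= per_sample_total")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.structure_id < 1:
            raise ValueError("structure_id must be >= 1")

    def targets(self) -> tuple[float, ...]:
        """Per-sample target J values (alternating for mixed datasets)."""
        if self.evenness_class == "mixed":
            return tuple(
                LOW_EVENNESS_J if i % 2 == 0 else HIGH_EVENNESS_J
                for i in range(self.n_samples)
            )
        j = self.target_j
        if j is None:
            j = LOW_EVENNESS_J if self.evenness_class == "low" else HIGH_EVENNESS_J
        return (j,) * self.n_samples


def _geometric_counts(richness: int, decay: float, total: int) -> np.ndarray:
    """Integerise a geometric rank-abundance series to sum exactly to ``total``.

    Every taxon receives at least one individual (richness is a design
    property of the sample); the remainder is allocated by largest
    remainder on the geometric weights.
    """
    w = decay ** np.arange(richness)
    w = w / w.sum()
    spare = total - richness
    raw = w * spare
    base = np.floor(raw).astype(np.int64)
    short = spare - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base + 1


def _solve_decay(richness: int, target_j: float, total: int) -> float:
    """Bisect the geometric decay so the integerised sample hits target J."""

    def realised(decay: float) -> float:
        j = pielou_evenness(_geometric_counts(richness, decay, total))
        return 1.0 if j is None else j

    lo, hi = 1e-4, 1.0
    j_lo, j_hi = realised(lo), realised(hi)
    if not (min(j_lo, j_hi) - 0.02 <= target_j <= max(j_lo, j_hi) + 0.02):
        raise ValueError(
            f"target J={target_j} unattainable at richness {richness} with "
            f"{total} individuals; attainable range ~[{j_lo:.3f}, {j_hi:.3f}]"
        )
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if realised(mid) < target_j:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def build_selected_dataset(spec: SelectedSpec) -> CommunityMatrix:
    """Construct one dataset with selected (deterministic) abundances.

    Each sample is a geometric rank-abundance series hitting its target
    evenness exactly at 200 individuals.  Samples represent distinct
    communities in two dichotomous groups: the second half of the
    samples shifts the whole composition by half the taxon pool, while
    within a group the dominant taxon stays put and the subordinate
    ranks rotate by ``structure_id`` positions per sample.  The result
    is a dataset with clear between-group and graded within-group
    compositional differences — structure a multivariate analysis can
    recover — rather than uniformly equidistant samples.
    """
    targets = spec.targets()
    decay_cache: dict[float, np.ndarray] = {}
    rows = []
    half = spec.n_samples // 2
    for i, tj in enumerate(targets):
        if tj not in decay_cache:
            decay = _solve_decay(spec.richness, tj, spec.per_sample_total)
            decay_cache[tj] = _geometric_counts(spec.richness, decay, spec.per_sample_total)
        ranks = decay_cache[tj]
        group = 0 if i < half else 1
        within = i if group == 0 else i - half
        tail = np.roll(ranks[1:], (within * spec.structure_id) % (spec.richness - 1))
        sample = np.roll(np.concatenate([ranks[:1], tail]), group * (spec.richness // 2))
        rows.append(sample)
    return CommunityMatrix(
        counts=np.vstack(rows),
        sample_ids=tuple(f"s{i + 1:03d}" for i in range(spec.n_samples)),
        taxon_ids=tuple(f"t{j + 1:03d}" for j in range(spec.richness)),
    )


def selected_design_suite(
    evenness_classes: Sequence[str] = ("low", "high", "mixed"),
    richness_levels: Sequence[int] = (10, 20, 50),
    sample_counts: Sequence[int] = (5, 10),
    structure_ids: Sequence[int] = (1, 2, 3, 4),
) -> list[SelectedSpec]:
    """Full-factorial suite of selected-abundance designs.

    Defaults give 24 datasets per evenness class (3 richness levels x 2
    sample counts x 4 community structures).
    """
    return [
        SelectedSpec(
            n_samples=ns, richness=r, evenness_class=ec, structure_id=sid
        )
        for ec in evenness_classes
        for r in richness_levels
        for ns in sample_counts
        for sid in structure_ids
    ]


# ---------------------------------------------------------------------------
# design-table driven generation


@dataclass(frozen=True)
class GradientDesignRow:
    """One row of the gradient experiment design."""

    n_samples: int
    n_taxa: int
    gradient_size: int
    replicates: int = 10
    label: str = ""


#: The 22-row gradient design (10 replicates each gives 220 datasets).
DEFAULT_GRADIENT_DESIGN: tuple[GradientDesignRow, ...] = tuple(
    GradientDesignRow(n_samples=ns, n_taxa=nt, gradient_size=g, label=f"row{k + 1:02d}")
    for k, (ns, nt, g) in enumerate(
        [
            (15, 15, 1000),
            (15, 15, 5000),
            (20, 20, 100),
            (20, 20, 5000),
            (20, 30, 100),
            (20, 40, 100),
            (20, 40, 100),
            (20, 50, 100),
            (20, 50, 100),
            (25, 100, 100),
            (30, 20, 100),
            (30, 60, 100),
            (40, 20, 100),
            (50, 20, 100),
            (50, 50, 100),
            (50, 50, 5000),
            (50, 75, 100),
            (50, 100, 100),
            (50, 200, 100),
            (75, 50, 100),
            (100, 50, 100),
            (200, 50, 100),
        ]
    )
)


def desk_scale_design(
    design: Iterable[GradientDesignRow] = DEFAULT_GRADIENT_DESIGN,
    replicates: int = 1,
    max_gradient: int | None = 100,
) -> list[GradientDesignRow]:
    """Reduce a design for desk-scale runs.

    Caps the gradient length (longer gradients only rescale the position
    and tolerance units, so G = 100 designs are statistically equivalent)
    and sets the per-row replicate count.
    """
    rows = []
    for row in design:
        g = row.gradient_size if max_gradient is None else min(row.gradient_size, max_gradient)
        rows.append(replace(row, gradient_size=g, replicates=replicates))
    return rows


def generate_suite(
    design: Iterable[GradientDesignRow],
    seed: int = 0,
    ranges: ParamRanges = ParamRanges(),
) -> tuple[dict[str, CommunityMatrix], pd.DataFrame]:
    """Generate one dataset per design row per replicate.

    Per-dataset seeds derive deterministically from (master seed, row
    index, replicate index); the returned manifest records them together
    with realised median sample size and mean evenness, so any dataset
    can be regenerated in isolation.
    """
    datasets: dict[str, CommunityMatrix] = {}
    manifest_rows = []
    for r_idx, row in enumerate(design):
        for rep in range(row.replicates):
            child_seed = np.random.SeedSequence([int(seed), r_idx, rep])
            spec_seed = int(child_seed.generate_state(1)[0] % (2**31))
            spec = random_gradient_spec(
                n_samples=row.n_samples,
                n_taxa=row.n_taxa,
                gradient_length=row.gradient_size,
                seed=spec_seed,
                ranges=ranges,
            )
            matrix = simulate_gradient_dataset(spec)
            label = row.label or f"row{r_idx + 1:02d}"
            dataset_id = f"{label}_rep{rep + 1:02d}"
            datasets[dataset_id] = matrix
            summary = summarize(matrix)
            manifest_rows.append(
                {
                    "dataset_id": dataset_id,
                    "row": r_idx,
                    "replicate": rep,
                    "n_samples": row.n_samples,
                    "n_taxa": row.n_taxa,
                    "gradient_size": row.gradient_size,
                    "seed": spec_seed,
                    "median_sample_size": summary.median_sample_size,
                    "mean_evenness": summary.mean_evenness,
                }
            )
    return datasets, pd.DataFrame(manifest_rows)
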