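"""Experiment orchestration: subsample, compare, aggregate, threshold.

The full protocol for one dataset: build its Bray-Curtis matrix and NMDS
ordination once, stream subsampled replicates at each proportion, and
compare every replicate back to the complete dataset with a Mantel test
(dissimilarity structure) and PROTEST (ordination structure).  Replicate
records are aggregated to mean +/- SD goodness-of-fit curves against
median subsample size, from which a plateau breakpoint — the sample size
below which the subsample stops reproducing the complete result — is
estimated by a two-segment piecewise-linear fit on log10 size.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .community_matrix import CommunityMatrix
from .dissimilarity import DissimilarityMatrix, bray_curtis
from .matrix_compare import mantel, protest
from .nmds import Ordination, nmds
from .subsampling import SubsampleScheme, replicate_stream

__all__ = [
    "NmdsSettings",
    "ExperimentSettings",
    "ComparisonRecord",
    "compare_one",
    "run_experiment",
    "records_to_frame",
    "aggregate",
    "ThresholdResult",
    "detect_threshold",
    "group_tests",
    "export_results",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NmdsSettings:
    """NMDS settings shared by the complete and subsampled ordinations.

    A single fixed seed is used for every ordination so that identical
    dissimilarity matrices yield bit-identical configurations (which
    makes the proportion-1.0 control comparison exact).  Subsample
    ordinations use fewer random restarts than a standalone analysis
    would; each still gets the deterministic classical-scaling start.
    """

    dims: int = 2
    n_starts: int = 1
    max_iter: int = 150
    tol: float = 1e-5
    seed: int = 0


@dataclass(frozen=True)
class ExperimentSettings:
    n_permutations: int = 999
    statistics: tuple[str, ...] = ("mantel", "protest")
    nmds: NmdsSettings = field(default_factory=NmdsSettings)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.statistics) - {"mantel", "protest"}
        if unknown:
            raise ValueError(f"unknown statistics {sorted(unknown)}")


@dataclass(frozen=True)
class ComparisonRecord:
    """One subsample replicate's goodness-of-fit against the complete data."""

    dataset_id: str
    proportion: float
    replicate: int
    median_subsample_size: float
    mantel_r: float = float("nan")
    mantel_p: float = float("nan")
    protest_concordance: float = float("nan")
    protest_p: float = float("nan")
    failed: bool = False
    note: str = ""


def _check_alignment(complete: CommunityMatrix, subsample: CommunityMatrix) -> None:
    if complete.sample_ids != subsample.sample_ids:
        raise ValueError("sample ids/order differ between complete and subsample")
    if not (subsample.counts.sum(axis=1) <= complete.counts.sum(axis=1)).all():
        raise ValueError("subsample has more individuals than the complete dataset")


def compare_one(
    complete: CommunityMatrix,
    subsample: CommunityMatrix,
    n_permutations: int = 999,
    nmds_settings: NmdsSettings = NmdsSettings(),
    seed: int = 0,
    dataset_id: str = "dataset",
    proportion: float = float("nan"),
    replicate: int = 0,
    statistics: Sequence[str] = ("mantel", "protest"),
    complete_D: DissimilarityMatrix | None = None,
    complete_ordination: Ordination | None = None,
) -> ComparisonRecord:
    """Compare one subsampled matrix to its complete dataset.

    Computes Mantel R between the two Bray-Curtis matrices and the
    PROTEST concordance between the two NMDS ordinations.  The complete
    dataset's dissimilarity matrix and ordination may be passed in when
    cached by the caller.
    """
    _check_alignment(complete, subsample)
    sub_D = bray_curtis(subsample)
    median_size = float(np.median(subsample.sample_totals))
    kwargs: dict[str, float] = {}
    if "mantel" in statistics:
        if complete_D is None:
            complete_D = bray_curtis(complete)
        res = mantel(complete_D, sub_D, n_permutations=n_permutations, seed=seed)
        if res.undefined:
            return ComparisonRecord(
                dataset_id, proportion, replicate, median_size,
                failed=True, note="mantel undefined (zero variance)",
            )
        kwargs["mantel_r"] = res.r
        kwargs["mantel_p"] = res.p_value
    if "protest" in statistics:
        if complete_ordination is None:
            complete_ordination = nmds(
                complete_D if complete_D is not None else bray_curtis(complete),
                dims=nmds_settings.dims,
                n_starts=nmds_settings.n_starts,
                max_iter=nmds_settings.max_iter,
                tol=nmds_settings.tol,
                seed=nmds_settings.seed,
            )
        sub_ord = nmds(
            sub_D,
            dims=nmds_settings.dims,
            n_starts=nmds_settings.n_starts,
            max_iter=nmds_settings.max_iter,
            tol=nmds_settings.tol,
            seed=nmds_settings.seed,
        )
        pres = protest(
            complete_ordination.coords,
            sub_ord.coords,
            n_permutations=n_permutations,
            seed=seed,
        )
        kwargs["protest_concordance"] = pres.concordance
        kwargs["protest_p"] = pres.p_value
    return ComparisonRecord(
        dataset_id=dataset_id,
        proportion=proportion,
        replicate=replicate,
        median_subsample_size=median_size,
        **kwargs,
    )


def run_experiment(
    datasets: Mapping[str, CommunityMatrix],
    scheme: SubsampleScheme,
    settings: ExperimentSettings = ExperimentSettings(),
) -> list[ComparisonRecord]:
    """Run the whole subsample-and-compare experiment.

    For each dataset the complete Bray-Curtis matrix and (if PROTEST is
    requested) its ordination are computed once and reused for every
    replicate.  Per-replicate permutation seeds derive from
    (settings.seed, dataset, proportion, replicate), so records are
    reproducible regardless of execution order.  A failing replicate is
    logged and recorded with ``failed=True`` rather than aborting.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    records: list[ComparisonRecord] = []
    for d_idx, (dataset_id, matrix) in enumerate(datasets.items()):
        complete_D = bray_curtis(matrix)
        complete_ord = None
        if "protest" in settings.statistics:
            complete_ord = nmds(
                complete_D,
                dims=settings.nmds.dims,
                n_starts=settings.nmds.n_starts,
                max_iter=settings.nmds.max_iter,
                tol=settings.nmds.tol,
                seed=settings.nmds.seed,
            )
        dataset_scheme = SubsampleScheme(
            proportions=scheme.proportions,
            n_replicates=scheme.n_replicates,
            seed=int(
                np.random.SeedSequence([int(scheme.seed), d_idx]).generate_state(1)[0]
                % (2**31)
            ),
        )
        for proportion, rep, sub in replicate_stream(matrix, dataset_scheme):
            p_idx = scheme.proportions.index(proportion)
            perm_seed = int(
                np.random.SeedSequence(
                    [int(settings.seed), d_idx, p_idx, rep]
                ).generate_state(1)[0]
                % (2**31)
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rec = compare_one(
                        matrix,
                        sub,
                        n_permutations=settings.n_permutations,
                        nmds_settings=settings.nmds,
                        seed=perm_seed,
                        dataset_id=dataset_id,
                        proportion=proportion,
                        replicate=rep,
                        statistics=settings.statistics,
                        complete_D=complete_D,
                        complete_ordination=complete_ord,
                    )
            except Exception as exc:  # degenerate replicate: record, not fatal
                logger.warning("replicate failed (%s %.3f #%d): %s",
                               dataset_id, proportion, rep, exc)
                rec = ComparisonRecord(
                    dataset_id, proportion, rep,
                    float(np.median(sub.sample_totals)),
                    failed=True, note=str(exc),
                )
            records.append(rec)
    return records


def records_to_frame(records: Iterable[ComparisonRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def aggregate(records: Iterable[ComparisonRecord] | pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD goodness-of-fit per dataset x proportion.

    Failed replicates are excluded (their count is reported in
    ``n_failed``).  SDs are sample standard deviations (ddof = 1, zero
    for a single replicate).
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise ValueError("no records to aggregate")

    def _agg(group: pd.DataFrame) -> pd.Series:
        ok = group[~group["failed"]]
        sd = lambda s: float(s.std(ddof=1)) if len(s) > 1 else 0.0  # noqa: E731
        return pd.Series(
            {
                "n_replicates": int(len(ok)),
                "n_failed": int(group["failed"].sum()),
                "median_size_mean": float(ok["median_subsample_size"].mean()),
                "median_size_sd": sd(ok["median_subsample_size"]),
                "mantel_mean": float(ok["mantel_r"].mean()),
                "mantel_sd": sd(ok["mantel_r"].dropna()),
                "protest_mean": float(ok["protest_concordance"].mean()),
                "protest_sd": sd(ok["protest_concordance"].dropna()),
            }
        )

    out = (
        df.groupby(["dataset_id", "proportion"], sort=True)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    return out


@dataclass(frozen=True)
class ThresholdResult:
    """Breakpoint of the plateau-then-decline goodness-of-fit curve."""

    statistic: str
    breakpoint_size: float
    plateau_value: float
    method: str
    right_slope: float
    no_plateau: bool
    no_breakpoint: bool


def detect_threshold(
    curves: pd.DataFrame,
    statistic: str = "mantel",
    slope_tol: float = 0.1,
    min_improvement: float = 0.05,
) -> ThresholdResult:
    """Two-segment piecewise-linear breakpoint on log10(median size).

    Pools all (dataset, proportion) mean points, grid-searches the
    breakpoint over observed sizes, and fits the continuous two-segment
    model by least squares.  The plateau value is the mean fitted value
    over the right segment.  If the right segment's slope (per decade of
    sample size) exceeds ``slope_tol`` in magnitude the result is
    flagged ``no_plateau``; if the piecewise fit improves on a single
    line by less than ``min_improvement`` (relative SSE) the curve is
    considered breakpoint-free.
    """
    col = {"mantel": "mantel_mean", "protest": "protest_mean"}.get(statistic)
    if col is None:
        raise ValueError(f"unknown statistic {statistic!r}")
    pts = curves[["median_size_mean", col]].dropna()
    x = np.log10(pts["median_size_mean"].to_numpy(dtype=float))
    y = pts[col].to_numpy(dtype=float)
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct median sizes")

    ones = np.ones_like(x)
    sse_line = float(np.linalg.lstsq(np.c_[ones, x], y, rcond=None)[1].sum())

    candidates = np.unique(x)[1:-1]  # keep >= 1 point strictly on each side
    best: tuple[float, float, np.ndarray] | None = None
    for b in candidates:
        design = np.c_[ones, np.minimum(x - b, 0.0), np.maximum(x - b, 0.0)]
        beta, res, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        sse = float(res.sum()) if res.size else float(np.sum((design @ beta - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, b, beta)
    assert best is not None
    sse_pw, b, beta = best
    right = x >= b
    fitted_right = beta[0] + beta[2] * np.maximum(x[right] - b, 0.0)
    right_slope = float(beta[2])
    no_breakpoint = (
        sse_line < 1e-12  # a single line already fits exactly
        or sse_line <= sse_pw * (1 + 1e-9)
        or (sse_line - sse_pw) / sse_line < min_improvement
    )
    plateau = float(np.mean(y)) if no_breakpoint else float(np.mean(fitted_right))
    return ThresholdResult(
        statistic=statistic,
        breakpoint_size=float(10**b),
        plateau_value=plateau,
        method="two-segment piecewise linear on log10 size",
        right_slope=right_slope,
        no_plateau=abs(right_slope) > slope_tol,
        no_breakpoint=no_breakpoint,
    )


def group_tests(
    values: pd.DataFrame,
    grouping: str,
    value_col: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Significance tests for group differences in goodness-of-fit.

    Two groups: Welch two-sample t-test.  Three or more: one-way ANOVA
    followed by Bonferroni-corrected pairwise Welch t-tests.  Degenerate
    groups (n < 2 or zero variance in both members of a pair) are
    flagged rather than fatal.
    """
    if grouping not in values.columns or value_col not in values.columns:
        raise ValueError("grouping or value column missing")
    groups = {k: g[value_col].dropna().to_numpy() for k, g in values.groupby(grouping)}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    names = sorted(groups)

    def _welch(a: np.ndarray, b: np.ndarray, label: str, n_comp: int = 1) -> dict:
        flag = ""
        if len(a) < 2 or len(b) < 2:
            flag = "degenerate group (n < 2)"
            t = p = float("nan")
        elif a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            flag = "zero variance in both groups"
            t, p = (0.0, 1.0) if np.isclose(a.mean(), b.mean()) else (float("inf"), 0.0)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        return {
            "test": "welch_t" if n_comp == 1 else "welch_t_bonferroni",
            "groups": label,
            "statistic": float(t),
            "p_value": float(p),
            "p_adjusted": float(min(p * n_comp, 1.0)) if np.isfinite(p) else float("nan"),
            "significant": bool(np.isfinite(p) and min(p * n_comp, 1.0) < alpha),
            "note": flag,
        }

    if len(names) == 2:
        a, b = groups[names[0]], groups[names[1]]
        rows.append(_welch(a, b, f"{names[0]} vs {names[1]}"))
    else:
        arrays = [groups[k] for k in names]
        if all(len(a) >= 2 for a in arrays):
            f, p = stats.f_oneway(*arrays)
        else:
            f, p = float("nan"), float("nan")
        rows.append(
            {
                "test": "anova",
                "groups": " vs ".join(str(n) for n in names),
                "statistic": float(f),
                "p_value": float(p),
                "p_adjusted": float(p),
                "significant": bool(np.isfinite(p) and p < alpha),
                "note": "" if np.isfinite(p) else "degenerate group (n < 2)",
            }
        )
        pairs = list(combinations(names, 2))
        for g1, g2 in pairs:
            rows.append(_welch(groups[g1], groups[g2], f"{g1} vs {g2}", n_comp=len(pairs)))
    return pd.DataFrame(rows)


def export_results(
    out_dir: str | Path,
    curves: pd.DataFrame | None = None,
    thresholds: Sequence[ThresholdResult] = (),
    tests: pd.DataFrame | None = None,
    records: pd.DataFrame | None = None,
    manifest: Mapping | None = None,
) -> dict[str, Path]:
    """Write curves/thresholds/tests/records as CSV plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if curves is not None:
        path = out / "curves.csv"
        curves.to_csv(path, index=False)
        written["curves"] = path
    tcols = ["statistic", "breakpoint_size", "plateau_value", "method",
             "right_slope", "no_plateau", "no_breakpoint"]
    path = out / "thresholds.csv"
    pd.DataFrame([asdict(t) for t in thresholds], columns=tcols).to_csv(path, index=False)
    written["thresholds"] = path
    if tests is not None:
        path = out / "group_tests.csv"
        tests.to_csv(path, index=False)
        written["group_tests"] = path
    if records is not None:
        path = out / "records.csv"
        records.to_csv(path, index=False)
        written["records"] = path
    if manifest is not None:
        path = out / "manifest.json"
        path.write_text(json.dumps(dict(manifest), indent=2, default=str))
        written["manifest"] = path
    return written
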