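"""Whole-genome-amplification evenness QC for single cells.

Two evenness metrics are computed from the log2 copy-number ratios of
adjacent fixed-size genomic bins: MAPD, the median of absolute adjacent-bin
differences, and CoV, the coefficient of variation (population SD / mean) of
those absolute differences.  Both increase with amplification unevenness.
They combine with mean depth and breadth of coverage into a composite score

    QC = 0.3 Depth/max(Depth) + 0.3 Coverage/max(Coverage)
       + 0.2 (1 - MAPD/max(MAPD)) + 0.2 (1 - CoV/max(CoV))

with maxima taken over the cohort; cells with QC > 0.5 are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

QC_WEIGHTS = (0.3, 0.3, 0.2, 0.2)
DEFAULT_BIN_SIZE = 100_000
DEFAULT_QC_THRESHOLD = 0.5


class EmptyRatioError(ValueError):
    """All bins have zero depth; no log2 ratios can be formed."""


class InsufficientBinsError(ValueError):
    """Fewer than two usable adjacent-bin pairs."""


class CohortMismatchError(ValueError):
    """A cell's metrics exceed the cohort maxima it is scored against."""


@dataclass
class CellQC:
    cell_id: str
    depth: float  # mean fold-coverage
    coverage: float  # fraction of genome with >= 1x
    mapd: float
    cov_metric: float
    qc_score: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.coverage <= 1:
            raise ValueError("coverage must lie in [0, 1]")
        if self.mapd < 0 or self.cov_metric < 0:
            raise ValueError("MAPD and CoV are non-negative")


def compute_bin_ratios(depths: np.ndarray, median_depth: float | None = None) -> np.ndarray:
    """log2(depth / median depth) per bin; zero-depth bins become NaN.

    ``median_depth`` defaults to the median over nonzero bins.
    """
    depths = np.asarray(depths, dtype=float)
    nonzero = depths[depths > 0]
    if nonzero.size == 0:
        raise EmptyRatioError("depth profile is all zero")
    if median_depth is None:
        median_depth = float(np.median(nonzero))
    if median_depth <= 0:
        raise ValueError("reference median depth must be positive")
    with np.errstate(divide="ignore"):
        ratios = np.log2(depths / median_depth)
    ratios[depths <= 0] = np.nan
    return ratios


def _adjacent_abs_diffs(ratios: np.ndarray) -> np.ndarray:
    """|r_{b+1} - r_b| over adjacent pairs where both bins are non-missing."""
    r = np.asarray(ratios, dtype=float)
    a, b = r[:-1], r[1:]
    ok = np.isfinite(a) & np.isfinite(b)
    return np.abs(b[ok] - a[ok])


def mapd(ratios: np.ndarray) -> float:
    """Median absolute pairwise difference of adjacent-bin log2 ratios."""
    diffs = _adjacent_abs_diffs(ratios)
    if diffs.size < 1 or np.isfinite(np.asarray(ratios, float)).sum() < 2:
        raise InsufficientBinsError("MAPD requires >= 2 usable adjacent bins")
    return float(np.median(diffs))


def cov_metric(ratios: np.ndarray) -> float:
    """Coefficient of variation (population SD / mean) of absolute adjacent diffs.

    A zero mean (perfectly even profile) is defined as CoV 0.
    """
    diffs = _adjacent_abs_diffs(ratios)
    if diffs.size < 1:
        raise InsufficientBinsError("CoV requires >= 2 usable adjacent bins")
    m = diffs.mean()
    if m == 0:
        return 0.0
    return float(diffs.std() / m)  # population SD (ddof=0)


def cohort_maxima(cells: list[CellQC]) -> dict[str, float]:
    return {
        "depth": max(c.depth for c in cells),
        "coverage": max(c.coverage for c in cells),
        "mapd": max(c.mapd for c in cells),
        "cov_metric": max(c.cov_metric for c in cells),
    }


def qc_score(cell: CellQC, maxima: dict[str, float]) -> float:
    """Composite QC score in [0, 1], weights 0.3/0.3/0.2/0.2.

    A zero cohort maximum for MAPD or CoV means every cell is perfectly even
    there, so the penalty term contributes its full weight.
    """
    if maxima["depth"] <= 0 or maxima["coverage"] <= 0:
        raise ValueError("cohort depth and coverage maxima must be positive")
    for key, val in (
        ("depth", cell.depth),
        ("coverage", cell.coverage),
        ("mapd", cell.mapd),
        ("cov_metric", cell.cov_metric),
    ):
        if val > maxima[key] * (1 + 1e-12):
            raise CohortMismatchError(
                f"cell {cell.cell_id}: {key}={val} exceeds cohort maximum {maxima[key]}"
            )
    w_d, w_c, w_m, w_v = QC_WEIGHTS
    score = w_d * cell.depth / maxima["depth"] + w_c * cell.coverage / maxima["coverage"]
    score += w_m * (1 - cell.mapd / maxima["mapd"]) if maxima["mapd"] > 0 else w_m
    score += w_v * (1 - cell.cov_metric / maxima["cov_metric"]) if maxima["cov_metric"] > 0 else w_v
    return float(score)


def score_cohort(cells: list[CellQC]) -> list[CellQC]:
    """Populate qc_score for every cell against the cohort maxima."""
    maxima = cohort_maxima(cells)
    for c in cells:
        c.qc_score = qc_score(c, maxima)
    return cells


def filter_cells(
    cells: list[CellQC], threshold: float = DEFAULT_QC_THRESHOLD
) -> tuple[list[CellQC], list[CellQC]]:
    """Split cells into (included, excluded) by strict QC > threshold."""
    if any(c.qc_score is None for c in cells):
        raise ValueError("qc_score not populated; call score_cohort first")
    included = [c for c in cells if c.qc_score > threshold]
    excluded = [c for c in cells if c.qc_score <= threshold]
    return included, excluded


def qc_table(cells: list[CellQC], threshold: float = DEFAULT_QC_THRESHOLD) -> pd.DataFrame:
    included, _ = filter_cells(cells, threshold)
    inc = {c.cell_id for c in included}
    return pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "depth": c.depth,
                "coverage": c.coverage,
                "mapd": c.mapd,
                "cov": c.cov_metric,
                "qc_score": c.qc_score,
                "included": c.cell_id in inc,
            }
            for c in cells
        ]
    )


def cell_qc_from_bins(cell_id: str, bins: pd.DataFrame) -> CellQC:
    """Derive a CellQC from a binned depth profile (chrom, start, end, depth)."""
    depths = bins["depth"].to_numpy(float)
    lengths = (bins["end"] - bins["start"]).to_numpy(float)
    mean_depth = float((depths * lengths).sum() / lengths.sum())
    coverage = float(lengths[depths >= 1].sum() / lengths.sum())
    ratios = compute_bin_ratios(depths)
    return CellQC(cell_id, mean_depth, coverage, mapd(ratios), cov_metric(ratios))
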