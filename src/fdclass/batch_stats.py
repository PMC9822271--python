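"""Batch-level statistics: type frequencies, adhesion-force histograms,
windowed temporal drift, success rate, and an RMS surface-roughness utility.

Percentages are computed over ALL recorded curves, artifacts included — the
success rate is defined with respect to the total number of F-d curves, not
only the analysable ones.  The drift profile measures, for each class and
each window of ``window_size`` consecutive curves, the difference between the
window percentage and the overall percentage; with equal partitioning windows
these deltas average exactly to zero per class, so any systematic trend along
the temporal series (tip degradation) shows up as a monotone drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import SUCCESS_CLASSES, CurveClass
from .preprocess import ParameterError

ALL_CODES = [c.value for c in CurveClass]


@dataclass(frozen=True)
class TypeDistribution:
    """Counts and percentages per curve class over one batch."""

    counts: dict
    percentages: dict
    n_total: int


@dataclass(frozen=True)
class DriftProfile:
    """Per-window, per-class deviation from the overall composition.

    ``deltas`` is a DataFrame (rows: window index, columns: class codes) of
    window percentage minus overall percentage; ``complete`` marks windows of
    exactly ``window_size`` curves (a trailing partial window is reported but
    flagged).
    """

    window_size: int
    deltas: pd.DataFrame
    complete: np.ndarray


def _class_codes(results: pd.DataFrame) -> pd.Series:
    codes = results["class_code"].dropna()
    bad = set(codes.unique()) - set(ALL_CODES)
    if bad:
        raise ValueError(f"unknown class codes in results: {sorted(bad)}")
    return codes


def type_distribution(results: pd.DataFrame) -> TypeDistribution:
    """Counts and percentages over all seven classes; errors on empty input."""
    if results is None or len(results) == 0:
        raise ValueError("cannot compute a type distribution of an empty results table")
    codes = _class_codes(results)
    if codes.empty:
        raise ValueError("results table contains no classified curves")
    n_total = int(len(codes))
    counts = {code: int((codes == code).sum()) for code in ALL_CODES}
    percentages = {code: 100.0 * counts[code] / n_total for code in ALL_CODES}
    return TypeDistribution(counts=counts, percentages=percentages, n_total=n_total)


def success_rate(dist: TypeDistribution) -> float:
    """Fraction of curves showing at least one specific interaction (Types 3-6)."""
    good = sum(dist.counts[c.value] for c in SUCCESS_CLASSES)
    return good / dist.n_total


def adhesion_histogram(results: pd.DataFrame, bin_width: float = 50.0, upper: float = 2100.0):
    """Histogram of maximum adhesion forces with half-open bins [lo, hi).

    Bins cover [0, upper) in steps of ``bin_width`` plus a final overflow bin
    [upper, inf); counts always sum to the number of curves.  The default
    50 pN width places the 200 and 650 pN class boundaries on bin edges.
    """
    if not bin_width > 0:
        raise ParameterError(f"bin_width must be positive, got {bin_width}")
    values = results["f_max_pN"].dropna().to_numpy(dtype=float) if len(results) else np.array([])
    edges = np.arange(0.0, upper + bin_width, bin_width)
    bins = np.append(edges, np.inf)
    counts, _ = np.histogram(values, bins=bins)
    return bins, counts


def drift_profile(results: pd.DataFrame, window_size: int = 50) -> DriftProfile:
    """Windowed composition drift along the temporal series.

    Results must be in temporal order; windows are consecutive and
    non-overlapping.  delta_pct = window percentage - overall percentage.
    """
    n = len(results)
    if window_size < 1:
        raise ParameterError("window_size must be >= 1")
    if window_size > n:
        raise ParameterError(f"window_size {window_size} exceeds batch size {n}")
    overall = type_distribution(results).percentages
    codes = results["class_code"].reset_index(drop=True)
    n_windows = int(np.ceil(n / window_size))
    rows, complete = [], []
    for w in range(n_windows):
        chunk = codes.iloc[w * window_size : (w + 1) * window_size].dropna()
        m = len(chunk)
        complete.append(m == window_size)
        rows.append(
            {code: 100.0 * (chunk == code).sum() / m - overall[code] for code in ALL_CODES}
        )
    deltas = pd.DataFrame(rows, columns=ALL_CODES)
    deltas.index.name = "window"
    return DriftProfile(
        window_size=window_size, deltas=deltas, complete=np.asarray(complete, dtype=bool)
    )


def rms_roughness(heightmap, plane_correct: bool = False) -> float:
    """RMS deviation of a 2-D height map (nm) about its mean or best-fit plane."""
    h = np.asarray(heightmap, dtype=float)
    if h.ndim != 2 or min(h.shape) < 2:
        raise ValueError("heightmap must be a 2-D grid of at least 2x2 values")
    if not np.all(np.isfinite(h)):
        raise ValueError("heightmap contains non-finite values")
    if plane_correct:
        ny, nx = h.shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        design = np.column_stack([xx.ravel(), yy.ravel(), np.ones(h.size)])
        coef, *_ = np.linalg.lstsq(design, h.ravel(), rcond=None)
        resid = h.ravel() - design @ coef
    else:
        resid = (h - h.mean()).ravel()
    return float(np.sqrt(np.mean(resid**2)))


def load_heightmap(path) -> np.ndarray:
    """Read a height map from a plain-text matrix or a single-channel TIFF."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        return np.asarray(tifffile.imread(path), dtype=float)
    return np.loadtxt(path, dtype=float)


def batch_report(
    results: pd.DataFrame, window_size: int = 50, bin_width: float = 50.0
) -> dict:
    """JSON-serializable summary: distribution, success rate, histogram, drift."""
    dist = type_distribution(results)
    bins, counts = adhesion_histogram(results, bin_width)
    drift = drift_profile(results, window_size)
    return {
        "n_total": dist.n_total,
        "counts": dist.counts,
        "percentages": dist.percentages,
        "success_rate": success_rate(dist),
        "histogram": {
            "bin_edges_pN": [float(b) if np.isfinite(b) else None for b in bins],
            "counts": [int(c) for c in counts],
        },
        "drift": [
            {
                "window": int(i),
                "complete": bool(drift.complete[i]),
                "delta_pct": {k: float(v) for k, v in row.items()},
            }
            for i, row in drift.deltas.iterrows()
        ],
    }
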