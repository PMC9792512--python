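"""Synaptic tenacity from tracked puncta, and puncta detection/measurement.

Synaptic tenacity — the capacity of individual synapses to hold on to
their molecular configuration — is quantified from time-lapse fluorescence
of tracked postsynaptic puncta: within an analysis window, the normalized
fluorescence of every punctum at increasing intervals Delta is regressed
on its fluorescence at the window start, and the coefficient of
determination R^2(Delta) measures how quickly the population scrambles
away from its initial configuration (R^2 = 1: frozen; R^2 -> 0: fully
reshuffled).

Trajectory tables are tidy with columns

    cell_id, punctum_id, condition, timepoint_h, fluorescence_au

Pipeline order: smooth (3-sample moving average) -> per-cell
normalization (divide by the cell's mean punctum fluorescence at a
reference time, compensating reporter-expression differences) ->
regression.

The imaging half implements the punctum quantification used throughout:
Mexican-hat (difference-of-Gaussians) filtering, strict local maxima
within a 5-pixel radius, and fixed-size square ROI intensity averages
with a saturation exclusion rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "smooth_trajectory",
    "normalize_per_cell",
    "TenacityCurve",
    "tenacity_curve",
    "mexican_hat",
    "detect_puncta",
    "measure_puncta",
    "puncta_timecourse",
]

TRAJECTORY_COLUMNS = ["cell_id", "punctum_id", "condition", "timepoint_h", "fluorescence_au"]


def smooth_trajectory(values, width: int = 3) -> np.ndarray:
    """Centered moving average with shrunken windows at the edges.

    ``width`` must be odd; series ends use whatever part of the window is
    available rather than padded data, so a constant series is preserved
    exactly and the output never leaves the input range.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D series")
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be an odd positive integer")
    if width > v.size:
        raise ValueError(f"smoothing width {width} exceeds series length {v.size}")
    return pd.Series(v).rolling(window=width, center=True, min_periods=1).mean().to_numpy()


def smooth_trajectories(traj: pd.DataFrame, width: int = 3) -> pd.DataFrame:
    """Apply :func:`smooth_trajectory` per punctum in a tidy trajectory table."""
    out = traj.sort_values(["condition", "cell_id", "punctum_id", "timepoint_h"]).copy()
    out["fluorescence_au"] = (
        out.groupby(["condition", "cell_id", "punctum_id"], observed=True)["fluorescence_au"]
        .transform(lambda s: smooth_trajectory(s.to_numpy(), width)))
    return out.reset_index(drop=True)


def normalize_per_cell(traj: pd.DataFrame, reference_time: float = 0.0) -> pd.DataFrame:
    """Divide every punctum's series by its cell's mean punctum fluorescence
    at ``reference_time`` (separately per condition/reporter).

    Compensates for cell-to-cell differences in reporter expression so data
    from different neurons and experiments can be pooled.  Raises, naming
    the cell, if a cell has no positive punctum value at the reference time.
    """
    ref = traj[traj["timepoint_h"] == reference_time]
    cell_mean = ref.groupby(["condition", "cell_id"])["fluorescence_au"].mean()
    all_cells = pd.MultiIndex.from_frame(
        traj[["condition", "cell_id"]].drop_duplicates())
    missing = all_cells.difference(cell_mean.index)
    if len(missing):
        cond, cell = missing[0]
        raise ValueError(f"cell {cell!r} ({cond}) has no punctum at t = {reference_time} h")
    bad = cell_mean[cell_mean <= 0]
    if len(bad):
        (cond, cell), _ = next(iter(bad.items())), None
        raise ValueError(f"cell {cell!r} ({cond}) has non-positive mean fluorescence "
                         f"at t = {reference_time} h")
    key = pd.MultiIndex.from_frame(traj[["condition", "cell_id"]])
    out = traj.copy()
    out["fluorescence_au"] = out["fluorescence_au"].to_numpy() / cell_mean.reindex(key).to_numpy()
    return out


@dataclass
class TenacityCurve:
    """R^2-vs-interval curve for one analysis window.

    ``table`` columns: delta_h, slope, intercept, r_squared, n.  NaN rows
    mark intervals where the regression was undefined (zero variance at
    the window start or fewer than 3 puncta).
    """

    window_start_h: float
    table: pd.DataFrame


def tenacity_curve(traj: pd.DataFrame, window_start: float = 0.0,
                   window_length: float = 24.0,
                   value_col: str = "fluorescence_au") -> TenacityCurve:
    """Regress punctum fluorescence at increasing intervals on the window start.

    For every interval Delta (one sample up to ``window_length`` hours)
    the values at ``window_start + Delta`` are regressed (OLS) across
    puncta on the values at ``window_start``; slope, intercept and R^2 are
    returned per Delta.  Input should already be smoothed and per-cell
    normalized.  Puncta missing either time point (e.g. eliminated) are
    dropped pairwise.
    """
    wide = traj.pivot_table(index=["condition", "cell_id", "punctum_id"],
                            columns="timepoint_h", values=value_col, aggfunc="mean")
    if window_start not in wide.columns:
        raise ValueError(f"no samples at window start t = {window_start} h")
    times = np.array(sorted(c for c in wide.columns
                            if window_start < c <= window_start + window_length))
    x_all = wide[window_start].to_numpy(dtype=float)
    rows = []
    for t in times:
        y = wide[t].to_numpy(dtype=float)
        mask = np.isfinite(x_all) & np.isfinite(y)
        x, yy = x_all[mask], y[mask]
        if x.size < 3 or np.ptp(x) == 0:
            rows.append({"delta_h": t - window_start, "slope": np.nan,
                         "intercept": np.nan, "r_squared": np.nan, "n": int(x.size)})
            continue
        if np.ptp(yy) == 0:
            # every punctum landed on the same value: perfectly predicted
            # iff it never moved at all
            r2 = 1.0 if np.allclose(yy, x) else 0.0
            slope = 1.0 if np.allclose(yy, x) else 0.0
            rows.append({"delta_h": t - window_start, "slope": slope,
                         "intercept": float(yy[0] - slope * x[0]),
                         "r_squared": r2, "n": int(x.size)})
            continue
        fit = stats.linregress(x, yy)
        rows.append({"delta_h": t - window_start, "slope": float(fit.slope),
                     "intercept": float(fit.intercept),
                     "r_squared": float(fit.rvalue ** 2), "n": int(x.size)})
    return TenacityCurve(window_start_h=float(window_start), table=pd.DataFrame(rows))


def mexican_hat(image: np.ndarray, sigma_inner: float = 1.5,
                sigma_outer: float = 3.0) -> np.ndarray:
    """Mexican-hat (difference-of-Gaussians) band-pass filter."""
    img = np.asarray(image, dtype=float)
    return (ndimage.gaussian_filter(img, sigma_inner)
            - ndimage.gaussian_filter(img, sigma_outer))


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    y, x = np.ogrid[-r:r + 1, -r:r + 1]
    return x * x + y * y <= r * r


def detect_puncta(image: np.ndarray, sigma_inner: float = 1.5,
                  sigma_outer: float = 3.0, radius: int = 5,
                  threshold: float | None = None) -> np.ndarray:
    """Detect fluorescent puncta as local maxima of the Mexican-hat-filtered image.

    A pixel is a detection if it is the maximum of the filtered image
    within a ``radius``-pixel (Euclidean) neighbourhood and exceeds
    ``threshold`` (default: mean + 3 SD of the filtered image).  Plateau
    ties within the radius are broken toward the lexicographically
    smallest (row, column) coordinate so the output is deterministic,
    in row-major order.  Returns an (n, 2) int array of (row, col).
    """
    if np.asarray(image).ndim != 2:
        raise ValueError("expected a 2-D intensity image")
    filt = mexican_hat(image, sigma_inner, sigma_outer)
    if threshold is None:
        threshold = float(filt.mean() + 3.0 * filt.std())
    foot = _disk(radius)
    local_max = ndimage.maximum_filter(filt, footprint=foot, mode="nearest")
    cand = np.argwhere((filt >= local_max) & (filt > threshold))
    # row-major greedy suppression of remaining ties within the radius
    kept: list[np.ndarray] = []
    r2 = radius * radius
    for c in cand:
        if all((c[0] - k[0]) ** 2 + (c[1] - k[1]) ** 2 > r2 for k in kept):
            kept.append(c)
    return np.array(kept, dtype=int).reshape(-1, 2)


def measure_puncta(image: np.ndarray, centers: np.ndarray, roi_size: int = 9,
                   saturation: float | None = None) -> pd.DataFrame:
    """Mean intensity of a square ROI centered on each punctum.

    ``roi_size`` x ``roi_size`` pixel boxes (default 9 x 9) are centered on
    each (row, col); boxes overhanging the image border are clipped to the
    available pixels and flagged.  ROIs containing any pixel at or above
    ``saturation`` are excluded (NaN mean, flagged) — puncta approaching
    detector saturation are not quantifiable.
    """
    img = np.asarray(image, dtype=float)
    if roi_size < 1:
        raise ValueError("roi_size must be >= 1")
    half = roi_size // 2
    rows = []
    for r, c in np.asarray(centers, dtype=int).reshape(-1, 2):
        if not (0 <= r < img.shape[0] and 0 <= c < img.shape[1]):
            raise ValueError(f"center ({r}, {c}) outside the image")
        r0, r1 = max(r - half, 0), min(r + half + 1, img.shape[0])
        c0, c1 = max(c - half, 0), min(c + half + 1, img.shape[1])
        roi = img[r0:r1, c0:c1]
        clipped = roi.size < roi_size * roi_size
        saturated = bool(saturation is not None and np.any(roi >= saturation))
        rows.append({"row": int(r), "col": int(c),
                     "roi_mean": np.nan if saturated else float(roi.mean()),
                     "clipped": bool(clipped), "excluded_saturation": saturated})
    return pd.DataFrame(rows, columns=["row", "col", "roi_mean", "clipped",
                                       "excluded_saturation"])


def puncta_timecourse(images, timepoints, normalization_time: float,
                      roi_size: int = 9, saturation: float | None = None,
                      **detect_kwargs) -> pd.DataFrame:
    """Puncta counts and mean fluorescence over an image series, normalized.

    Runs detection and ROI measurement on every image, then normalizes the
    per-timepoint punctum count and mean ROI fluorescence to their values
    at ``normalization_time``.  Raises if nothing is detected at the
    normalization time.
    """
    timepoints = [float(t) for t in timepoints]
    if len(images) != len(timepoints):
        raise ValueError("one timepoint per image required")
    if normalization_time not in timepoints:
        raise ValueError("normalization_time must be one of the timepoints")
    rows = []
    for img, t in zip(images, timepoints):
        centers = detect_puncta(img, **detect_kwargs)
        meas = measure_puncta(img, centers, roi_size=roi_size, saturation=saturation)
        ok = meas[~meas["excluded_saturation"]]
        rows.append({"timepoint_h": t, "count": int(len(ok)),
                     "mean_fluorescence": float(ok["roi_mean"].mean()) if len(ok) else np.nan})
    out = pd.DataFrame(rows)
    ref = out[out["timepoint_h"] == normalization_time].iloc[0]
    if ref["count"] == 0:
        raise ValueError(f"no puncta detected at normalization time {normalization_time} h")
    out["count_norm"] = out["count"] / ref["count"]
    out["fluorescence_norm"] = out["mean_fluorescence"] / ref["mean_fluorescence"]
    return out
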