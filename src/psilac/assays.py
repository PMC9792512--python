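"""Quantification of the functional readouts around the proteomics core.

Five small, self-contained procedures:

* :func:`suppression_fold` — protein-synthesis suppression from a
  HaloTag-ligand / mTurquoise2 dual-reporter assay: background-corrected
  per-cell fluorescence ratios, and the control/treated fold reduction
  that parameterizes the kinetic model (k = 1/fold).
* :func:`fm_release` — FM4-64 vesicle-recycling destaining: dim-bouton
  exclusion, fractional dye release and the responder rule.
* :func:`viability_ratio` — calcein/propidium-iodide live-cell fraction.
* :func:`activity_normalize` / :func:`activity_slope_test` — spontaneous
  network spike rates: baseline normalization and the paired comparison
  of pre/post treatment linear trends.
* :func:`flux_normalize` — extracellular-flux (OCR/ECAR) plate
  normalization with the standard mito-stress exclusion rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SuppressionResult",
    "suppression_fold",
    "FMReleaseResult",
    "fm_release",
    "ViabilityResult",
    "viability_ratio",
    "activity_normalize",
    "SlopeTestResult",
    "activity_slope_test",
    "FluxPlate",
    "FluxResult",
    "flux_normalize",
]


@dataclass
class SuppressionResult:
    fold: float
    per_cell: pd.DataFrame
    n_excluded: int


def suppression_fold(treated: pd.DataFrame, control: pd.DataFrame) -> SuppressionResult:
    """Fold reduction in protein synthesis from dual-reporter fluorescence.

    Input frames carry one row per cell with columns ``cell_id, jf_mean,
    mturq_mean, background_jf, background_mturq``.  Per cell the
    background-subtracted ratio (jf - bg_jf)/(mturq - bg_mturq) is formed
    (cells whose corrected mTurquoise signal is non-positive are excluded
    and counted); the fold suppression is the mean control ratio divided by
    the mean treated ratio.  Feed the result to
    :func:`psilac.kinetics.k_from_fold_suppression`.
    """
    frames, excluded = [], 0
    for label, df in (("treated", treated), ("control", control)):
        if df.empty:
            raise ValueError(f"no cells in the {label} group")
        jf = df["jf_mean"].to_numpy(dtype=float) - df["background_jf"].to_numpy(dtype=float)
        mt = df["mturq_mean"].to_numpy(dtype=float) - df["background_mturq"].to_numpy(dtype=float)
        ok = mt > 0
        excluded += int((~ok).sum())
        frames.append(pd.DataFrame({"cell_id": df["cell_id"].to_numpy()[ok],
                                    "group": label, "ratio": jf[ok] / mt[ok]}))
    per_cell = pd.concat(frames, ignore_index=True)
    means = per_cell.groupby("group")["ratio"].mean()
    if means.get("treated", 0) <= 0:
        raise ValueError("mean treated ratio is non-positive; fold undefined")
    return SuppressionResult(fold=float(means["control"] / means["treated"]),
                             per_cell=per_cell, n_excluded=excluded)


@dataclass
class FMReleaseResult:
    table: pd.DataFrame
    responder_pct: float
    mean_fraction: float
    n_excluded_baseline: int
    n_excluded_zero_load: int


def fm_release(traces: pd.DataFrame, baseline_min: float = 600.0,
               responder_threshold: float = 0.15,
               background: float = 0.0) -> FMReleaseResult:
    """Fractional FM4-64 dye release per bouton, with exclusion rules.

    ``traces`` has one row per bouton: ``bouton_id, field_id,
    baseline_mean, load_value, unload_value``.  Boutons with mean baseline
    fluorescence below ``baseline_min`` AU (default 600) are too dim to
    quantify and are excluded, as are boutons with zero load.  The
    fraction released is (load - unload)/load, optionally after
    subtracting a constant ``background`` from both values; a bouton
    responded to the unloading stimulus if its fraction exceeds
    ``responder_threshold`` (default 15%, above the 8-12% dimming seen
    from washout and bleaching alone).
    """
    df = traces.copy()
    dim = df["baseline_mean"].to_numpy(dtype=float) < baseline_min
    n_dim = int(dim.sum())
    df = df[~dim].copy()
    load = df["load_value"].to_numpy(dtype=float) - background
    unload = df["unload_value"].to_numpy(dtype=float) - background
    zero = load <= 0
    n_zero = int(zero.sum())
    df = df[~zero].copy()
    load, unload = load[~zero], unload[~zero]
    df["fraction_released"] = (load - unload) / load
    df["responder"] = df["fraction_released"] > responder_threshold
    n = len(df)
    return FMReleaseResult(
        table=df.reset_index(drop=True),
        responder_pct=float(100.0 * df["responder"].mean()) if n else np.nan,
        mean_fraction=float(df["fraction_released"].mean()) if n else np.nan,
        n_excluded_baseline=n_dim, n_excluded_zero_load=n_zero)


@dataclass
class ViabilityResult:
    mean: float
    sem: float
    per_field: pd.DataFrame
    n_skipped: int


def viability_ratio(counts: pd.DataFrame) -> ViabilityResult:
    """Live-cell fraction per field: calcein-positive / (calcein + PI).

    Fields with zero total count are skipped and counted.  The summary is
    the mean fraction over fields with its standard error (SD/sqrt(n)).
    """
    total = counts["n_calcein"].to_numpy(dtype=float) + counts["n_pi"].to_numpy(dtype=float)
    skip = total == 0
    if skip.all():
        raise ValueError("every field has zero total cell count")
    df = counts[~skip].copy()
    df["live_fraction"] = df["n_calcein"] / (df["n_calcein"] + df["n_pi"])
    n = len(df)
    sem = float(df["live_fraction"].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    return ViabilityResult(mean=float(df["live_fraction"].mean()), sem=sem,
                           per_field=df.reset_index(drop=True), n_skipped=int(skip.sum()))


def activity_normalize(series, baseline_bins: int = 180) -> np.ndarray:
    """Normalize a binned spike-count series to its baseline mean.

    ``baseline_bins`` is the number of leading bins forming the reference
    window (default 180 one-minute bins = the first 3 hours; for slowly
    perfused preparations use the first 24 h).  Raises on a non-positive
    baseline mean.
    """
    v = np.asarray(series, dtype=float)
    if baseline_bins < 1 or baseline_bins > v.size:
        raise ValueError("baseline window must be non-empty and within the series")
    base = v[:baseline_bins].mean()
    if base <= 0:
        raise ValueError("baseline mean spike rate is non-positive")
    return v / base


@dataclass
class SlopeTestResult:
    slopes: pd.DataFrame
    t_statistic: float
    p_value: float


def activity_slope_test(experiments: Sequence, pre_window: tuple[int, int],
                        post_window: tuple[int, int]) -> SlopeTestResult:
    """Paired comparison of activity trends before and after treatment.

    For each experiment's normalized rate series a line is fitted (OLS on
    the bin index) separately within the pre- and post-treatment windows
    (half-open bin ranges); the per-experiment slope pairs are compared by
    a two-sided paired t-test.  With fewer than 2 experiments the p-value
    is undefined (NaN).
    """
    rows = []
    for i, series in enumerate(experiments):
        v = np.asarray(series, dtype=float)
        pair = {}
        for name, (a, b) in (("pre", tuple(pre_window)), ("post", tuple(post_window))):
            if not (0 <= a < b <= v.size):
                raise ValueError(f"{name} window ({a}, {b}) outside the series")
            x = np.arange(a, b)
            pair[name] = float(stats.linregress(x, v[a:b]).slope)
        rows.append({"experiment": i, "pre_slope": pair["pre"], "post_slope": pair["post"]})
    slopes = pd.DataFrame(rows)
    if len(slopes) < 2:
        return SlopeTestResult(slopes=slopes, t_statistic=np.nan, p_value=np.nan)
    diff = slopes["post_slope"] - slopes["pre_slope"]
    if np.allclose(diff, 0):
        return SlopeTestResult(slopes=slopes, t_statistic=0.0, p_value=1.0)
    t, p = stats.ttest_rel(slopes["post_slope"], slopes["pre_slope"])
    return SlopeTestResult(slopes=slopes, t_statistic=float(t), p_value=float(p))


@dataclass
class FluxPlate:
    """One extracellular-flux plate: wells x measurement cycles.

    ``values`` is a DataFrame indexed by well id with one column per
    measurement cycle (0-based, in acquisition order).  ``background_wells``
    are cell-free perimeter wells; ``injections`` maps compound name
    ('oligomycin', 'fccp', 'rot_aa', optionally '2dg') to the first cycle
    index after that injection.  Cycles before the first injection are the
    baseline (``baseline_cycles`` of them, default 5).
    """

    values: pd.DataFrame
    background_wells: frozenset = field(default_factory=frozenset)
    baseline_cycles: int = 5
    injections: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        bg = frozenset(self.background_wells)
        object.__setattr__(self, "background_wells", bg)
        if not bg <= set(self.values.index):
            raise ValueError("background wells must be wells of the plate")
        if self.baseline_cycles < 5:
            raise ValueError("need at least 5 baseline cycles")


@dataclass
class FluxResult:
    normalized: pd.DataFrame
    flags: pd.DataFrame
    n_excluded: int


def flux_normalize(plate: FluxPlate, fccp_factor: float = 1.1,
                   rotaa_factor: float = 0.9) -> FluxResult:
    """Background- and baseline-normalize a flux plate and flag failed wells.

    Per cycle the mean of the background wells is subtracted; each sample
    well is then divided by its own 5th baseline measurement (the most
    stable baseline cycle) and expressed in percent, so every retained
    well reads exactly 100% at that cycle.  Wells are flagged and excluded
    when the pharmacology clearly failed to arrive: OCR *increased* after
    oligomycin (post-oligomycin mean above the baseline mean), no FCCP
    response (post-FCCP mean <= ``fccp_factor`` x post-oligomycin mean),
    no rotenone/antimycin-A response (post-Rot/AA mean >=
    ``rotaa_factor`` x post-oligomycin mean), or a non-positive 5th
    baseline measurement after background subtraction.
    """
    for name in ("oligomycin", "fccp", "rot_aa"):
        if name not in plate.injections:
            raise ValueError(f"injection {name!r} not annotated on the plate")
    vals = plate.values.astype(float)
    sample_wells = [w for w in vals.index if w not in plate.background_wells]
    bg = vals.loc[list(plate.background_wells)].mean(axis=0) if plate.background_wells else 0.0
    corrected = vals.loc[sample_wells] - bg
    ref = corrected.iloc[:, plate.baseline_cycles - 1]

    n_cycles = corrected.shape[1]
    starts = dict(plate.injections)
    order = sorted(starts, key=starts.get)
    windows = {}
    for i, name in enumerate(order):
        stop = starts[order[i + 1]] if i + 1 < len(order) else n_cycles
        windows[name] = (starts[name], stop)

    flags = pd.DataFrame(False, index=sample_wells,
                         columns=["excluded_nonpositive_baseline",
                                  "increased_after_oligomycin",
                                  "no_fccp_response", "no_rotaa_response"])
    pct = 100.0 * corrected.div(ref, axis=0)
    flags["excluded_nonpositive_baseline"] = ref <= 0
    base_mean = pct.iloc[:, :plate.baseline_cycles].mean(axis=1)
    post = {name: pct.iloc[:, slice(*win)].mean(axis=1) for name, win in windows.items()}
    flags["increased_after_oligomycin"] = post["oligomycin"] > base_mean
    flags["no_fccp_response"] = post["fccp"] <= fccp_factor * post["oligomycin"]
    flags["no_rotaa_response"] = post["rot_aa"] >= rotaa_factor * post["oligomycin"]
    flags.loc[flags["excluded_nonpositive_baseline"],
              ["increased_after_oligomycin", "no_fccp_response", "no_rotaa_response"]] = False

    excluded = flags.any(axis=1)
    return FluxResult(normalized=pct.loc[~excluded], flags=flags,
                      n_excluded=int(excluded.sum()))
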