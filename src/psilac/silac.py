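"""Dynamic-SILAC differential-loss pipeline.

Operates on tidy :class:`pandas.DataFrame` tables.  Peptide-level input
carries one row per H/M ratio measurement with columns

    protein_id, experiment_id, timepoint_h, ratio_hm [, peptide_id]

and protein-level estimates (the pipeline currency) carry

    protein_id, experiment_id, timepoint_h, log2_ratio, n_peptides

Pipeline order: :func:`aggregate_peptides` (peptide -> protein per
experiment x time point, median of peptide log2 ratios) ->
:func:`normalize_to_reference` (subtract the per experiment x time point
median log2 ratio of a set of abundant long-lived reference proteins) ->
:func:`filter_stringent` (minimum peptide / experiment support) ->
:func:`volcano` (fold change vs two-sided t-test) and the downstream
model comparison, ranking and enrichment-term post-filtering steps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import expected_log2_ratio

__all__ = [
    "DEFAULT_REFERENCE_PROTEINS",
    "aggregate_peptides",
    "normalize_to_reference",
    "filter_stringent",
    "protein_means",
    "VolcanoResult",
    "volcano",
    "ModelComparison",
    "compare_to_model",
    "rank_proteins",
    "GroupRankSummary",
    "group_rank_summary",
    "filter_enrichment_terms",
]

#: Abundant, particularly long-lived proteins used for H/M normalization
#: (versican, B-type lamins, two nucleoporins, the two macro-H2A histones).
DEFAULT_REFERENCE_PROTEINS = frozenset(
    {"Vcan", "Lmnb1", "Lmnb2", "Nup155", "Nup205", "Macroh2a1", "Macroh2a2"}
)

ESTIMATE_COLUMNS = ["protein_id", "experiment_id", "timepoint_h", "log2_ratio", "n_peptides"]


def aggregate_peptides(peptides: pd.DataFrame) -> pd.DataFrame:
    """Combine peptide H/M ratios into per protein x experiment x time point estimates.

    The combined log2 ratio is the **median** of the peptide log2 ratios
    (robust to single-peptide outliers); the peptide count is recorded in
    ``n_peptides``.
    """
    if peptides.empty:
        raise ValueError("no peptide records to aggregate")
    if np.any(peptides["ratio_hm"].to_numpy(dtype=float) <= 0):
        raise ValueError("H/M ratios must be positive")
    df = peptides.assign(log2_ratio=np.log2(peptides["ratio_hm"].to_numpy(dtype=float)))
    grouped = df.groupby(["protein_id", "experiment_id", "timepoint_h"], sort=True,
                         observed=True)["log2_ratio"]
    out = grouped.agg(log2_ratio="median", n_peptides="size").reset_index()
    return out[ESTIMATE_COLUMNS]


def normalize_to_reference(estimates: pd.DataFrame,
                           reference_ids: Iterable[str] = DEFAULT_REFERENCE_PROTEINS
                           ) -> pd.DataFrame:
    """Subtract the reference-protein median log2 ratio per experiment x time point.

    Corrects for unequal mixing of the treated and control extracts: within
    every experiment x time point cell, the median log2 ratio of the
    reference proteins (abundant, long-lived, hence expected at log2 = 0)
    is subtracted from every protein's log2 ratio.  Raises if some cell has
    no reference protein; warns if part of the reference set is absent from
    the table altogether.
    """
    ref_ids = set(reference_ids)
    if not ref_ids:
        raise ValueError("reference set must be non-empty")
    present = set(estimates["protein_id"].unique()) & ref_ids
    if not present:
        raise ValueError("none of the reference proteins occur in the table")
    if present != ref_ids:
        warnings.warn(
            f"{len(ref_ids - present)} of {len(ref_ids)} reference proteins absent "
            f"from the table: {sorted(ref_ids - present)}", stacklevel=2)

    ref = estimates[estimates["protein_id"].isin(ref_ids)]
    med = ref.groupby(["experiment_id", "timepoint_h"])["log2_ratio"].median()
    cells = estimates.groupby(["experiment_id", "timepoint_h"]).size()
    missing = cells.index.difference(med.index)
    if len(missing):
        exp, tp = missing[0]
        raise ValueError(
            f"no reference protein measured in experiment {exp!r} at {tp} h "
            f"({len(missing)} cell(s) affected)")

    key = pd.MultiIndex.from_frame(estimates[["experiment_id", "timepoint_h"]])
    offset = med.reindex(key).to_numpy()
    out = estimates.copy()
    out["log2_ratio"] = out["log2_ratio"].to_numpy() - offset
    return out


def filter_stringent(estimates: pd.DataFrame, min_peptides: int = 5,
                     min_experiments: int = 3) -> pd.DataFrame:
    """Keep protein x time point entries with enough peptide and experiment support.

    A protein is retained at a time point only if, summed over experiments,
    it was quantified from at least ``min_peptides`` peptide pairs and
    measured in at least ``min_experiments`` experiments (defaults follow
    the "minimum of 5 peptide pairs from at least 3 experiments" rule).
    Filtering is applied independently per protein per time point.
    """
    if min_peptides < 1 or min_experiments < 1:
        raise ValueError("thresholds must be >= 1")
    if estimates.empty:
        return estimates.copy()
    grp = estimates.groupby(["protein_id", "timepoint_h"], observed=True)
    support = grp.agg(n_peptides_total=("n_peptides", "sum"),
                      n_experiments=("experiment_id", "nunique"))
    ok = support[(support["n_peptides_total"] >= min_peptides)
                 & (support["n_experiments"] >= min_experiments)].index
    key = pd.MultiIndex.from_frame(estimates[["protein_id", "timepoint_h"]])
    return estimates[key.isin(ok)].reset_index(drop=True)


def protein_means(estimates: pd.DataFrame) -> pd.DataFrame:
    """Per protein x time point mean log2 ratio across experiments."""
    out = (estimates.groupby(["protein_id", "timepoint_h"], observed=True)
           .agg(mean_log2=("log2_ratio", "mean"),
                n_experiments=("experiment_id", "nunique"),
                n_peptides_total=("n_peptides", "sum"))
           .reset_index())
    return out


def _wide(estimates: pd.DataFrame, timepoint: float) -> pd.DataFrame:
    sub = estimates[estimates["timepoint_h"] == timepoint]
    return sub.pivot_table(index="protein_id", columns="experiment_id",
                           values="log2_ratio", aggfunc="mean")


@dataclass
class VolcanoResult:
    """Volcano classification of per-protein loss at each time point.

    ``records`` has one row per protein x time point with the log2 fold
    change versus t = 0, the t-test p-value, the two pass flags, the class
    label and a per-protein ``is_hit_4and8`` flag (significant and above
    threshold at both 4 h and 8 h; such proteins are highlighted at every
    time point).  ``magnitude_threshold`` is twice the standard deviation
    of the per-protein mean log2 ratios at t = 0.
    """

    records: pd.DataFrame
    magnitude_threshold: float
    t0_sd: float
    alpha: float


def volcano(estimates: pd.DataFrame, alpha: float = 0.05,
            timepoints: Iterable[float] = (2.0, 4.0, 8.0),
            paired: bool = False, welch: bool = False,
            fdr: bool = False) -> VolcanoResult:
    """Classify per-protein loss: fold change vs statistical significance.

    For every protein at every requested time point the log2 fold change is
    the mean log2 ratio over experiments minus the mean at t = 0, and the
    p-value comes from a two-sided two-sample t-test on the per-experiment
    values (pooled variance by default — exact at the small repeat numbers
    of such designs; ``welch=True`` drops the equal-variance assumption and
    ``paired=True`` pairs on experiment id).  A change is
    biologically relevant if |log2 FC| exceeds twice the SD of the t = 0
    population of per-protein means (at t = 0 any departure from H/M = 1 is
    measurement noise), and statistically significant if p <= ``alpha``
    (raw p-values by default; ``fdr=True`` applies Benjamini-Hochberg per
    time point).  Proteins clearing both bars at both 4 h and 8 h are the
    high-confidence hits.
    """
    w0 = _wide(estimates, 0.0)
    if w0.empty:
        raise ValueError("volcano requires estimates at t = 0")
    t0_means = w0.mean(axis=1)
    t0_sd = float(t0_means.std(ddof=1))
    threshold = 2.0 * t0_sd

    frames = []
    for tp in timepoints:
        wt = _wide(estimates, float(tp))
        common = wt.index.intersection(w0.index)
        if len(common) == 0:
            continue
        a = wt.loc[common]
        b = w0.loc[common]
        fc = a.mean(axis=1) - b.mean(axis=1)
        if paired:
            cols = a.columns.intersection(b.columns)
            d = (a[cols] - b[cols]).to_numpy(dtype=float)
            n_pairs = np.isfinite(d).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = stats.ttest_rel(a[cols].to_numpy(dtype=float),
                                        b[cols].to_numpy(dtype=float),
                                        axis=1, nan_policy="omit").pvalue
            enough = n_pairs >= 2
        else:
            av, bv = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
            na = np.isfinite(av).sum(axis=1)
            nb = np.isfinite(bv).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = stats.ttest_ind(av, bv, axis=1, equal_var=not welch,
                                        nan_policy="omit").pvalue
            enough = (na >= 2) & (nb >= 2)
        p = np.asarray(p, dtype=float)
        p[~enough] = np.nan
        if fdr:
            finite = np.isfinite(p)
            if finite.any():
                p_adj = p.copy()
                p_adj[finite] = _benjamini_hochberg(p[finite])
                p = p_adj
        frames.append(pd.DataFrame({
            "protein_id": common,
            "timepoint_h": float(tp),
            "log2_fc": fc.to_numpy(dtype=float),
            "p_value": p,
        }))
    if not frames:
        raise ValueError("no overlapping proteins between t = 0 and the requested timepoints")
    rec = pd.concat(frames, ignore_index=True)
    rec["passes_magnitude"] = np.abs(rec["log2_fc"].to_numpy()) > threshold
    rec["passes_significance"] = rec["p_value"].to_numpy() <= alpha
    both = rec["passes_magnitude"] & rec["passes_significance"]

    hit_at = rec[both].groupby("protein_id")["timepoint_h"].agg(set)
    hits = set(hit_at[hit_at.apply(lambda s: {4.0, 8.0} <= s)].index)
    rec["is_hit_4and8"] = rec["protein_id"].isin(hits)
    rec["klass"] = np.where(both & rec["is_hit_4and8"], "hit_4and8",
                            np.where(both, "significant", "not_significant"))
    return VolcanoResult(records=rec, magnitude_threshold=threshold,
                         t0_sd=t0_sd, alpha=alpha)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    n = p.size
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class ModelComparison:
    """Measured vs model-expected log2 ratios, with half-life-stratified correlations."""

    table: pd.DataFrame
    correlations: pd.DataFrame
    n_missing_halflife: int


def compare_to_model(estimates: pd.DataFrame, half_lives: Mapping[str, float] | pd.Series,
                     k: float, timepoints: Iterable[float] = (2.0, 4.0, 8.0),
                     strata_max_days: Iterable[float] = (2.0, 10.0)) -> ModelComparison:
    """Compare measured mean log2 ratios to the first-order model prediction.

    For every protein with a known half-life the expected log2(H/M) is
    computed from the decay model at the given fractional synthesis rate
    ``k``; Pearson correlations between measured and expected values are
    reported per time point within half-life strata (by default proteins
    with t_half <= 2 days and <= 10 days, where PSI-induced loss is large
    enough to rise above measurement noise).  Strata with fewer than 3
    proteins get no correlation (NaN).
    """
    hl = pd.Series(half_lives, dtype=float)
    if np.any(hl <= 0):
        raise ValueError("half-lives must be positive")
    means = protein_means(estimates)
    means = means[means["timepoint_h"].isin([float(t) for t in timepoints])]
    n_missing = int((~means["protein_id"].isin(hl.index)).sum())
    tab = means[means["protein_id"].isin(hl.index)].copy()
    tab["t_half_days"] = hl.reindex(tab["protein_id"]).to_numpy()
    tab["expected_log2"] = expected_log2_ratio(
        tab["timepoint_h"].to_numpy(dtype=float), tab["t_half_days"].to_numpy(), k)

    rows = []
    for tp in timepoints:
        sub = tab[tab["timepoint_h"] == float(tp)]
        for max_days in strata_max_days:
            sel = sub[sub["t_half_days"] <= max_days]
            if len(sel) >= 3 and sel["mean_log2"].std() > 0 and sel["expected_log2"].std() > 0:
                r = float(np.corrcoef(sel["mean_log2"], sel["expected_log2"])[0, 1])
            else:
                r = np.nan
            rows.append({"timepoint_h": float(tp), "stratum_max_days": float(max_days),
                         "n": int(len(sel)), "pearson_r": r})
    corr = pd.DataFrame(rows)
    return ModelComparison(table=tab.reset_index(drop=True), correlations=corr,
                           n_missing_halflife=n_missing)


def rank_proteins(estimates: pd.DataFrame,
                  timepoints: Iterable[float] = (2.0, 4.0, 8.0),
                  require_all: bool = False) -> pd.DataFrame:
    """Rank proteins by loss (most decreased = rank 1) and average over time points.

    Per time point, proteins are ranked ascending by their mean log2 ratio
    (ties get the average rank).  The per-protein mean rank over the time
    points where the protein was measured is reported together with its
    log10.  ``require_all=True`` drops proteins missing any time point.
    """
    means = protein_means(estimates)
    tps = [float(t) for t in timepoints]
    parts = []
    for tp in tps:
        sub = means[means["timepoint_h"] == tp]
        if sub.empty:
            continue
        ranks = stats.rankdata(sub["mean_log2"].to_numpy(), method="average")
        parts.append(pd.DataFrame({"protein_id": sub["protein_id"].to_numpy(),
                                   "timepoint_h": tp, "rank": ranks}))
    if not parts:
        raise ValueError("no estimates at the requested timepoints")
    long = pd.concat(parts, ignore_index=True)
    agg = long.groupby("protein_id", observed=True)["rank"].agg(["mean", "size"])
    agg.columns = ["mean_rank", "n_timepoints"]
    if require_all:
        agg = agg[agg["n_timepoints"] == len(tps)]
    agg["log10_rank"] = np.log10(agg["mean_rank"].to_numpy())
    return agg.reset_index()


@dataclass
class GroupRankSummary:
    """Per-annotation-group rank summary (e.g. SynGO-style synaptic categories)."""

    summary: pd.DataFrame
    members: pd.DataFrame


def group_rank_summary(ranks: pd.DataFrame,
                       groups: Mapping[str, Iterable[str]]) -> GroupRankSummary:
    """Summarize average-loss ranks within named protein groups.

    For each group the member proteins' log10 mean ranks are listed and
    averaged; a protein belonging to several groups is counted in each.
    Groups with no ranked member are reported with count 0 and NaN mean.
    """
    if not groups:
        raise ValueError("no annotation groups provided")
    idx = ranks.set_index("protein_id")["log10_rank"]
    member_rows, summary_rows = [], []
    for name, members in groups.items():
        found = idx.reindex(sorted(set(members))).dropna()
        for pid, lr in found.items():
            member_rows.append({"group": name, "protein_id": pid, "log10_rank": float(lr)})
        summary_rows.append({
            "group": name,
            "n_members": int(found.size),
            "mean_log10_rank": float(found.mean()) if found.size else np.nan,
        })
    return GroupRankSummary(summary=pd.DataFrame(summary_rows),
                            members=pd.DataFrame(member_rows,
                                                 columns=["group", "protein_id", "log10_rank"]))


def filter_enrichment_terms(terms: pd.DataFrame, top_fraction: float = 0.25,
                            timepoints: Iterable[float] = (2.0, 4.0, 8.0)
                            ) -> pd.DataFrame:
    """Post-filter an enrichment-term table (e.g. GO terms from a ranked-list tool).

    Input is wide: one row per term with ``fold_enrichment_<t>`` columns
    (NaN where the term was not enriched at that time point).  Rules, in
    order: terms already enriched at the t = 0 control are dropped
    (baseline artifacts); terms enriched at fewer than two of the PSI time
    points are dropped; the remaining terms are scored by their summed fold
    enrichment over the PSI time points and the top ``top_fraction`` kept
    (ties at the cut retained).  Returns the kept rows with a
    ``sum_fold_enrichment`` column, sorted descending.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    tp_cols = [f"fold_enrichment_{int(t)}" for t in timepoints]
    for col in tp_cols + ["fold_enrichment_0"]:
        if col not in terms.columns:
            raise ValueError(f"column {col!r} missing from enrichment table")
    fe = terms[tp_cols].to_numpy(dtype=float)
    if np.any(fe[np.isfinite(fe)] <= 0):
        raise ValueError("fold enrichments must be positive where present")
    at_t0 = terms["fold_enrichment_0"].notna().to_numpy()
    n_late = np.isfinite(fe).sum(axis=1)
    eligible = terms[~at_t0 & (n_late >= 2)].copy()
    if eligible.empty:
        return eligible.assign(sum_fold_enrichment=pd.Series(dtype=float))
    eligible["sum_fold_enrichment"] = np.nansum(eligible[tp_cols].to_numpy(dtype=float), axis=1)
    sums = np.sort(eligible["sum_fold_enrichment"].to_numpy())[::-1]
    n_keep = math.ceil(top_fraction * len(eligible))
    cutoff = sums[n_keep - 1]
    kept = eligible[eligible["sum_fold_enrichment"] >= cutoff]
    return kept.sort_values("sum_fold_enrichment", ascending=False).reset_index(drop=True)
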