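"""Readers, writers, run configuration and the end-to-end pipeline driver.

All tables are UTF-8, tab-separated, header-first, '.' decimal separator;
floating-point output is written at 6 significant digits so reruns diff
byte-identically.  The SILAC reader understands two dialects: the
package's own tidy format and a MaxQuant evidence-style export
("Proteins" / "Experiment" / "Ratio H/M" columns, semicolon-separated
protein groups, time point parsed from the experiment name, e.g.
``Exp1_8h``).
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from . import silac

__all__ = [
    "read_silac_table",
    "read_halflife_table",
    "read_annotation_groups",
    "read_enrichment_table",
    "read_trajectory_table",
    "write_table",
    "read_image",
    "write_image",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("psilac")

FLOAT_FORMAT = "%.6g"

_GENERIC_REQUIRED = ["protein_id", "experiment", "timepoint_h", "ratio_hm"]
_MAXQUANT_MAP = {"Proteins": "protein_id", "Experiment": "experiment",
                 "Ratio H/M": "ratio_hm"}
_TIME_RE = re.compile(r"(\d+(?:\.\d+)?)\s*h", re.IGNORECASE)


def read_silac_table(path, dialect: str = "generic") -> pd.DataFrame:
    """Read a peptide-level H/M ratio table.

    ``generic`` expects tab-separated columns ``protein_id, experiment,
    timepoint_h, ratio_hm`` plus optional ``peptide_id`` and
    ``orientation`` ("HM" or "MH"; "MH" rows are inverted so ratios are
    always stored treated/control).  ``maxquant`` maps the MaxQuant
    evidence columns, takes the first id of a semicolon-separated protein
    group, and parses the time point from the experiment name.  Rows with
    non-numeric or non-positive ratios are dropped with a warning listing
    their line numbers; a missing required column raises.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if dialect == "maxquant":
        missing = [c for c in _MAXQUANT_MAP if c not in df.columns]
        if missing:
            raise ValueError(f"column {missing[0]!r} missing from {path}")
        df = df.rename(columns=_MAXQUANT_MAP)
        df["protein_id"] = df["protein_id"].str.split(";").str[0]
        if "timepoint_h" not in df.columns:
            tp = df["experiment"].map(
                lambda s: float(m.group(1)) if (m := _TIME_RE.search(str(s))) else np.nan)
            if tp.isna().any():
                raise ValueError("cannot parse timepoint from Experiment names; "
                                 "add a timepoint_h column")
            df["timepoint_h"] = tp
    elif dialect == "generic":
        missing = [c for c in _GENERIC_REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"column {missing[0]!r} missing from {path}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    ratio = pd.to_numeric(df["ratio_hm"], errors="coerce")
    tp = pd.to_numeric(df["timepoint_h"], errors="coerce")
    bad = ratio.isna() | (ratio <= 0) | tp.isna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        warnings.warn(f"dropped {bad.sum()} malformed row(s) at line(s) {lines}",
                      stacklevel=2)
    out = df[~bad].copy()
    out["ratio_hm"] = ratio[~bad]
    out["timepoint_h"] = tp[~bad]
    if "orientation" in out.columns:
        flip = out["orientation"].str.upper() == "MH"
        out.loc[flip, "ratio_hm"] = 1.0 / out.loc[flip, "ratio_hm"]
        out = out.drop(columns=["orientation"])
    out = out.rename(columns={"experiment": "experiment_id"})
    keep = ["protein_id", "experiment_id", "timepoint_h", "ratio_hm"]
    if "peptide_id" in out.columns:
        keep.append("peptide_id")
    out = out[keep].reset_index(drop=True)
    out.attrs["n_rejected"] = int(bad.sum())
    return out


def read_halflife_table(path) -> pd.Series:
    """Half-life CSV (protein_id, t_half_days) -> Series indexed by protein."""
    df = pd.read_csv(path)
    for col in ("protein_id", "t_half_days"):
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing from {path}")
    s = df.set_index("protein_id")["t_half_days"].astype(float)
    if (s <= 0).any():
        raise ValueError("half-lives must be positive")
    return s


def read_annotation_groups(path) -> dict:
    """Two-column TSV (group_name, protein_id) -> {group: set of proteins}."""
    df = pd.read_csv(path, sep="\t")
    for col in ("group_name", "protein_id"):
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing from {path}")
    return {g: set(sub["protein_id"]) for g, sub in df.groupby("group_name")}


def read_enrichment_table(path) -> pd.DataFrame:
    """Enrichment TSV: term_id, term_name, fold_enrichment_<t> [, fdr_<t>]."""
    df = pd.read_csv(path, sep="\t")
    if "term_id" not in df.columns:
        raise ValueError(f"column 'term_id' missing from {path}")
    return df


def read_trajectory_table(path) -> pd.DataFrame:
    """Punctum trajectory CSV with the tidy trajectory columns."""
    df = pd.read_csv(path)
    missing = [c for c in ("cell_id", "punctum_id", "condition", "timepoint_h",
                           "fluorescence_au") if c not in df.columns]
    if missing:
        raise ValueError(f"column {missing[0]!r} missing from {path}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a TSV with stable 6-significant-digit floats."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_image(path) -> np.ndarray:
    import tifffile
    return tifffile.imread(path)


def write_image(image: np.ndarray, path) -> None:
    import tifffile
    tifffile.imwrite(path, np.asarray(image, dtype=np.uint16))


class RunConfig(BaseModel):
    """Configuration of one end-to-end SILAC pipeline run.

    Echoed verbatim into the run summary; unknown keys are rejected so a
    summary always re-executes the exact same run.
    """

    model_config = ConfigDict(extra="forbid")

    input_path: str
    out_dir: str
    dialect: str = "generic"
    min_peptides: int = 5
    min_experiments: int = 3
    alpha: float = 0.05
    timepoints_h: tuple[float, ...] = (2.0, 4.0, 8.0)
    reference_proteins: tuple[str, ...] = tuple(sorted(silac.DEFAULT_REFERENCE_PROTEINS))
    k: Optional[float] = None
    halflife_path: Optional[str] = None
    groups_path: Optional[str] = None
    paired: bool = False
    fdr: bool = False
    seed: int = 0


def run_pipeline(config: RunConfig) -> dict:
    """Aggregate -> normalize -> filter -> volcano (+ optional model
    comparison and ranking), writing TSV outputs and a JSON run summary.

    Deterministic given inputs and config; on any stage failure partial
    outputs are removed.  Returns the run summary dict.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_json = config.model_dump_json()
    logger.info("run config hash %s (seed %d)",
                hashlib.sha256(cfg_json.encode()).hexdigest()[:12], config.seed)
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out_dir / name
        write_table(df, path)
        written.append(path)

    try:
        peptides = read_silac_table(config.input_path, dialect=config.dialect)
        if peptides.empty:
            raise ValueError("input table contains no usable peptide records")
        estimates = silac.aggregate_peptides(peptides)
        normalized = silac.normalize_to_reference(estimates, config.reference_proteins)
        filtered = silac.filter_stringent(normalized, config.min_peptides,
                                          config.min_experiments)
        result = silac.volcano(filtered, alpha=config.alpha,
                               timepoints=config.timepoints_h,
                               paired=config.paired, fdr=config.fdr)
        emit("volcano.tsv", result.records)

        summary = {
            "psilac_version": __version__,
            "config": json.loads(cfg_json),
            "magnitude_threshold": result.magnitude_threshold,
            "t0_population_sd": result.t0_sd,
            "counts": {
                "input_records": int(len(peptides)),
                "input_rejected_rows": int(peptides.attrs.get("n_rejected", 0)),
                "aggregated_estimates": int(len(estimates)),
                "post_filter_estimates": int(len(filtered)),
                "proteins_post_filter": int(filtered["protein_id"].nunique()),
                "volcano_significant_per_timepoint": {
                    f"{tp:g}": int(((result.records["timepoint_h"] == tp)
                                    & (result.records["klass"] != "not_significant")).sum())
                    for tp in config.timepoints_h},
                "hits_4and8": int(result.records.loc[result.records["is_hit_4and8"],
                                                     "protein_id"].nunique()),
            },
        }

        if config.halflife_path and config.k is not None:
            half = read_halflife_table(config.halflife_path)
            comp = silac.compare_to_model(filtered, half, k=config.k,
                                          timepoints=config.timepoints_h)
            emit("model_compare.tsv", comp.table)
            emit("model_correlations.tsv", comp.correlations)
            summary["counts"]["proteins_without_halflife"] = comp.n_missing_halflife

        ranks = silac.rank_proteins(filtered, timepoints=config.timepoints_h)
        emit("ranks.tsv", ranks)
        if config.groups_path:
            groups = read_annotation_groups(config.groups_path)
            grs = silac.group_rank_summary(ranks, groups)
            emit("groups.tsv", grs.summary)

        with open(out_dir / "run_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return summary
    except Exception as err:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed: {err}") from err
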