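"""Seeded generators for every input the analysis consumes, with ground truth.

Three generators:

* :func:`simulate_silac` — peptide-level H/M ratio tables following the
  first-order decay model under suppressed synthesis: lognormal half-life
  proteome, multiplicative (lognormal) peptide noise, per-sample mixing
  offsets, a planted long-lived reference subset and an optional
  accelerated-degradation subset.
* :func:`simulate_trajectories` — mean-reverting multiplicative punctum
  fluorescence (log-fluorescence Ornstein-Uhlenbeck / AR(1)) with an
  optional treatment onset that raises volatility, adds downward drift
  and eliminates puncta at a constant hazard.
* :func:`simulate_assay_fixtures` — small deterministic fixtures that
  exercise every exclusion branch of :mod:`psilac.assays`.

All randomness flows from one root seed through named
:class:`numpy.random.SeedSequence` substreams, so adding a generator
never perturbs another's output and identical seeds give bit-identical
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .assays import FluxPlate
from .kinetics import HOURS_PER_DAY, residual_fraction

__all__ = [
    "SilacSimConfig",
    "SilacSimResult",
    "simulate_silac",
    "TrajectorySimConfig",
    "TrajectorySimResult",
    "simulate_trajectories",
    "AssayFixtures",
    "simulate_assay_fixtures",
]

_LN2 = np.log(2.0)


def _stream(seed: int, label: str) -> np.random.Generator:
    """Named substream: independent generator derived from the root seed."""
    digest = np.frombuffer(label.encode(), dtype=np.uint8)
    return np.random.default_rng(np.random.SeedSequence([int(seed), *digest.tolist()]))


@dataclass(frozen=True)
class SilacSimConfig:
    """Study design of a simulated dynamic-SILAC PSI experiment.

    Defaults mirror the design the pipeline targets: five biological
    repeats with harvests at 0/2/4/8 h, a proteome whose half-lives are
    lognormal around a median of 5 days (sigma_log 1 spans the short-lived
    tail through the weeks-long bulk), ~10 peptide pairs per protein and
    sample, 0.2 log2-units of multiplicative peptide noise, per-sample
    mixing offsets of 0.1 log2-units, seven planted abundant long-lived
    reference proteins, and the fractional synthesis rate measured for
    cycloheximide (k = 1/39.2).
    """

    n_proteins: int = 2000
    halflife_median_days: float = 5.0
    halflife_sigma_log: float = 1.0
    k_true: float = 1.0 / 39.2
    timepoints_h: tuple = (0.0, 2.0, 4.0, 8.0)
    n_experiments: int = 5
    peptides_mean: float = 10.0
    noise_sigma_log2: float = 0.2
    experiment_offset_sigma: float = 0.1
    n_reference: int = 7
    reference_peptides_mean: float = 25.0
    accelerated_fraction: float = 0.0
    gamma: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins < 1 or self.n_experiments < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.k_true <= 1:
            raise ValueError("k_true must lie in [0, 1]")
        if not 0 <= self.accelerated_fraction <= 1:
            raise ValueError("accelerated_fraction must lie in [0, 1]")
        if self.peptides_mean < 1 or self.reference_peptides_mean < 1:
            raise ValueError("peptide means must be >= 1 (shifted Poisson)")


@dataclass
class SilacSimResult:
    peptides: pd.DataFrame
    truth: pd.DataFrame
    offsets: pd.DataFrame  # experiment x timepoint mixing offsets (log2)
    config: SilacSimConfig


def simulate_silac(config: SilacSimConfig) -> SilacSimResult:
    """Generate a peptide-level H/M table plus its ground truth.

    Each peptide's log2 ratio is the model-true log2 residual fraction of
    its protein at that time point, plus the sample's mixing offset, plus
    Gaussian noise of ``noise_sigma_log2`` (i.e. lognormal multiplicative
    noise on the ratio).  Reference proteins are long-lived (100-300 d
    half-lives drawn uniformly) and more abundant (higher peptide yield);
    an optional accelerated subset degrades ``gamma`` times faster under
    treatment than its nominal half-life predicts.
    """
    cfg = config
    P, E = cfg.n_proteins, cfg.n_experiments
    tps = np.asarray(cfg.timepoints_h, dtype=float)
    T = tps.size

    rng_half = _stream(cfg.seed, "halflife")
    rng_flags = _stream(cfg.seed, "flags")
    rng_counts = _stream(cfg.seed, "counts")
    rng_noise = _stream(cfg.seed, "noise")
    rng_off = _stream(cfg.seed, "offsets")

    n_ref = min(cfg.n_reference, P)
    n_bulk = P - n_ref
    t_half = np.empty(P)
    t_half[:n_bulk] = cfg.halflife_median_days * np.exp(
        cfg.halflife_sigma_log * rng_half.standard_normal(n_bulk))
    t_half[n_bulk:] = rng_half.uniform(100.0, 300.0, n_ref)
    is_ref = np.zeros(P, dtype=bool)
    is_ref[n_bulk:] = True

    is_accel = np.zeros(P, dtype=bool)
    n_accel = int(round(cfg.accelerated_fraction * n_bulk))
    if n_accel:
        is_accel[rng_flags.choice(n_bulk, size=n_accel, replace=False)] = True

    eff_half = np.where(is_accel, t_half / cfg.gamma, t_half)
    true_log2 = np.log2(residual_fraction(tps[None, :], eff_half[:, None], cfg.k_true))

    counts_mean = np.where(is_ref, cfg.reference_peptides_mean, cfg.peptides_mean)
    counts = 1 + rng_counts.poisson(counts_mean[:, None, None] - 1.0, size=(P, E, T))
    offsets = (rng_off.normal(0.0, cfg.experiment_offset_sigma, size=(E, T))
               if cfg.experiment_offset_sigma > 0 else np.zeros((E, T)))

    p_idx, e_idx, t_idx = np.unravel_index(np.arange(P * E * T), (P, E, T))
    reps = counts.ravel()
    p_rep = np.repeat(p_idx, reps)
    e_rep = np.repeat(e_idx, reps)
    t_rep = np.repeat(t_idx, reps)
    n_rows = p_rep.size
    log2 = (true_log2[p_rep, t_rep] + offsets[e_rep, t_rep]
            + cfg.noise_sigma_log2 * rng_noise.standard_normal(n_rows))

    width = len(str(P))
    pid = np.array([f"REF{i - n_bulk + 1:02d}" if i >= n_bulk else f"P{i + 1:0{width}d}"
                    for i in range(P)])
    eid = np.array([f"E{j + 1}" for j in range(E)])
    peptides = pd.DataFrame({
        "protein_id": pid[p_rep],
        "experiment_id": eid[e_rep],
        "timepoint_h": tps[t_rep],
        "ratio_hm": np.exp2(log2),
        "peptide_id": np.arange(n_rows),
    })

    truth = pd.DataFrame({"protein_id": pid, "t_half_days": t_half,
                          "is_reference": is_ref, "is_accelerated": is_accel})
    for j, t in enumerate(tps):
        truth[f"true_log2_{t:g}h"] = true_log2[:, j]
    offsets_df = pd.DataFrame(offsets, index=eid, columns=tps)
    return SilacSimResult(peptides=peptides, truth=truth, offsets=offsets_df, config=cfg)


@dataclass(frozen=True)
class TrajectorySimConfig:
    """Mean-reverting multiplicative punctum-fluorescence dynamics.

    Log fluorescence of each punctum follows a stationary AR(1)
    (discretized Ornstein-Uhlenbeck) around a fixed level: reversion
    timescale ``tau_c_h`` and stationary log-SD ``sigma``.  ``sigma = 0.2``
    (about +/-20% hourly wandering) emulates the spontaneous configuration
    change of tracked postsynaptic puncta.  ``punctum_spread`` adds a
    fixed per-punctum log offset (across-population size heterogeneity
    that does not relax); keep it 0 when validating the R^2 curve against
    the closed-form autocorrelation of the process.  After
    ``treatment_onset_h`` the innovation SD is multiplied by
    ``vol_multiplier``, the level drifts by ``-drift_per_h`` per hour and
    puncta are eliminated with constant ``elimination_hazard_per_h``.
    """

    n_cells: int = 20
    puncta_per_cell: int = 50
    dt_h: float = 1.0
    duration_h: float = 48.0
    tau_c_h: float = 12.0
    sigma: float = 0.2
    punctum_spread: float = 0.0
    cell_gain_sigma: float = 0.3
    mean_fluorescence_au: float = 1000.0
    treatment_onset_h: float | None = None
    vol_multiplier: float = 2.0
    drift_per_h: float = 0.0
    elimination_hazard_per_h: float = 0.0
    condition: str = "treated"
    seed: int = 0

    def __post_init__(self):
        if self.tau_c_h <= 0:
            raise ValueError("reversion timescale must be positive")
        if self.sigma < 0 or self.punctum_spread < 0:
            raise ValueError("volatilities must be non-negative")


@dataclass
class TrajectorySimResult:
    trajectories: pd.DataFrame
    truth: pd.DataFrame
    config: TrajectorySimConfig


def simulate_trajectories(config: TrajectorySimConfig) -> TrajectorySimResult:
    cfg = config
    n = cfg.n_cells * cfg.puncta_per_cell
    times = np.arange(0.0, cfg.duration_h + cfg.dt_h / 2, cfg.dt_h)
    T = times.size
    phi = np.exp(-cfg.dt_h / cfg.tau_c_h)
    innov_sd = cfg.sigma * np.sqrt(1.0 - phi * phi)

    rng_proc = _stream(cfg.seed, "trajectory-process")
    rng_cell = _stream(cfg.seed, "trajectory-cells")
    rng_elim = _stream(cfg.seed, "trajectory-elimination")

    base = cfg.punctum_spread * rng_cell.standard_normal(n)
    gains = np.exp(cfg.cell_gain_sigma * rng_cell.standard_normal(cfg.n_cells))
    cell_of = np.repeat(np.arange(cfg.n_cells), cfg.puncta_per_cell)

    x = np.empty((n, T))
    x[:, 0] = cfg.sigma * rng_proc.standard_normal(n)
    mu = 0.0
    onset = np.inf if cfg.treatment_onset_h is None else cfg.treatment_onset_h
    for j in range(1, T):
        treated = times[j] > onset
        sd = innov_sd * (cfg.vol_multiplier if treated else 1.0)
        if treated:
            mu -= cfg.drift_per_h * cfg.dt_h
        x[:, j] = mu + phi * (x[:, j - 1] - mu) + sd * rng_proc.standard_normal(n)

    fluor = (gains[cell_of][:, None] * cfg.mean_fluorescence_au
             * np.exp(base[:, None] + x))

    eliminated_at = np.full(n, np.nan)
    if cfg.elimination_hazard_per_h > 0 and np.isfinite(onset):
        p_step = 1.0 - np.exp(-cfg.elimination_hazard_per_h * cfg.dt_h)
        alive = np.ones(n, dtype=bool)
        for j in range(T):
            if times[j] <= onset:
                continue
            die = alive & (rng_elim.random(n) < p_step)
            eliminated_at[die] = times[j]
            alive &= ~die
            fluor[~alive, j] = np.nan

    punctum_ids = np.array([f"c{c:03d}_p{p:03d}" for c, p in
                            zip(cell_of, np.tile(np.arange(cfg.puncta_per_cell), cfg.n_cells))])
    cell_ids = np.array([f"c{c:03d}" for c in cell_of])
    traj = pd.DataFrame({
        "cell_id": np.repeat(cell_ids, T),
        "punctum_id": np.repeat(punctum_ids, T),
        "condition": cfg.condition,
        "timepoint_h": np.tile(times, n),
        "fluorescence_au": fluor.ravel(),
    })
    truth = pd.DataFrame({"punctum_id": punctum_ids, "cell_id": cell_ids,
                          "base_log_offset": base, "cell_gain": gains[cell_of],
                          "eliminated_at_h": eliminated_at})
    return TrajectorySimResult(trajectories=traj, truth=truth, config=cfg)


@dataclass
class AssayFixtures:
    """Deterministic small fixtures exercising every assay exclusion branch."""

    suppression_treated: pd.DataFrame
    suppression_control: pd.DataFrame
    fm_traces: pd.DataFrame
    viability: pd.DataFrame
    activity: list
    flux: FluxPlate
    truth: Mapping


def simulate_assay_fixtures(seed: int = 0) -> AssayFixtures:
    """Small, seeded fixtures with planted ground truth for the assay ops.

    Planted facts (recorded in ``truth``): a 10-fold synthesis
    suppression; 3 boutons below the 600 AU baseline cutoff and one
    non-responder; one zero-total viability field around a 0.9 live
    fraction; 6 activity experiments with a planted post-onset downward
    drift; a flux plate with one textbook well, one oligomycin-increase
    well, one FCCP-unresponsive well and one dead (background-level) well.
    """
    rng = _stream(seed, "assay-fixtures")
    truth: dict = {}

    # --- suppression: planted fold 10 ----------------------------------
    n_cells = 40
    mturq = rng.uniform(800, 1200, 2 * n_cells)
    ratio_ctrl, fold = 2.0, 10.0
    bg_jf, bg_mt = 50.0, 40.0
    jf_ctrl = ratio_ctrl * (mturq[:n_cells] - bg_mt) * np.exp(0.05 * rng.standard_normal(n_cells))
    jf_trt = (ratio_ctrl / fold) * (mturq[n_cells:] - bg_mt) * np.exp(
        0.05 * rng.standard_normal(n_cells))
    mk = lambda jf, mt, tag: pd.DataFrame({
        "cell_id": [f"{tag}{i}" for i in range(n_cells)],
        "jf_mean": jf + bg_jf, "mturq_mean": mt,
        "background_jf": bg_jf, "background_mturq": bg_mt})
    truth["suppression_fold"] = fold

    # --- FM4-64: 3 dim boutons, one non-responder -----------------------
    n_b = 10
    baseline = np.full(n_b, 1500.0)
    baseline[:3] = 500.0  # below the 600 AU cutoff
    load = rng.uniform(1200, 2500, n_b)
    frac = np.full(n_b, 0.6)
    frac[3] = 0.10  # washout/bleaching-level dimming only
    fm = pd.DataFrame({"bouton_id": [f"b{i}" for i in range(n_b)],
                       "field_id": "f0", "baseline_mean": baseline,
                       "load_value": load, "unload_value": load * (1 - frac)})
    truth["fm_excluded_baseline"] = 3
    truth["fm_non_responders"] = 1

    # --- viability: one empty field around 0.9 live ---------------------
    viability = pd.DataFrame({"field_id": [f"v{i}" for i in range(4)],
                              "n_calcein": [90, 85, 95, 0],
                              "n_pi": [10, 15, 5, 0]})
    truth["viability_skipped"] = 1
    truth["viability_mean"] = 0.9

    # --- activity: planted post-onset downward drift --------------------
    n_exp, n_bins, onset = 6, 480, 240
    drift = 0.002
    activity = []
    for _ in range(n_exp):
        noise = 0.05 * rng.standard_normal(n_bins)
        v = np.ones(n_bins) + noise
        v[onset:] -= drift * np.arange(n_bins - onset)
        activity.append(np.clip(v * 100, 0, None))
    truth["activity_onset_bin"] = onset
    truth["activity_drift_per_bin"] = drift

    # --- flux plate ------------------------------------------------------
    cycles = 20
    shape = np.concatenate([np.full(5, 100.0), np.full(5, 60.0),
                            np.full(5, 180.0), np.full(5, 20.0)])
    wells = {}
    wells["textbook"] = shape + 200.0  # background 200 adds everywhere
    oligo_up = shape + 200.0
    oligo_up[5:10] = 330.0  # OCR rises after oligomycin
    wells["oligo_increase"] = oligo_up
    no_fccp = shape + 200.0
    no_fccp[10:15] = 262.0  # FCCP arrives but nothing happens
    wells["no_fccp"] = no_fccp
    wells["dead"] = np.full(cycles, 200.0)  # background-level: baseline <= 0
    for b in ("bg1", "bg2"):
        wells[b] = np.full(cycles, 200.0)
    flux = FluxPlate(values=pd.DataFrame(wells).T,
                     background_wells=frozenset({"bg1", "bg2"}),
                     baseline_cycles=5,
                     injections={"oligomycin": 5, "fccp": 10, "rot_aa": 15})
    truth["flux_oligo_increase_wells"] = 1
    truth["flux_no_fccp_wells"] = 1
    truth["flux_nonpositive_baseline_wells"] = 1
    truth["flux_textbook_percent"] = (100.0, 60.0, 180.0, 20.0)

    return AssayFixtures(
        suppression_treated=mk(jf_trt, mturq[n_cells:], "t"),
        suppression_control=mk(jf_ctrl, mturq[:n_cells], "c"),
        fm_traces=fm, viability=viability, activity=activity, flux=flux, truth=truth)
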