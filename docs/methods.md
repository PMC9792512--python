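# Methods

## The kinetic model

`psilac.kinetics` implements the minimal turnover model for a protein
pool under acute, partial suppression of synthesis. Synthesis is a
zero-order reaction with rate α; degradation is first-order with rate
constant β = ln 2 / t<sub>1/2</sub> (time constant τ = 1/β =
t<sub>1/2</sub>/ln 2, the familiar "1.44 · t<sub>1/2</sub>"; internally
the exact 1/ln 2 is used and 1.44 appears only as a display rounding).
A protein-synthesis inhibitor (PSI) multiplies the synthesis rate by a
fraction k = α<sub>i</sub>/α ∈ [0, 1] while leaving β unchanged.
Starting from steady state, the abundance relative to time-matched
untreated controls obeys

    dC′/dt = βk − βC′,   C′(0) = 1   ⇒   C′(t) = (1 − k) e^(−βt) + k

with the new steady state C′(∞) = k. In a dynamic-SILAC design the
reference-normalized H/M ratio estimates C′, so log₂ C′ is the expected
log₂(H/M) given a protein's half-life, the exposure time, and the
independently measured fold suppression (k = 1/fold; e.g. a 39.2-fold
suppression gives k ≈ 0.0255).

Assumptions worth keeping in mind: single well-mixed pool, no transport
or compartment structure, degradation unchanged by the inhibitor. Real
data contain counterexamples — a handful of proteins are lost much
faster than their half-life predicts, consistent with degradation being
*accelerated* when synthesis stops. The model deliberately does not fit
such acceleration; the synthetic generator exposes it instead as a
γ-factor on β for a planted subset, so downstream steps (ranking, group
scoring) can be validated against proteins that break the model.

Units: half-lives in days (the unit half-life tables are published in),
exposure times in hours; conversion is ×24 at the model boundary.

`estimate_k` recovers k by bounded least squares on measured log₂
ratios given known half-lives. Identifiability is physical, not
numerical: proteins that barely turn over within the exposure window
carry no information about k, so a sensible recovery design is
short-half-life-rich. Two caveats the implementation surfaces
deliberately: measurements at t = 0 are useless for k (all-t = 0 input
raises), and any systematic per-time-point level error propagates into
k amplified by roughly the ratio Σsᵢ/Σsᵢ² of model sensitivities — with
a 7-protein normalization reference the absolute level is only known to
~±0.02 log₂ units per time point, which dominates the error budget of k
long before peptide noise does. Parameter-recovery validation therefore
runs on aggregated (offset-free) simulations, while the normalization
machinery is validated by its exact invariance property.

## The SILAC loss pipeline

`psilac.silac` operates on tidy DataFrames (one row per peptide
measurement, then one row per protein × experiment × time point).

* **Aggregation** — peptide log₂ ratios are combined per protein ×
  experiment × time point by the **median** (robust to single outlier
  peptides; the choice matters little at ≥5 peptides but protects the
  single-digit-peptide tail).
* **Reference normalization** — per experiment × time point, the median
  log₂ ratio of a set of abundant, very long-lived proteins (defaults:
  Vcan, Lamin-B1/B2, Nup155, Nup205, macro-H2A.1/.2) is subtracted from
  every protein. This removes mixing imbalance between the treated and
  control extracts exactly (any per-sample additive log₂ offset cancels
  to machine precision). Median rather than mean: one aberrant
  reference measurement should not shift an entire sample.
* **Stringent filtering** — a protein enters the analysis at a time
  point only with ≥5 peptide measurements summed over ≥3 experiments,
  evaluated per protein per time point.
* **Volcano classification** — per protein and time point, the log₂
  fold change is the mean over experiments minus the mean at t = 0; the
  magnitude bar is 2 × SD of the t = 0 population of per-protein means
  (at t = 0 every departure from H/M = 1 is noise, so 2 SD of that
  population is the smallest change distinguishable from it; an SD of
  0.26 puts the bar at ~30% loss); significance is a two-sided
  two-sample t-test on per-experiment values at p ≤ 0.05, uncorrected
  (a Benjamini–Hochberg option exists but is off by default —
  hit-calling here feeds ranked downstream summaries, not a fixed
  discovery list). The default test pools variances: with five repeats
  per group and one shared protocol, the pooled test is exact at the
  nominal level, whereas the Welch variant is measurably conservative
  (type-I ≈ 0.042 at n = 5); `welch=True` and `paired=True` are
  available. Proteins clearing both bars at both 4 h and 8 h form the
  high-confidence hit set and are flagged at every time point.
* **Model comparison** — measured mean log₂ ratios against
  model-expected values, with Pearson r reported within half-life
  strata (≤2 d, ≤10 d) per time point; correlations strengthen with
  exposure duration as true loss grows relative to measurement noise.
  Strata under 3 proteins report no r.
* **Ranking and group scores** — proteins ranked ascending by mean log₂
  ratio per time point (rank 1 = most lost, average-rank ties), the
  per-protein rank averaged over 2/4/8 h (over available time points by
  default; a strict all-three mode exists) and reported as log₁₀.
  Annotation groups (e.g. SynGO-style synaptic categories) get their
  members' log₁₀ ranks and the group mean. Proteins that *increase*
  simply rank at the bottom — no special handling.
* **Enrichment-term post-filter** — given a per-term table of fold
  enrichments from a ranked-list enrichment tool, drop terms already
  enriched at the t = 0 control, drop terms enriched at fewer than two
  of the three PSI time points, then keep the top 25% by summed fold
  enrichment (ties at the cut kept). Ontology-hierarchy pruning is out
  of scope (requires the GO graph).

## Synaptic tenacity

`psilac.tenacity` quantifies how fast a population of tracked synaptic
puncta forgets its configuration. Pipeline order: 3-sample centered
moving average (shrunken windows at the edges — no invented padding),
per-cell normalization (divide each punctum by its cell's mean punctum
fluorescence at a reference time, canceling reporter-expression
differences exactly), then for each interval Δ within an analysis
window, OLS regression of fluorescence at window-start + Δ on
fluorescence at window-start across puncta. R²(Δ) = 1 means frozen
configurations; decay toward 0 measures configuration drift. R² is
invariant to common affine rescaling; windows with zero variance at the
start report no value.

For the validating generator (log-fluorescence AR(1)/OU with reversion
time τ_c), the population R²(Δ) equals the squared autocorrelation
e^(−2Δ/τ_c). That closed form holds for the *unsmoothed* process — the
3-point filter correlates neighboring samples and lifts short-interval
R² above it — so the generator-vs-theory check runs on unsmoothed,
normalized trajectories, and smoothing is validated by its own exact
examples. A treatment that multiplies the innovation volatility from an
onset time lowers R² at every Δ > 0 (the inhibitor signature:
accelerated configuration change), because the window starts from the
baseline-variance state while extra noise accumulates.

Puncta detection mirrors the standard imaging procedure: Mexican-hat
filter, here difference-of-Gaussians with σ_inner = 1.5 px and
σ_outer = 3 px (the kernel widths are not dictated by the procedure;
these bracket a ~2 px punctum), then strict local maxima within a
5-pixel Euclidean radius above a threshold of mean + 3 SD of the
*filtered image* (spots included — on realistically dense fields this
self-scales the threshold well above the filtered noise floor).
Plateau ties break to the lexicographically smallest coordinate for
determinism. Intensities are means over square ROIs (9×9 default;
other assays use 7×7 or 10×10 — ROI size is a parameter) centered on
each punctum, border-clipped ROIs flagged, ROIs containing saturated
pixels excluded.

## Functional assays

Each quantification in `psilac.assays` is a direct transcription of a
measurement rule plus its exclusion logic: background-corrected
two-channel ratios and the control/treated fold (→ k); FM-dye
fractional release with the <600 AU dim-bouton exclusion and the >15%
responder rule (washout/bleaching alone dims 8–12%); calcein/PI live
fractions with zero-total fields skipped; spike-rate series normalized
to a leading baseline window (180 one-minute bins by default) and
compared by paired t-test on per-experiment pre/post OLS slopes;
extracellular-flux plates background-subtracted per cycle, scaled to
each well's 5th baseline measurement (exactly 100% there by
construction) with wells flagged for failed oligomycin/FCCP/Rot-AA
pharmacology. "Failed to respond" is not numerically defined by the
source procedure; the defaults here are post-FCCP mean > 1.1 × post-
oligomycin mean and post-Rot/AA mean < 0.9 × post-oligomycin mean, both
configurable. Background correction uses means of designated
background wells/regions (plate-reader convention). FM release can be
computed on raw or background-corrected values (`background=` offset),
since the source analyses did both in different figures.

## Synthetic data: what it emulates, and what it does not

`simulate_silac` draws a proteome of lognormal half-lives (median 5 d,
σ_log = 1 — days-to-weeks bulk with a short-lived tail), computes true
residual fractions from the model at k (default 1/39.2), and emits
peptide-level ratios with Gaussian log₂ noise (σ = 0.2), per-sample
mixing offsets (σ = 0.1 log₂, drawn per experiment × time point — each
mixed treated/control pair is its own mixing event), shifted-Poisson
peptide counts (mean 10; reference proteins mean 25 — they are
abundant by definition), seven planted reference proteins with 100–300 d
half-lives, and an optional γ-accelerated subset. Not emulated:
ratio-compression, missingness correlated with abundance, peptide-level
systematic effects (shared peptides, modification states), or
biological co-regulation — so passing recovery tests demonstrates the
pipeline's correctness under its own noise model, not robustness to
every MS pathology.

`simulate_trajectories` draws per-punctum log-fluorescence AR(1) series
(τ_c = 12 h, stationary σ = 0.2 by default), multiplies by per-cell
lognormal gains, and optionally applies a treatment onset (volatility
multiplier 2, optional downward drift and constant elimination hazard).
`punctum_spread` adds a non-relaxing per-punctum size offset: with it,
σ → 0 yields heterogeneous frozen trajectories (R² = 1 everywhere);
without it (default 0) the across-puncta variance is exactly the OU
stationary variance, which is the regime where R²(Δ) = e^(−2Δ/τ_c)
holds. Real puncta have heavy-tailed sizes and tracking artifacts the
generator omits.

All generators derive their randomness from one root seed through named
substreams, so identical configs are bit-reproducible and adding a
generator never perturbs another.

## Numerical choices and problem sizes

* Exact constants (1/ln 2) internally; table output at 6 significant
  digits for byte-stable reruns.
* `estimate_k`: bounded scalar minimization on [0, 1], xatol 1e-10;
  verified against a 1e-4 grid search.
* t-tests via scipy; ranks via average-rank `rankdata`; regressions via
  `linregress`.
* Validation sizes, chosen to pin Monte-Carlo error well below the
  tolerances being checked: 2000-protein proteomes for recovery and
  correlation ordering (100 seeds), 100 seeds × 200 proteins for null
  calibration (SE of the mean fraction estimated from the across-seed
  spread, which absorbs within-seed correlation from shared sample
  offsets), 10,000 puncta for the R²(Δ) curve (deviations compared at
  3 × the delta-method SE of a squared correlation), 50 planted spots
  at SNR 5 on a 256×256 field for detection.

## Known limitations

* The model treats β as inhibitor-independent; accelerated degradation
  is generated but never fitted.
* Absolute-scale inference (k) from reference-normalized data is
  limited by the reference set's own measurement noise (~±0.02 log₂ per
  time point with 7 references); k should come from a dedicated
  suppression assay, with SILAC-based estimation reserved for
  offset-free or many-reference designs.
* Enrichment post-filtering consumes an external tool's term table; the
  enrichment statistics themselves, and GO-hierarchy level pruning, are
  out of scope.
* Punctum tracking (drift, merge/split) is assumed done; detection is
  2-D only.
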