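# psilac

Analysis toolkit for dynamic-SILAC experiments in which protein
synthesis is acutely suppressed, and for the companion live-imaging and
functional assays used to pin down what fails first in neurons when the
supply of newly synthesized proteins is interrupted.

Most neuronal and synaptic proteins live for days to weeks, but a
short-lived minority does not. When a protein-synthesis inhibitor (PSI,
e.g. cycloheximide) removes the supply of new copies, those short-lived
proteins are lost within hours — and with them, specific functions.
`psilac` packages the quantitative analyses this kind of study needs:

* **Turnover kinetics** (`psilac.kinetics`) — with zero-order synthesis
  and first-order degradation (β = ln 2/t₁/₂, τ = 1/β ≈ 1.44·t₁/₂), a
  PSI that reduces synthesis to a fraction *k* of its nominal rate
  leaves the residual protein fraction

      C′(t) = (1 − k)·e^(−βt) + k,   C′(0) = 1,  C′(∞) = k

  so log₂ C′(t) is the expected log₂(H/M) SILAC ratio given a protein's
  half-life. Includes prediction, inversion (k = 1/fold-suppression)
  and least-squares recovery of k from measured ratios.
* **SILAC loss pipeline** (`psilac.silac`) — peptide→protein
  aggregation (median log₂ H/M), normalization to a set of abundant
  long-lived reference proteins per experiment × time point, stringent
  filtering (≥5 peptides from ≥3 experiments), volcano classification
  (|log₂ FC| > 2·SD of the t = 0 population and t-test p ≤ 0.05),
  measured-vs-model comparison with half-life-stratified Pearson r,
  loss ranking with annotation-group summaries, and enrichment-term
  post-filtering.
* **Synaptic tenacity** (`psilac.tenacity`) — for tracked fluorescent
  puncta: smoothing, per-cell normalization, and the R²-vs-interval
  regression that measures how fast synaptic configurations drift;
  plus Mexican-hat puncta detection and ROI intensity measurement.
* **Functional assays** (`psilac.assays`) — synthesis-suppression fold
  from dual-reporter fluorescence, FM-dye recycling with responder
  rules, calcein/PI viability, network spike-rate normalization and
  paired slope tests, extracellular-flux plate normalization with
  mito-stress exclusion rules.
* **Synthetic data** (`psilac.simulate`) — seeded generators with
  ground truth for every input the pipeline consumes.

## Worked example

Simulate a 2000-protein dynamic-SILAC experiment at the cycloheximide
suppression level (39.2-fold, k ≈ 0.0255), run the pipeline, and compare
to the model:

```python
from psilac import kinetics, silac
from psilac.simulate import SilacSimConfig, simulate_silac

cfg = SilacSimConfig(n_proteins=2000, seed=1)   # k_true = 1/39.2
res = simulate_silac(cfg)

est = silac.aggregate_peptides(res.peptides)
refs = set(res.truth.loc[res.truth.is_reference, "protein_id"])
est = silac.normalize_to_reference(est, refs)
est = silac.filter_stringent(est)               # >=5 peptides, >=3 experiments

v = silac.volcano(est)
print(f"magnitude threshold: {v.magnitude_threshold:.3f} log2 units")
half = res.truth.set_index("protein_id")["t_half_days"]
comp = silac.compare_to_model(est, half, k=1/39.2)
print(comp.correlations.query("stratum_max_days == 2.0").to_string(index=False))
```

Output:

```
magnitude threshold: 0.071 log2 units
 timepoint_h  stratum_max_days   n  pearson_r
         2.0               2.0 353   0.822516
         4.0               2.0 353   0.944087
         8.0               2.0 353   0.986129
```

The magnitude threshold is twice the spread of the t = 0 population
(pure measurement noise, here ~0.035 log₂ units), and the correlation
between measured and model-expected log₂(H/M) among short-lived
proteins (t₁/₂ ≤ 2 d) strengthens with exposure duration — at 2 h true
loss barely rises above noise, by 8 h the model explains nearly all of
the variance.

The same steps run from the shell:

```sh
psilac sim silac --n-proteins 2000 --seed 1 --out sim/
psilac run --input sim/peptides.tsv --out results/ \
       --reference "$(python -c "
import pandas as pd
t = pd.read_csv('sim/ground_truth.tsv', sep='\t')
print(','.join(t.loc[t.is_reference,'protein_id']))")"
```

which writes `volcano.tsv`, `ranks.tsv` and a `run_summary.json` that
records every threshold, count and seed needed to re-execute the run.

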