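# tmadissect

Spatial-domain analysis of hyperplexed immunofluorescence tissue-microarray
(TMA) data for solid-tumor recurrence prognosis.  Given per-cell tables from
segmented TMA spots (coordinates, QC metadata, an E-cadherin-based
epithelial/stromal call, and log2 intensities for a multiplexed biomarker
panel) plus per-patient recurrence outcomes, `tmadissect`:

1. **virtually dissects** each spot into epithelial, stromal, and
   epithelial–stromal boundary domains — the boundary is the union of 50 µm
   circles containing both E-cadherin-positive and -negative cells, a band
   ~100 µm wide along the interface;
2. **summarizes** each domain as a feature vector **f** of thresholded mean
   intensities and pairwise Kendall rank correlations
   (`M = P + P(P−1)/2 = 1540` for a 55-marker panel), counting only
   intensities above the per-spot 85th percentile as expression;
3. **fits** a recurrence-guided penalized Cox model per domain — LASSO
   selection at the CV-optimal penalty, a 90% bootstrap selection-frequency
   screen, a 90% coefficient-sign-stability screen, then an L2 refit — and
   scores patients with the multiplicative combination
   `HR = Π_{s∈S} exp(f_s'β_s)` over S = {epithelial, stromal, epi-stromal};
4. **evaluates** with year-stratified train/test splits: ROC/AUC of the
   5-year binary outcome, the Youden operating point with likelihood ratios,
   Kaplan–Meier risk stratification, time-dependent AUC(t), and a six-model
   comparison harness (clinical, intensity, null/undissected, spatial, and
   +clinical combinations);
5. **infers** recurrence-specific domain networks: per-patient partial
   correlations from shrinkage-stabilized Kendall correlation matrices,
   Jensen–Shannon information distances between the outcome groups'
   distributions, and 99th-percentile thresholded graphs.

It is aimed at computational pathology and systems-biology groups working
with Cell DIVE-style iterative multiplexed imaging of solid tumors, and at
methodologists who need a fully synthetic, ground-truthed test bed for
spatially resolved survival modeling.  Because matched public cohorts of
this kind are not available, the package ships a first-class synthetic
cohort generator (`tmadissect.simulate`) with planted, recoverable signal.

## Worked example

```python
from tmadissect import RunConfig, run_pipeline, write_results
from tmadissect.simulate import PlantedFeature, SyntheticCohortConfig, generate_cohort

sim = SyntheticCohortConfig(
    n_patients=40, panel_size=8, n_epithelial=150, n_stromal=150,
    planted=(PlantedFeature("epithelial", "mean__m02", 1.0),
             PlantedFeature("stromal", "mean__m05", -1.0)),
    target_event_fraction=0.4, seed=17,
)
cells, surv, truth = generate_cohort(sim)

config = RunConfig(n_bootstraps=10, n_eval_splits=2, seed=7)
result = run_pipeline(cells, surv, config)
print(result.qc_counts)
print({d: m.features for d, m in result.spatial_model.models.items()})
print(round(result.evaluation["auc"], 3), round(result.evaluation["sensitivity"], 3))
write_results(result, "results/demo")
```

On this 40-patient cohort the run prints:

```
{'removed_small': 369, 'removed_low_quality': 395, 'removed_total': 754, 'retained': 11246}
{'epithelial': ['mean__m02'], 'stromal': ['mean__m02', 'mean__m04', 'mean__m05', 'mean__m08'], 'epi_stromal': ['mean__m02', 'mean__m05']}
0.942 0.923
```

Reading: QC removed ~6% of the 12,000 simulated cells; the stability
screens recovered both planted features — the epithelial domain keeps the
planted `mean__m02`, and the stromal domain keeps the planted protective
`mean__m05` (plus correlated passengers, expected at this small cohort
size); and the full-data spatial risk score separates 5-year recurrences
from non-recurrences with AUC 0.942 and sensitivity 0.923 at the Youden
operating point.  The same
pipeline is available from the shell via subcommands
(`tmadissect simulate|qc|dissect|features|fit|evaluate|networks|all`), every
output carrying a JSON sidecar with the config hash and seed.

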