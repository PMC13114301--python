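# ldrtox

Spatial-dosimetric prediction of long-term urinary toxicity after permanent
low-dose-rate (LDR) prostate brachytherapy.

After an I-125 seed implant, many patients' urinary symptoms (measured by
the International Prostate Symptom Score, IPSS, 0–35) flare and then settle
back toward baseline; patients whose IPSS has not returned to within 2
points of baseline by 12 months are labeled as having long-term urinary
toxicity. Whole-organ dose–volume metrics (prostate D₉₀%, V₁₅₀%, urethra
D₅% …) are kept nearly constant by planning protocol and carry little
discriminative information, so this package asks a finer question: *where*
inside the gland the dose lands. It is written for medical-physics and
outcome-modelling researchers who want a fully reproducible, testable
version of that analysis — including a synthetic cohort generator, since
clinical implant datasets are private.

## Pipeline

1. **Dosimetry** — TG-43 1-D point-source formalism for each seed,
   `dD/dt(r) = S_k Λ (r₀/r)² g(r) φ_an(r)`, integrated over complete decay
   (`D = dD/dt · T½/ln 2`), superposed over the implant on a voxel grid.
2. **Segmentation** — the prostate∪urethra voxels are partitioned three
   ways: Apex/MidGland/Base (1:2:1 along the superior–inferior axis),
   Anterior/Posterior (coronal plane through the urethral center per
   slice), and Urethra (<7 mm from the urethral center) / Urethra10mm
   (7–10 mm annulus) / Peripheral. The 9 individual zones and their
   intersections form a 48-zone catalogue.
3. **Featurization** — a cumulative DVH per zone (0–400% of the 110 Gy
   prescription, 1% steps); per-zone PCA across the cohort keeps the first
   two component scores (96 spatial features), joined by ten indicators
   (prostate D₉₀/V₁₀₀/V₁₅₀, urethra D₅/D₃₀/V₁₅₀, needle count, seed
   count, prostate volume, baseline IPSS). Min–max scaling, then Pearson
   pruning of collinear columns (|r| > 0.9).
4. **Model** — sequential backward selection (SBS) wrapped around a
   shuffle-and-split (S&S) RBF-SVM: each SBS step removes the feature whose
   exclusion maximizes the mean test AUC over repeated stratified 80/20
   splits; selection stops at the one-in-ten level (⌊n/10⌋ features).
   Hyperparameters (C ∈ [0,100], γ ∈ [10⁻⁵,100]) are tuned by particle
   swarm optimization. Feature importance = mean AUC after removing each
   selected feature (lower = more important).
5. **Univariate screen** — Spearman ρ with the toxicity label plus each
   feature's standalone orientation-corrected AUC.

The synthetic generator produces planning-goal-compliant cohorts
(prostate D₉₀ ≥ 100%, V₁₅₀ < 50%, urethra D_max < 150%) with a planted
logistic dose–toxicity mechanism in a named subzone, so recovery of the
planted signal is an end-to-end test of the whole chain.

## Worked example

```python
from ldrtox import GeneratorConfig, generate_cohort
from ldrtox.featurization import assemble_feature_table, scale_and_prune
from ldrtox.model import SplitScheme, sbs_select

cohort = generate_cohort(GeneratorConfig(n_patients=85, master_seed=1))
table, models = assemble_feature_table(
    cohort.zone_curves, cohort.indicators, cohort.zone_empty)
pruned = scale_and_prune(table)
print(len(table.feature_names), "->", len(pruned.feature_names))

trace = sbs_select(pruned.values, cohort.labels,
                   scheme=SplitScheme(n_repeats=200, master_seed=2),
                   selection_scheme=SplitScheme(n_repeats=8, master_seed=3))
print(len(trace.final_features), "features, mean AUC",
      round(trace.final_performance.mean_auc, 3))
```

prints (exact values depend on the seeds; these are from this example):

```
106 -> 77
8 features, mean AUC 0.724
```

106 features are assembled (96 spatial + 10 indicators), collinearity
pruning keeps 77, and the one-in-ten rule stops selection at ⌊85/10⌋ = 8
features whose shuffle-split SVM separates toxic from non-toxic patients
with a mean AUC of about 0.72 on this synthetic cohort.

A CLI mirrors the stages (`ldrtox simulate | segment | dose | dvh |
features | train | uva | run`); `ldrtox run --seed 17 --out out/` executes the whole pipeline and
writes `features.csv`, `uva.csv`, `roc.csv`, `importance.csv` and
`model_report.json`.

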