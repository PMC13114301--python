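# Methods

## Scope and model

`ldrtox` implements a spatial-dosimetric analysis of long-term urinary
toxicity after permanent I-125 LDR prostate brachytherapy: seed dosimetry,
subzone segmentation, DVH featurization, a wrapper-selection SVM classifier
and a univariate screen, together with a synthetic cohort generator that
stands in for private clinical data. This note records the modelling
assumptions, the tunable parameters, the numerical conventions and the
places where the design was genuinely open.

## Dosimetry

The TG-43 1-D point-source formalism is used:
`rate(r) = S_k · Λ · (r₀/r)² · g(r) · φ_an(r)` with r₀ = 1 cm. Loose seeds
have no reliable orientation after implantation, so the anisotropy *factor*
φ_an(r) replaces the 2-D function F(r, θ). Interseed attenuation, tissue
heterogeneity and seed migration are not modelled, nor is any external-beam
contribution.

* Source parameters (`dosimetry.BEST_2301`): consensus-style constants for
  the Best Medical 2301 I-125 seed — Λ = 1.018 cGy·h⁻¹·U⁻¹, T½ = 59.4 d,
  tabulated g(r) (normalized to 1 at 1 cm) and φ_an(r). A generic I-125
  set with unit anisotropy (`GENERIC_I125`) is selectable.
* Tables are interpolated log-linearly in r. Beyond the last node the last
  tabulated value is held and only the inverse-square factor continues the
  fall-off (bounded, conservative tails).
* Radii below r_min = 1 mm are evaluated at 1 mm so the voxel containing a
  seed stays finite — standard planning-system practice; it affects only
  that voxel.
* Permanent-implant total dose is the initial rate times the mean life
  τ = T½/ln 2 ≈ 2057 h (≈ 20.6 Gy per cGy/h of initial rate).

## Segmentation

Voxels default to 1×1×1 mm (tests and large simulations use 2–2.5 mm;
sub-millimetre detail is below contouring accuracy). Membership is decided
by the voxel center: inside the nearest contoured prostate polygon, or
inside the 7 mm urethra disc of its plane. Urethral centers are linearly
interpolated between contoured slices.

Conventions chosen for determinism:

* The 1:2:1 apex/midgland/base split is measured per patient on the
  contoured z-extent; internal boundaries are half-open and owned by the
  superior zone (a voxel exactly at the apex/mid boundary is mid-gland).
* Anterior/posterior is decided per slice by the anterior–posterior
  coordinate of the urethral center; a voxel exactly on the line is
  posterior.
* Radial bands: Urethra r < 7 mm, Urethra10mm 7 ≤ r < 10 mm, Peripheral
  r ≥ 10 mm.
* The urethra disc can poke outside the prostate contour; those voxels stay
  in the labeled set (the urethra is its own subzone and participates in
  all three partition families). The "Prostate" zone includes overlapping
  urethra voxels; whether a whole-gland DVH should exclude the urethra is
  ambiguous in general, and this inclusive convention is fixed here.

## DVH and metrics

Cumulative DVHs are sampled on a fixed axis, 0–400% of the 110 Gy
prescription in 1% steps (401 nodes), as *fractional* volumes — fixed-length
commensurate vectors are what makes cross-patient PCA well-posed, and LDR
hotspots routinely exceed 200%. Empty zones (possible for tiny composites
in small glands) yield an all-zero curve flagged `empty` instead of an
error.

`D_x` uses the floor-node convention: the largest axis node whose volume
fraction still reaches x/100. This is exact for voxelized (piecewise
constant) dose distributions — a uniform 120% zone has D₉₀ = 120 exactly —
and within one 1% bin of the continuous quantile otherwise. `V_y` is read
off the curve with linear interpolation.

## Featurization

Per zone, the cohort's DVH matrix is mean-centered (no per-bin
standardization — all bins share units) and the first two principal
components are kept; each loading's sign is fixed so its sum is
non-negative. Patients with an empty zone project to 0 (the cohort mean).
Zones empty for every patient are dropped with a warning; zones with fewer
than three non-empty patients are an error. Scores are named
`<Zone>_PCA1/2`; two per zone × 48 zones = 96 spatial features, plus the
ten indicators = 106 columns.

Min–max scaling maps each column to [0, 1]; constant columns become
all-zero and are flagged. Pearson pruning walks columns in catalogue order
and drops any later column with |r| > 0.9 against an already-kept one,
recording the keeper. The dropped→keeper map is also how downstream
analyses reason about where a pruned zone's information went.

PCA and scaling are fitted once on the full cohort before any
train/test splitting. This mirrors the described architecture and shares
its leakage; the validation AUCs here are therefore selection-optimistic by
construction, which is one reason the acceptance checks compare against a
label-permuted null rather than an absolute bar.

## Outcome

Toxicity label 1 = no follow-up IPSS within 12 months returned to within
2 points of baseline. The band is one-sided (scores below baseline are an
improvement, not a failure to resolve) and a single qualifying visit
suffices; requiring sustained resolution would be a stricter variant the
data schema supports but the default does not apply.

## Model

* S&S validation: stratified random 80/20 train/test splits of the whole
  cohort (the test fraction is a package default; 0.2 is standard
  shuffle-split practice), mean test AUC over repeats as the score. The
  production default is 1000 repeats; desk-scale runs use fewer (below).
* SBS: at each step every leave-one-feature-out subset is scored; the
  removal with the highest mean AUC is applied (ties break to the earliest
  column). Stops at ⌊n/10⌋ features (one-in-ten rule). Because candidate
  RBF kernels differ from the current set's kernel by a single feature's
  squared-distance matrix, SBS uses an exact precomputed-kernel fast path
  (verified identical to refitting from raw features).
* Hyperparameters: RBF-SVM C ∈ [0, 100] (clamped to ≥ 10⁻³ for the solver),
  γ ∈ [10⁻⁵, 100]. PSO is a textbook global-best swarm (inertia 0.72,
  cognitive/social weights 1.49, velocity clamping, γ searched in log₁₀
  space), tuned once on the post-pruning feature set and frozen during SBS
  — per-iteration retuning would multiply the fit count a thousandfold for
  little benefit at these cohort sizes. Defaults when PSO is off:
  C = 10, γ = 0.05 (features live in [0, 1]).
* Accuracy/sensitivity/specificity use the SVM's natural decision threshold
  0 on each test split, averaged. With an AUC-only tuning objective the
  swarm can prefer very small γ, where ranking is preserved but the
  0-threshold collapses toward the majority class — reported AUC stays
  meaningful while threshold metrics can be unbalanced; they are reported
  as-is rather than re-thresholded.
* The mean ROC is the vertical average of per-split ROC curves on a fixed
  FPR grid (0–1, step 0.01), pinned to (0,0) and (1,1).
* Importance-by-removal: the final model refit without each selected
  feature, on the same split family; rows ascend by post-removal AUC.

## Univariate screen

Spearman ρ (mid-rank ties, asymptotic two-sided p) of each feature against
the label, plus the feature's standalone AUC folded to max(a, 1−a) so
protective predictors (e.g. high baseline IPSS, which predicts *resolution*)
report their discriminative ability above 0.5. Thresholds p < 0.05
(significant) and p < 0.1 (trend) are reported without multiplicity
adjustment, with Benjamini–Hochberg q-values emitted as an extra
transparency column that nothing downstream consumes.

## Synthetic cohorts

The generator emulates the study conditions: 85 patients by default, ~48%
toxicity prevalence, lognormal prostate volumes (median 35 cc, σ_log 0.3),
110 Gy prescription, and implants that pass the planning goals
(D₉₀ ≥ 100%, V₁₅₀ < 50%, urethra D_max < 150%).

* **Anatomy**: an ellipsoid (axis ratios ≈ 1 : 0.8 : 0.9 lateral : AP : SI)
  with low-order harmonic surface irregularity, contoured every 2.5 mm.
  Contours stop at 0.85 of the SI semi-axis — TRUS contours do not chase
  the gland tips, and untruncated tips cannot be seeded under the standoff
  and erosion rules — with semi-axes inflated so the contoured volume
  matches the sampled target. The urethra runs slightly posterior of
  center with a gentle per-patient drift.
* **Implant**: candidate sites on a 5 mm template (half-positions for
  small glands), z-planes every 5 mm plus cap planes 2.5 mm beyond the end
  slices; sites keep an 8 mm standoff from the urethral center and an
  adaptive erosion from the capsule. Seeds are drawn peripheral-first
  (85%) by greedy max–min-distance spread, ≈ 2 seeds/cc. Air-kerma
  strength is scaled analytically so D₉₀ hits ~103%, and a retry grid
  (escalating seed count, more peripheral weighting) re-plans until the
  goal checker passes. The D_max constraint is checked on a 3 mm-radius
  planning urethra: the 7 mm circle is the zone-definition surrogate for
  the peri-urethral region, while the dose constraint applies to the organ
  itself — enforcing 150% over the whole 7 mm disc is geometrically
  incompatible with interior seed placement. Needles = distinct template
  columns used.
* **Outcome mechanism**: toxicity probability =
  logistic(α + Σ β_z · z(zone mean dose) + β_IPSS · z(baseline IPSS)), with
  the intercept α calibrated by root-finding so the cohort-mean probability
  equals the prevalence target. Defaults plant β = ln 2 per SD on the
  `Apex_Urethra10mm` mean dose and −ln 2 per SD on baseline IPSS (higher
  baseline predicts resolution). Effects act on *true zone mean doses*,
  never on PCA scores, so recovering them through the DVH→PCA→SBS chain is
  a genuine end-to-end test. Baseline IPSS is a discretized Gamma(2, 3.5)
  clipped to [0, 35]. IPSS trajectories rise by +5..+15 points at ~3
  months and decay; the resolution time is placed before or after the
  12-month horizon according to the drawn label, so `label_toxicity`
  reproduces the latent label exactly.

What the generator does **not** emulate: EBRT dose summation, seed
migration or edema, contouring/registration error, correlated comorbidities,
loss to follow-up, and any real spatial dose–response anatomy beyond the
planted mechanism. Passing tests therefore demonstrate that the pipeline
recovers a known mechanism under clean conditions — not that the clinical
effect sizes or AUCs transfer to real cohorts.

## Problem sizes and seeds

Every stage draws from one master seed through named `SeedSequence`
children; identical seeds give byte-identical reports. Default test-scale
sizes, chosen as desk-scale study conditions: 2.5 mm voxels and 8 S&S
repeats for SBS scoring in the recovery study (n = 300 cohorts, 10
generator seeds, 200-repeat final and null AUCs), 2 mm voxels in the
acceptance script, 200 repeats for reported performance. The production
defaults (1 mm voxels, 1000 repeats) are configuration away and change no
code path.

## Known limitations

* The 1-D TG-43 model ignores seed orientation; φ_an(r) tables carry the
  residual anisotropy on average only.
* Fixed-axis DVHs cap at 400%; hotter voxels accumulate in the last bin
  (irrelevant for the metrics used, which sit far below the cap).
* Cohort-level PCA/scaling before splitting is leakage-prone by design
  fidelity; a split-wise refit would lower reported AUCs.
* The PSO budget is small (tens of evaluations); it finds good, not
  provably optimal, (C, γ).
* Threshold-0 sensitivity/specificity can be degenerate at AUC-optimal
  hyperparameters (see Model above).
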