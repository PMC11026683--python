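# capdyn

Co-activation pattern (CAP) analysis of resting-state fMRI as a tested,
reusable pipeline:

- **`capdyn.synthetic_cohort`** — synthetic cohorts with known ground truth:
  spatial co-activation topographies (anti-paired by construction) driven by
  a subject-level Markov state sequence, Gaussian noise, and optional
  per-group effects (amplitude scaling on voxel subsets, transition-matrix
  overrides). Writes NIfTI-1 scans, a binary mask, a CSV manifest and a JSON
  ground-truth record.
- **`capdyn.conditioning`** — the signal-conditioning chain: frame trimming,
  zero-phase Butterworth band-pass (0.01–0.2 Hz), re-trimming, quadratic
  detrending, nuisance regression, voxel-wise z-scoring (a 1,000-frame scan
  leaves 980 frames).
- **`capdyn.extraction`** — CAP extraction: per-frame rank thresholding
  (top 10% / bottom 5% of voxels), K-means++ clustering under correlation
  distance (1 − Pearson's r), explained variance over K = 2..30, elbow
  selection by the 0.5% fractional-gain rule, cohort/group CAP maps and
  CAP/anti-CAP pairing.
- **`capdyn.cap_stats`** — one-sample T maps (Bonferroni p < 0.01),
  voxel-wise two-way ANOVA (age × genotype) with interaction-dropping,
  BH-FDR post-hocs with an in-plane 10-voxel cluster-extent rule; occurrence
  percentage and mean duration with a mixed (repeated-measures) two-way
  ANOVA.
- **`capdyn.classifier`** — leakage-controlled genotype(-age) classification
  from CAP spatial or temporal features: per-iteration stratified 80/20
  splits, training-only CAP derivation, regularized multinomial logistic
  regression, shuffled-label chance baselines and Wilcoxon comparison over
  50 iterations, pooled confusion matrices.
- **`capdyn.transitions`** — persistence and inter-CAP transition
  probabilities pooled at group level, tested against per-subject
  label-permutation surrogates (10,000 by default) with add-one permutation
  p-values and BH-FDR; directionality (p_ij vs p_ji) and inter-group
  difference tests.
- **`capdyn.pipeline` / `capdyn.cli`** — one-config orchestration with
  seeds, logging, config-hash provenance in every CSV, and a figure report.

## CLI

```bash
# generate a synthetic cohort with known ground truth
capdyn simulate --out data/ --subjects-per-cell 2 --frames 980 --states 6 --seed 1

# full analysis from the manifest (extraction, statistics, classification,
# transitions); `capdyn all` additionally renders the report
capdyn all --manifest data/manifest.csv --mask data/mask.nii.gz \
           --out run/ --seed 1

# individual stages
capdyn extract --manifest data/manifest.csv --mask data/mask.nii.gz \
               --out run/ --k-range 2:9 --top-pct 10 --bottom-pct 5 --seed 1
capdyn classify --manifest data/manifest.csv --mask data/mask.nii.gz \
                --out run/ --mode spatial --classes 2 --age 4M --iters 50 --seed 1
capdyn report run/
```

All stages can also be driven from a single YAML config
(`capdyn all --config run.yaml`); CLI flags override config values.

## Layout

```
src/capdyn/          package modules (one per pipeline stage)
tests/               pytest suite incl. test_acceptance.py
scripts/acceptance.py
```
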