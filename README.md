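# painmorph

ROI-level gray-matter morphometry for chronic-pain cohorts: structural
covariance networks, ternary "barcode" signatures, and an exponential model
of whole-brain reorganization versus pain chronicity.

## The problem

Chronic pain conditions — chronic back pain (CBP), complex regional pain
syndrome (CRPS), knee osteoarthritis (OA) — reshape cortical gray matter
(GM) in condition-specific ways. When the cortex is parceled into 82
regions of interest (ROIs, approximating bilateral Brodmann areas) and each
subject is summarized by a vector of ROI GM densities, several questions
become tractable with ordinary statistics:

* Does total neocortical GM volume differ between groups once age, gender
  and intracranial volume (ICV) are controlled? (ANCOVA with planned
  patient-vs-healthy contrasts; per-group volume-vs-age slopes.)
* Which ROIs discriminate the conditions? (Per-ROI one-way ANOVA on
  confound-corrected densities, Holm–Bonferroni corrected, with an
  F-threshold selection rule.)
* How does the *structural covariance network* — the across-subject
  correlation of corrected density between ROI pairs — depend on the
  Euclidean distance between ROI centroids, and how do patients deviate
  from the healthy distance decay? (Pairwise regression, 25-mm distance
  bins, seed-ROI connection maps at r > 0.6.)
* Can a subject's whole-brain profile classify them? Each profile is
  z-scored against its own mean and ternarized at ±θ into {−1, 0, +1} — a
  *barcode*. θ is chosen by scanning a grid and trading off the sum of
  pairwise group-barcode correlations (minimized) against the joint entropy
  of the group symbols (kept near maximal). Subjects are assigned to the
  group barcode they correlate with best; accuracy is reported as
  per-class sensitivity/specificity, including held-out validation with
  group barcodes built from 5- or 10-subject training draws.
* How far has a patient's brain reorganized, and how fast does it happen?
  Barcode correlations map to similarity distances d = (r + 1)/2 and place
  each subject in a 2-D ternary space (three patient poles, healthy
  center). The distance Δd from the healthy mean is modelled against pain
  duration t as

  Δd(t) = Δd₀ + Δd₁ · (1 − exp(−t / τ)),

  where τ (years) is the characteristic time constant of reorganization
  and Δd₁ the asymptotic amplitude. Groups are summarized in the plane by
  Tukey-depth bagplots (depth median, 50 % bag, 3× fence).

Because no clinical MRI dataset ships with the package, a first-class
synthetic cohort generator (`painmorph.simulate`) produces cohorts with the
statistical structure the analyses assume: four groups (46/36/28/20
subjects), age-dependent volume decline of −2 to −3 cm³/yr,
distance-decaying inter-ROI covariance with a long-range lift in patients,
mutually anti-correlated group density signatures, and duration-dependent
signature expression with group-specific τ (CBP 11.72 yr, CRPS 1.71 yr —
slow and large versus fast and small).

## Worked example

```python
import painmorph as pm
from painmorph.barcode import classify_cohort

atlas = pm.build_default_atlas(seed=0)              # 82 mirrored ROIs
cohort = pm.simulate_cohort(atlas, pm.default_config(atlas, seed=0))
corrected = pm.residualize_gm(cohort)               # age/gender/ICV removed

scan = pm.optimize_threshold(corrected)             # theta* = 0.38 here
result = classify_cohort(corrected, theta=scan.theta_star)
report = pm.confusion_metrics(result["true"], result["pred"])
```

On this seed the full-cohort classification prints

```
healthy  sensitivity  71.7%  specificity  96.4%
CBP      sensitivity  88.9%  specificity  96.8%
CRPS     sensitivity  96.4%  specificity  99.0%
OA       sensitivity 100.0%  specificity  90.0%
```

against a 25 % chance level for four groups — the ternary signature alone
separates the conditions. Continuing to the chronicity model
(`examples/05_embedding_chronicity.py`) fits, for the CBP group,
τ = 7.8 yr with amplitude 0.083 (generator: τ = 11.72 yr); single-cohort τ
estimates are broad, and replicate-median recovery is what the acceptance
script reports. The `examples/` directory holds one short script per
capability (simulation + confound correction, regional statistics,
covariance networks, barcodes, embedding/chronicity); each prints the
numbers it computes with a line on what they mean.

A thin CLI mirrors the stages (`painmorph simulate|correct|stats|network|
barcode|embed|chronicity|run`); `painmorph run --seed 0 --out runs/demo`
executes the whole chain and writes a reproducible JSON report keyed by a
config hash.

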