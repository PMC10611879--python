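# recipet

Response assessment for longitudinal PSMA PET in prostate cancer:
threshold-based lesion delineation, whole-body tumour-volume
quantification, new-lesion detection, RECIP 1.0 classification, and the
prognostic and inter-rater statistics that validate such classifications
against overall survival.

## The problem

Patients with recurrent prostate cancer are imaged with PSMA-targeted
PET at baseline and again months later to judge whether disease has
progressed. RECIP 1.0 (Response Evaluation Criteria in PSMA PET/CT)
classifies each patient from two measurements taken between the scans:

* **ΔTTV** — the percentage change in whole-body total tumour volume,
  where TTV is the number of delineated lesion voxels times the voxel
  volume (mL);
* the appearance of **new lesions** — follow-up uptake foci with no
  spatial counterpart at baseline.

The four classes are

| class | rule |
|---|---|
| CR | no lesions on the follow-up scan |
| PR | ΔTTV ≤ −30% and no new lesions |
| PD | ΔTTV ≥ +20% **and** ≥ 1 new lesion |
| SD | everything else |

and the prognostically decisive dichotomy is PD vs non-PD. Validating
the criteria means showing that RECIP-PD patients die sooner: Kaplan–
Meier curves with the log-rank test, a univariate Cox model giving the
hazard ratio HR = exp(β) with Wald 95% CI, and Harrell's concordance
index. When two delineation methods (e.g. a human reader and an
automated one) classify the same patients, their concordance is
summarised by Cohen's κ = (p_o − p_e)/(1 − p_e), percent agreement, and
Spearman correlation of the underlying volumes.

Because paired clinical PET scans with expert contours and survival
follow-up are not shareable, the package ships a synthetic phantom
cohort generator (`recipet.synthetic`) that emulates all of it: paired
volumes with growing/appearing lesions (including faint ones below the
delineation threshold), physiologic-uptake distractors, imperfect
observers, and exponential proportional-hazards survival — so the whole
pipeline is testable offline.

## Worked example

```python
from recipet import TTVPair, classify_recip, delta_ttv

pair = TTVPair(baseline_ttv=7.86, followup_ttv=13.60)
delta = delta_ttv(pair)
print(f"{delta.percent:+.1f}%")                    # +73.0%
print(classify_recip(delta, new_lesions=1, pair=pair).value)  # PD
```

A tumour burden growing from 7.86 mL to 13.60 mL (+73.0%, a 5.74 mL
increase) together with one new lesion meets the PD definition.

Running `python examples/cohort_analysis.py` (40 synthetic patients,
seed 1) prints:

```
Patients analysed: 40
RECIP-PD: 4 (10.0%)
dTTV >= 20%: 5
Class counts: CR=3, PR=4, SD=29, PD=4
Log-rank: chi2=32.974, p=9.342e-09
Cox (RECIP-PD): HR=29.15 (95% CI 5.13-165.53), p=0.0001411, C-index=0.73
Agreement: 95.0% overall; kappa=0.72 (substantial)
...
```

i.e. 4/40 phantoms progressed, their mortality hazard is sharply higher
(small-sample HR estimates are wide; at n = 199 the fitted HR settles
near the generator's true value of 3.78), and the degraded observer
agrees with the reference reader on 95% of progression calls (κ = 0.72).

Other examples: `examples/worked_example_progression.py` (single
patient), `examples/delineate_phantom.py` (thresholding + manual-edit
emulation). A thin CLI wraps the same pipeline:
`recipet generate|classify|all --help`.

## Layout

* `recipet.imaging` — volume/mask geometry, SUV conversion, NIfTI I/O
* `recipet.delineation` — SUV thresholding, connected components, manual-edit emulation, lesion statistics
* `recipet.longitudinal` — baseline/follow-up lesion matching, new-lesion counting
* `recipet.recip` — TTV, ΔTTV, the four-class rule engine
* `recipet.survival` — Kaplan–Meier, log-rank, univariate Cox, Harrell's C
* `recipet.agreement` — Cohen's κ, percent agreement, Spearman, ΔTTV cutoff sweep
* `recipet.synthetic` — phantom cohort generator, observer models, survival simulation
* `recipet.pipeline` / `recipet.cli` — orchestration and the command-line front end

See `docs/methods.md` for the modelling choices and their rationale.
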