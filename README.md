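# spectscore

Automated quantification and risk stratification for myocardial SPECT
imaging: short-axis count volumes → polar maps → 17-segment scores →
summed scores (SSS/SRS/SDS/SBS) → outcome statistics.

## The problem

Stress myocardial perfusion SPECT (e.g. thallium-201) and resting fatty
acid metabolism SPECT (¹²³I-BMIPP) are read in clinical practice by
expert visual scoring of a 17-segment left-ventricle model: each segment
is graded 0 (normal) to 4 (absent uptake) and the grades are summed into
the **summed stress score** (SSS), **summed rest score** (SRS), **summed
difference score** (SDS = Σᵢ max(stressᵢ − restᵢ, 0)) and **summed
BMIPP score** (SBS). These indices predict cardiac events, but expert
scoring needs training that many community facilities lack. `spectscore`
implements a fully automated alternative plus the survival-analysis
toolkit used to evaluate it:

1. **Imaging** — maximal-count circumferential profiles from every
   short-axis slice, resampled into a ring×sector polar (bull's-eye)
   map and normalized to percent uptake relative to the single maximal
   data point (hottest bin = 100 %).
2. **Scoring** — the standard 17-segment partition (6 basal + 6 mid +
   4 apical + apex); each segment's mean % uptake, expressed relative
   to a normal database, is banded at 70/50/30/10 % into scores 0–4;
   a summed score ≥ 4 is classified abnormal (≤ 3 normal).
3. **Prognosis** — 2×2 contingency tables with positive/negative
   predictive values (including AND/OR combination of two abnormality
   flags), Kaplan–Meier curves with the log-rank test, Cox
   proportional-hazards fits (Efron ties) with global χ² increments
   quantifying added prognostic value, and ROC AUC with the DeLong test
   for correlated AUCs.
4. **Synthetic data** — LV phantoms (half-ellipsoid myocardial shell,
   polar-coordinate perfusion defects, Poisson noise) with analytic
   ground truth, and cohort simulation with exponential
   proportional-hazards event times — so the whole pipeline is testable
   without patient data.

## Worked example

Generate phantoms (a 5 %-severity defect fully covering the mid
anteroseptal segment on the stress image; clean rest and BMIPP images)
and score them:

```sh
spectscore --seed 1 phantom --out stress.npz --defect 60,90,0.3,0.7,0.05
spectscore --seed 1 phantom --out rest.npz  --tracer TL_REST
spectscore --seed 1 phantom --out bmipp.npz --tracer BMIPP
spectscore score --stress stress.npz --rest rest.npz --bmipp bmipp.npz \
    --patient-id demo --out report.json
```

`report.json` then contains

```
"summed":   {"SSS": 4, "SRS": 0, "SDS": 4, "SBS": 0}
"abnormal": {"SSS": true, "SRS": false, "SDS": true, "SBS": false}
```

exactly one stress segment (segment 8, mid anteroseptal) scored 4: its
mean uptake (~5 %) falls below the lowest band, SSS = SDS = 4 reaches
the abnormality cutoff, and the defect-free rest/BMIPP images score 0.

Simulate a 151-patient cohort and run the outcome battery:

```sh
spectscore --seed 9 cohort-sim --n 151 --out cohort.csv
spectscore prognosis cohort.csv --out prog/
```

`prog/` then holds the predictive-value table (SSS, SBS, and their
AND/OR combinations × all/hard events), baseline group comparisons, KM
curves with log-rank statistics, univariable and multivariable Cox fits
and ROC comparisons. With seed 9 the univariable diabetes hazard ratio
is 3.65 and SSS carries 1.20 per point; adding SSS to diabetes + LVEF
raises the model's global χ² by 8.2 (p = 0.004) — the "added prognostic
value" statistic.

As a library:

```python
from spectscore import (PhantomSpec, make_phantom, volume_to_polar_map,
                        build_segment_mask, score_polar_map, summed_score, Tracer)
volume, truth = make_phantom(PhantomSpec())
polar = volume_to_polar_map(volume)            # % uptake, max = 100
scores = score_polar_map(polar, build_segment_mask(), Tracer.TL_STRESS)
assert summed_score(scores) == 0               # defect-free phantom
```

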