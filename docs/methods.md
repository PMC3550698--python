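# Methods

This note records the quantitative model behind `spectscore`, the
choices made where the published description of such systems leaves the
arithmetic open, and what the synthetic-data tests do and do not
demonstrate.

## Polar-map quantification

**Input contract.** Volumes are assumed already reoriented to the short
axis (slice, row, col), apex-first unless flagged otherwise, with at
least 5 slices. Automatic reorientation from transaxial acquisitions is
scanner-specific and out of scope. The anterior wall is toward row 0;
the angular convention is fixed with sector 0 centered on the anterior
wall and angle increasing counterclockwise as seen from the apex
(anterior → septal → inferior → lateral).

**Circumferential profiles.** For each slice, counts are sampled by
bilinear interpolation along rays cast from the myocardial center, one
ray per angular bin (default 60 bins), with a step of half the smaller
in-plane voxel size; the profile value is the maximum along the ray.
The maximum (rather than a mean) follows standard maximal-count
circumferential profile analysis and makes normal territory robust to
adjacent defects: a normal bin next to a defect still finds
full-uptake samples on its own ray.

**Slice centering.** The center is initialized at the count-weighted
centroid and refined by three iterations of ridge centering: the center
is moved to the mean of the per-angle maximal-count positions. The raw
centroid is biased away from severe perfusion defects (a 5 %-severity,
90°-wide defect shifts it by several millimetres), which displaces the
apparent angular position of defect edges by up to two sectors; the
maximal-count radius is invariant to multiplicative severity, so the
refined center removes that parallax. On defect-free annuli both
definitions coincide.

**Polar map.** Profiles are resampled onto 36 rings × 60 sectors
(configurable; the sector count must be divisible by 6 and 4 for the
segment model). Ring 0 — the apical cap — carries the angular mean of
the most apical slice profile; rings 1…R−1 interpolate linearly along
the long axis with the apical slice innermost and the basal slice at
the rim. Uptake is then normalized to percent of the single maximal
bin, so the map maximum is exactly 100 % and percent uptake is
invariant under rescaling of the acquisition counts. A percentile
normalization option exists in the scoring configuration but is off by
default.

**A property of max-point normalization worth knowing.** Because the
denominator is the *extreme* over ~2000 bins, Poisson noise inflates it
and depresses every normalized value by a common factor (~6 % at 500
peak counts). The effect cancels out of any analysis that compares a
patient to a normal database built at similar count statistics, but it
means noisy segment means are not unbiased estimates of noise-free
percent uptake; the normal-database test therefore checks the uptake
*pattern* rather than the absolute level.

## 17-segment scoring

The mask partitions the grid exactly: an apical core of ⌈R/9⌉ rings is
segment 17; the remaining rings split into apical/mid/basal thirds by
floor division with the remainder assigned to the basal (outermost)
zone; basal and mid zones use six 60° wedges (segments 1–6 and 7–12,
counterclockwise from anterior), the apical zone four 90° wedges
(13–16). Sectors are assigned by their center angle, so any sector
count divisible by 6 and 4 yields an exact partition with all 17
segments non-empty.

Each segment's **mean** % uptake is computed first and the mean is
scored (not per-bin scoring then averaging). Scoring uses uptake
relative to the segment's normal-database mean, capped at 100 %:

    relative = min(100 · mean_uptake / normal_mean, 100)
    score    = #{boundaries strictly above relative}

with default boundaries (70, 50, 30, 10) % — the conventional 5-point
bands, fully configurable since published threshold sets vary. Equality
with a boundary takes the milder score (inclusive downward); the
direction is arbitrary but must be fixed for exact tests. The shipped
default normal database is uniform 100 % (scoring then reduces to raw
% uptake bands); `build_normal_db` constructs a per-segment mean/SD
database from a defect-free phantom population, and rejects degenerate
(zero-SD) populations.

SSS/SRS/SBS are plain sums (range 0–68). SDS clamps per-segment
negative differences to zero, so SDS ≥ 0 always and SDS = SSS − SRS
whenever no segment reverses. A summed score ≥ 4 is abnormal, ≤ 3
normal; the cutoff is configurable.

## Outcome statistics

Cohorts are plain CSV tables (one row per patient; covariates, summed
scores, follow-up days, event ∈ {none, soft, hard}). Patients have at
most one terminal event. The ALL event class counts soft + hard; HARD
counts hard only and, by default, censors soft events at their event
time (`CENSOR_AT_SOFT`); dropping soft-event patients entirely
(`DROP_SOFT`) is implemented as the alternative policy since published
analyses rarely state the rule.

* Kaplan–Meier and the two-group log-rank test are delegated to
  lifelines; with no censoring KM equals the empirical survival
  function, which the tests verify against a hand-written
  product-limit oracle.
* Cox fits use the partial likelihood with Efron tie handling and Wald
  95 % CIs. Constant covariates, exact collinearity, zero events and
  non-convergence raise explicit errors. The global χ² is the
  likelihood-ratio statistic against the null model; the added value of
  an extra covariate is the difference of global χ² between nested fits,
  referred to a χ² distribution with df = number of added covariates.
* ROC AUC is the normalized Mann–Whitney U (ties ½), computed by
  scikit-learn and verified against O(n²) pair enumeration; the paired
  comparison of two AUCs on the same subjects uses the DeLong
  placement-value variance, implemented here.
* Predictive values are PPV = TP/(TP+FP)·100 and NPV = TN/(TN+FN)·100,
  reported both unrounded and to the nearest integer percent; an empty
  denominator yields an explicit undefined value, never zero.
  Abnormality flags combine with AND (both abnormal) or OR (either).
* Baseline tables use the unpaired equal-variance t-test for continuous
  variables and Pearson's χ² without continuity correction for
  categorical ones; no multiple-testing correction is applied anywhere.
* Follow-up is stored in days; months convert at 30.44 days/month for
  display only.

## Synthetic data

**Phantom.** The myocardium is a half-ellipsoid shell: midwall radius
r(f) = R·√(1 − (1−f)²) for apex→base fraction f, R = 30 mm at the base,
with a Gaussian transmural profile of scale 4 mm (an effective wall
thickness) and 500 peak counts. Defects are defined in polar
coordinates (center angle, width, long-axis span, multiplicative
severity), so the noise-free ground truth is computable analytically on
the polar grid using the same ring→long-axis mapping as the polar-map
builder — independent of the ray-marching, centering and normalization
steps it validates. Overlapping defects compose multiplicatively (with
a warning). Poisson noise, when enabled, is applied last and seeded.
The default grid is 24 slices of 64×64 at 3.2 mm isotropic voxels —
SPECT-like sampling at which voxel quantization of the wall profile
spreads normalized segment means over roughly 90–100 % (all scoring 0);
quantitative uptake-agreement tests use a 1.0 mm in-plane grid (96×96),
where pipeline and analytic truth agree within 2 % uptake, including
phantoms with severe and moderate defects.

**Cohort simulator.** Covariates are drawn independently with
cohort-realistic defaults (n = 151; diabetes prevalence 14 %; LVEF
69 ± 8 %; age 65 ± 10; 55 % male). Seventeen stress segment scores per
patient are i.i.d. categorical with p(0…4) = (0.93, 0.04, 0.015, 0.01,
0.005), giving the low-score-skewed SSS distribution (mean ≈ 2) typical
of stable coronary cohorts without prior infarction; rest scores are
binomial thinning of stress scores (retention 0.45), which makes
SDS ≥ 0 structural; BMIPP segment scores copy the stress segment with
probability 0.6, else are drawn independently (configurable
correlation). Event times are exponential with rate
h₀·exp(β_DM·DM + β_SSS·SSS), default β_DM = log 6.1 and β_SSS =
log 1.18 per point, h₀ = 4·10⁻⁵/day, administratively censored at
2500 days — the marginal event fraction lands near 19 %. An observed
event is hard with probability 0.25. All generators are byte-identical
under a fixed seed.

**What the synthetic tests show — and don't.** Phantoms have no
attenuation, scatter, collimator blur or motion, and the cohort
simulator has independent covariates, exponential baseline hazard and
exactly proportional hazards. Passing tests therefore demonstrate the
*correctness of the algorithms under their stated model* (exact
partition, monotone scoring, unbiased Cox recovery, oracle-identical
KM/log-rank/AUC), not robustness to real acquisition physics or to
violations of proportional hazards.

## Numerical choices and degenerate inputs

* Ray step = half the smaller in-plane voxel size; bilinear
  interpolation with zero padding outside the grid.
* All-zero slices yield zero profiles and are flagged; all-zero volumes
  are an error ("empty volume"); single-slice stacks are an error
  ("insufficient slices"); an all-zero polar map cannot be normalized
  ("no counts").
* Score boundaries must be strictly decreasing within (0, 100); the
  normal database requires means in (0, 100] and positive SDs.
* A 2×2 table with a zero margin returns χ² = 0, p = 1 rather than an
  error (it carries no association information).
* Problem sizes in the test suite and acceptance script — 100 Cox
  replicates at n = 2000, χ² increments at n = 500, 200-point oracle
  fixtures — were chosen to make Monte-Carlo conclusions stable
  (CI-coverage standard error ≈ 2 %) while keeping a full run in the
  tens of seconds on one CPU.

## Known limitations

* No attenuation/scatter correction, gating, or LVEF computation from
  images (LVEF is a cohort covariate).
* Normalization to a single maximal data point is noise-sensitive (see
  above); the percentile option mitigates this but is off by default to
  preserve the max-point contract.
* The default threshold bands are the conventional ones, not a claim
  about any particular commercial system's calibrated thresholds.
* Competing risks, time-dependent covariates and propensity adjustment
  are out of scope.
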