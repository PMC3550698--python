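"""Synthetic inputs: LV phantom volumes and proportional-hazards cohorts.

Two generators make every stage of the pipeline testable without any
patient data:

* :func:`make_phantom` builds a left-ventricle-shaped count volume — a
  half-ellipsoid myocardial shell with a Gaussian transmural count
  profile — with perfusion defects defined in polar coordinates
  (angle x long-axis span x severity) and optional Poisson count noise.
  Because defects live in polar coordinates, the noise-free per-segment
  % uptake is computable analytically and returned as ground truth.

* :func:`simulate_cohort` draws covariates and 17-segment scores per
  patient and generates event times from an exponential
  proportional-hazards model, with administrative censoring and a
  configurable hard/soft event split. The defaults emulate a
  stable-coronary-disease cohort: low-score-skewed summed scores,
  ~14 % diabetes prevalence, LVEF 69 +/- 8 %, a diabetes log-hazard of
  log 6.1 and a per-SSS-point log-hazard of log 1.18, censored at
  2500 days.

Both generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import (
    DEFAULT_N_RINGS,
    DEFAULT_N_SECTORS,
    ShortAxisVolume,
    Tracer,
    volume_to_polar_map,
)
from .scoring import N_SEGMENTS, NormalDatabase, SegmentMask, build_segment_mask

__all__ = [
    "Defect",
    "PhantomSpec",
    "CohortSpec",
    "make_phantom",
    "phantom_truth_polar",
    "simulate_cohort",
    "build_normal_db",
]


@dataclass(frozen=True)
class Defect:
    """A perfusion defect in polar coordinates.

    ``center_deg``/``width_deg`` give the angular extent (same convention
    as the polar map: 0 = anterior, counterclockwise through septal);
    ``span`` is the long-axis extent as fractions of apex(0)->base(1);
    ``severity`` multiplies normal counts (0 = absent uptake, 1 = none).
    """

    center_deg: float
    width_deg: float
    span: tuple[float, float] = (0.0, 1.0)
    severity: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        if self.width_deg <= 0:
            raise ValueError("width_deg must be positive")
        lo, hi = self.span
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("span must satisfy 0 <= lo < hi <= 1")

    def covers(self, angle_deg: np.ndarray, axial_frac: np.ndarray) -> np.ndarray:
        """Boolean membership for broadcastable angle/axial arrays."""
        delta = np.abs((np.asarray(angle_deg) - self.center_deg + 180.0) % 360.0 - 180.0)
        in_angle = delta <= self.width_deg / 2.0
        f = np.asarray(axial_frac)
        in_span = (f >= self.span[0]) & (f <= self.span[1])
        return in_angle & in_span


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, defects and noise of a synthetic LV volume.

    The myocardium is a half-ellipsoid shell: midwall radius grows from 0
    at the apex to ``base_radius_mm`` at the base, and counts fall off as
    a Gaussian of the distance to the midwall with scale ``wall_sigma_mm``
    (an effective wall thickness).
    """

    n_slices: int = 24
    grid: tuple[int, int] = (64, 64)
    voxel_size_mm: tuple[float, float, float] = (3.2, 3.2, 3.2)
    base_radius_mm: float = 30.0
    wall_sigma_mm: float = 4.0
    peak_counts: float = 500.0
    defects: tuple[Defect, ...] = field(default_factory=tuple)
    poisson_noise: bool = False
    tracer: Tracer = Tracer.TL_STRESS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 5:
            raise ValueError("n_slices must be >= 5")
        if self.peak_counts <= 0:
            raise ValueError("peak_counts must be positive")
        object.__setattr__(self, "defects", tuple(self.defects))


def _defect_multiplier(defects, angle_deg, axial_frac) -> np.ndarray:
    """Multiplicative uptake factor; overlapping defects compose."""
    mult = np.ones(np.broadcast(np.asarray(angle_deg), np.asarray(axial_frac)).shape)
    for d in defects:
        mult = np.where(d.covers(angle_deg, axial_frac), mult * d.severity, mult)
    return mult


def make_phantom(spec: PhantomSpec) -> tuple[ShortAxisVolume, np.ndarray]:
    """Build a phantom volume and its ground-truth segment % uptake.

    Returns the short-axis volume (apex at slice 0) and the noise-free
    per-segment mean % uptake under the default 36x60 segment mask (see
    :func:`phantom_truth_polar` for the polar-grid ground truth).
    """
    overlaps = sum(
        d1.covers(np.array(d2.center_deg), np.array(sum(d2.span) / 2.0))
        for i, d1 in enumerate(spec.defects)
        for d2 in spec.defects[i + 1 :]
    )
    if np.any(overlaps):
        warnings.warn("overlapping defects compose multiplicatively", stacklevel=2)

    n_rows, n_cols = spec.grid
    vz, vr, vc = spec.voxel_size_mm
    cr, cc = (n_rows - 1) / 2.0, (n_cols - 1) / 2.0
    row_mm = (np.arange(n_rows) - cr) * vr
    col_mm = (np.arange(n_cols) - cc) * vc
    rr, cc_ = np.meshgrid(row_mm, col_mm, indexing="ij")
    rho = np.hypot(rr, cc_)
    # angle convention: anterior = -row, septal = -col
    angle = np.degrees(np.arctan2(-cc_, -rr)) % 360.0

    counts = np.empty((spec.n_slices, n_rows, n_cols))
    for s in range(spec.n_slices):
        f = s / (spec.n_slices - 1)  # 0 = apex, 1 = base
        r_mid = spec.base_radius_mm * np.sqrt(max(1.0 - (1.0 - f) ** 2, 0.0))
        radial = np.exp(-((rho - r_mid) ** 2) / (2.0 * spec.wall_sigma_mm**2))
        counts[s] = spec.peak_counts * radial * _defect_multiplier(spec.defects, angle, f)

    if spec.poisson_noise:
        rng = np.random.default_rng(spec.seed)
        counts = rng.poisson(counts).astype(float)

    volume = ShortAxisVolume(
        counts=counts, voxel_size_mm=spec.voxel_size_mm, apex_first=True, tracer=spec.tracer
    )
    mask = build_segment_mask(DEFAULT_N_RINGS, DEFAULT_N_SECTORS)
    truth_polar = phantom_truth_polar(spec, DEFAULT_N_RINGS, DEFAULT_N_SECTORS)
    truth_seg = np.array(
        [truth_polar[mask.assignment == seg].mean() for seg in range(1, N_SEGMENTS + 1)]
    )
    return volume, truth_seg


def phantom_truth_polar(
    spec: PhantomSpec,
    n_rings: int = DEFAULT_N_RINGS,
    n_sectors: int = DEFAULT_N_SECTORS,
) -> np.ndarray:
    """Noise-free % uptake of the phantom on the polar grid.

    Mirrors the polar-map builder's geometry: per-slice defect
    multipliers are interpolated linearly along the long axis at each
    ring's slice coordinate, and ring 0 is the apical slice's angular
    mean. Independent of the ray-marching, centroid and normalization
    steps of the imaging chain.
    """
    angles = np.arange(n_sectors) * (360.0 / n_sectors)
    fracs = np.arange(spec.n_slices) / (spec.n_slices - 1)
    per_slice = np.stack([_defect_multiplier(spec.defects, angles, f) for f in fracs])

    out = np.empty((n_rings, n_sectors))
    out[0] = per_slice[0].mean()
    t = np.linspace(0.0, spec.n_slices - 1.0, n_rings - 1)
    lo = np.floor(t).astype(int)
    hi = np.minimum(lo + 1, spec.n_slices - 1)
    frac = (t - lo)[:, None]
    out[1:] = per_slice[lo] * (1.0 - frac) + per_slice[hi] * frac
    return out * 100.0


DEFAULT_SEGMENT_SCORE_PROBS = (0.93, 0.04, 0.015, 0.01, 0.005)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the simulated outcome cohort (see module docstring)."""

    n: int = 151
    age_mean: float = 65.0
    age_sd: float = 10.0
    male_frac: float = 0.55
    dm_prev: float = 0.14
    lvef_mean: float = 69.0
    lvef_sd: float = 8.0
    htn_prev: float = 0.50
    dyslipidemia_prev: float = 0.30
    smoking_prev: float = 0.32
    uap_prev: float = 0.10
    ace_prev: float = 0.13
    bb_prev: float = 0.15
    ccb_prev: float = 0.49
    segment_score_probs: tuple[float, ...] = DEFAULT_SEGMENT_SCORE_PROBS
    rest_retention: float = 0.45
    bmipp_correlation: float = 0.6
    log_hr: dict = field(default_factory=lambda: {"dm": float(np.log(6.1)), "sss": float(np.log(1.18))})
    baseline_hazard: float = 4e-5  # events per day
    censor_days: float = 2500.0
    hard_frac: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censor_days <= 0:
            raise ValueError("censor_days must be positive")
        probs = np.asarray(self.segment_score_probs, dtype=float)
        if probs.shape != (5,) or abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
            raise ValueError("segment_score_probs must be 5 non-negative values summing to 1")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort with proportional-hazards event times.

    Event time is exponential with rate ``baseline_hazard x exp(sum of
    log-HR x covariate)``; patients are censored administratively at
    ``censor_days``. An observed event is hard with probability
    ``hard_frac`` and soft otherwise.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    age = rng.normal(spec.age_mean, spec.age_sd, n).round(1)
    sex = (rng.random(n) < spec.male_frac).astype(int)
    dm = (rng.random(n) < spec.dm_prev).astype(int)
    lvef = np.clip(rng.normal(spec.lvef_mean, spec.lvef_sd, n), 15.0, 90.0).round(1)
    binaries = {
        name: (rng.random(n) < prev).astype(int)
        for name, prev in [
            ("htn", spec.htn_prev), ("dyslipidemia", spec.dyslipidemia_prev),
            ("smoking", spec.smoking_prev), ("uap", spec.uap_prev),
            ("ace", spec.ace_prev), ("bb", spec.bb_prev), ("ccb", spec.ccb_prev),
        ]
    }

    probs = np.asarray(spec.segment_score_probs)
    stress_seg = rng.choice(5, size=(n, N_SEGMENTS), p=probs)
    rest_seg = rng.binomial(stress_seg, spec.rest_retention)
    copy_mask = rng.random((n, N_SEGMENTS)) < spec.bmipp_correlation
    bmipp_indep = rng.choice(5, size=(n, N_SEGMENTS), p=probs)
    bmipp_seg = np.where(copy_mask, stress_seg, bmipp_indep)

    sss = stress_seg.sum(axis=1)
    srs = rest_seg.sum(axis=1)
    sds = (stress_seg - rest_seg).clip(min=0).sum(axis=1)
    sbs = bmipp_seg.sum(axis=1)

    covariate_values = {
        "age": age, "sex": sex, "dm": dm, "lvef": lvef,
        "sss": sss, "srs": srs, "sds": sds, "sbs": sbs, **binaries,
    }
    linpred = np.zeros(n)
    for name, beta in spec.log_hr.items():
        if name not in covariate_values:
            raise ValueError(f"unknown covariate in log_hr: {name!r}")
        linpred += beta * covariate_values[name]
    rate = spec.baseline_hazard * np.exp(linpred)

    t_event = rng.exponential(1.0 / rate)
    if (rate * spec.censor_days).max() < 0.01:
        warnings.warn("hazard so low that essentially no events occur before censoring", stacklevel=2)
    observed = t_event <= spec.censor_days
    followup = np.minimum(t_event, spec.censor_days).round(1)
    hard = rng.random(n) < spec.hard_frac
    event = np.where(observed, np.where(hard, "hard", "soft"), "none")

    return pd.DataFrame(
        {
            "id": [f"P{i:04d}" for i in range(n)],
            "age": age, "sex": sex, "dm": dm, "lvef": lvef,
            "htn": binaries["htn"], "dyslipidemia": binaries["dyslipidemia"],
            "smoking": binaries["smoking"], "uap": binaries["uap"],
            "ace": binaries["ace"], "bb": binaries["bb"], "ccb": binaries["ccb"],
            "sss": sss, "srs": srs, "sds": sds, "sbs": sbs,
            "followup_days": followup, "event": event,
        }
    )


def build_normal_db(
    population: list[PhantomSpec],
    mask: SegmentMask | None = None,
    min_sd: float = 1e-6,
) -> NormalDatabase:
    """Per-segment mean/SD of % uptake across a defect-free phantom population.

    The population must be defect-free (it defines "normal"); identical
    noise-free phantoms produce a degenerate zero SD and are rejected —
    add Poisson noise or vary the specs to obtain a usable spread.
    """
    if len(population) < 2:
        raise ValueError("normal database needs at least 2 phantoms")
    if any(spec.defects for spec in population):
        raise ValueError("normal-database population must be defect-free")
    mask = mask if mask is not None else build_segment_mask()

    tracer = population[0].tracer
    seg_uptake = []
    for spec in population:
        volume, _ = make_phantom(spec)
        polar = volume_to_polar_map(volume, mask.n_rings, mask.n_sectors)
        seg_uptake.append(
            [polar.uptake[mask.assignment == seg].mean() for seg in range(1, N_SEGMENTS + 1)]
        )
    arr = np.asarray(seg_uptake)
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1)
    if np.any(sds <= min_sd):
        raise ValueError(
            "degenerate SD: population segment uptakes are (near-)identical; "
            "add Poisson noise or vary the phantom specs"
        )
    return NormalDatabase(means={tracer: means}, sds={tracer: sds})
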