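"""17-segment scoring of polar maps and summed scores (SSS/SRS/SDS/SBS).

The polar map is partitioned into the standard 17-segment left-ventricle
model (6 basal, 6 mid, 4 apical segments plus an apical cap). Each
segment's mean % uptake, expressed relative to a normal database, is
mapped onto the conventional 5-point scale — 0 (normal) to 4 (absent
uptake) — and the 17 scores are summed into the global abnormality
indices: summed stress score (SSS), summed rest score (SRS), summed
difference score (SDS, stress minus rest clamped at zero per segment)
and summed BMIPP score (SBS). A summed score of >= 4 is classified
abnormal; <= 3 is normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .imaging import DEFAULT_N_RINGS, DEFAULT_N_SECTORS, PolarMap, Tracer

__all__ = [
    "SegmentMask",
    "ThresholdTable",
    "NormalDatabase",
    "SegmentScores",
    "SummedScores",
    "build_segment_mask",
    "segment_mean_uptake",
    "score_segment",
    "score_polar_map",
    "summed_score",
    "summed_difference",
    "classify_abnormal",
    "DEFAULT_THRESHOLDS",
    "uniform_normal_db",
    "SEGMENT_NAMES",
]

N_SEGMENTS = 17
ABNORMAL_CUTOFF = 4  # summed score >= 4 is abnormal, <= 3 normal

SEGMENT_NAMES = (
    "basal anterior",
    "basal anteroseptal",
    "basal inferoseptal",
    "basal inferior",
    "basal inferolateral",
    "basal anterolateral",
    "mid anterior",
    "mid anteroseptal",
    "mid inferoseptal",
    "mid inferior",
    "mid inferolateral",
    "mid anterolateral",
    "apical anterior",
    "apical septal",
    "apical inferior",
    "apical lateral",
    "apex",
)


@dataclass(frozen=True)
class ThresholdTable:
    """Four strictly decreasing % relative-uptake cut points for scores 0-4.

    A segment whose relative uptake lies at or above ``boundaries[0]``
    scores 0; below ``boundaries[3]`` scores 4. Equality with a boundary
    takes the milder score (inclusive downward).
    """

    boundaries: tuple[float, float, float, float] = (70.0, 50.0, 30.0, 10.0)

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.boundaries)
        if len(b) != 4:
            raise ValueError("exactly 4 boundaries required")
        if any(not (0.0 < x < 100.0) for x in b):
            raise ValueError("boundaries must lie in (0, 100)")
        if any(b[i] <= b[i + 1] for i in range(3)):
            raise ValueError("boundaries must be strictly decreasing")
        object.__setattr__(self, "boundaries", b)


DEFAULT_THRESHOLDS = ThresholdTable()


@dataclass(frozen=True)
class NormalDatabase:
    """Per-segment normal mean % uptake and SD, per tracer.

    Scoring divides a patient's segment mean uptake by the corresponding
    normal mean (x100, capped at 100) before applying the threshold
    bands. The shipped default is a uniform 100 % database, which reduces
    scoring to the raw % uptake bands.
    """

    means: dict[Tracer, np.ndarray]
    sds: dict[Tracer, np.ndarray]

    def __post_init__(self) -> None:
        means = {Tracer(k): np.asarray(v, dtype=float) for k, v in self.means.items()}
        sds = {Tracer(k): np.asarray(v, dtype=float) for k, v in self.sds.items()}
        for tracer, m in means.items():
            if m.shape != (N_SEGMENTS,):
                raise ValueError("normal means must have 17 entries per tracer")
            if np.any(m <= 0) or np.any(m > 100):
                raise ValueError("normal means must lie in (0, 100]")
            sd = sds.get(tracer)
            if sd is None or sd.shape != (N_SEGMENTS,):
                raise ValueError("normal SDs must have 17 entries per tracer")
            if np.any(sd <= 0):
                raise ValueError("normal SDs must be positive")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)

    def mean_for(self, tracer: Tracer, segment_id: int) -> float:
        if not 1 <= segment_id <= N_SEGMENTS:
            raise ValueError(f"unknown segment id {segment_id}")
        return float(self.means[Tracer(tracer)][segment_id - 1])


def uniform_normal_db(sd: float = 5.0) -> NormalDatabase:
    """Uniform 100 % normal database for all tracers (default)."""
    means = {t: np.full(N_SEGMENTS, 100.0) for t in Tracer}
    sds = {t: np.full(N_SEGMENTS, float(sd)) for t in Tracer}
    return NormalDatabase(means=means, sds=sds)


@dataclass(frozen=True)
class SegmentMask:
    """Assignment of every (ring, sector) bin to one segment id in 1..17."""

    assignment: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        ids = np.unique(a)
        if ids.min() < 1 or ids.max() > N_SEGMENTS or ids.size != N_SEGMENTS:
            raise ValueError("mask must assign every bin to 1..17 with all 17 segments non-empty")
        object.__setattr__(self, "assignment", a)

    @property
    def n_rings(self) -> int:
        return self.assignment.shape[0]

    @property
    def n_sectors(self) -> int:
        return self.assignment.shape[1]


def _six_fold(angle_deg: np.ndarray) -> np.ndarray:
    # anterior-centered 60 deg wedges: 0=anterior, 1=anteroseptal, ... 5=anterolateral
    return np.floor(((angle_deg + 30.0) % 360.0) / 60.0).astype(int)


def _four_fold(angle_deg: np.ndarray) -> np.ndarray:
    # anterior-centered 90 deg wedges: 0=anterior, 1=septal, 2=inferior, 3=lateral
    return np.floor(((angle_deg + 45.0) % 360.0) / 90.0).astype(int)


def build_segment_mask(
    n_rings: int = DEFAULT_N_RINGS, n_sectors: int = DEFAULT_N_SECTORS
) -> SegmentMask:
    """Partition an (n_rings, n_sectors) polar grid into the 17 segments.

    Ring zones, inside out: an apical core of ceil(n_rings/9) rings is
    segment 17; the remaining rings split into apical/mid/basal thirds by
    floor division with the remainder given to the basal (outermost)
    zone. Sectors are assigned by their center angle: 60 deg wedges for
    basal and mid segments, 90 deg wedges for the four apical segments.
    """
    if n_sectors % 6 != 0 or n_sectors % 4 != 0:
        raise ValueError("n_sectors must be divisible by 6 and by 4")
    if n_rings < 4:
        raise ValueError("n_rings must be >= 4")

    core = math.ceil(n_rings / 9)
    rem = n_rings - core
    third = rem // 3
    if third < 1:
        raise ValueError("n_rings too small to form basal/mid/apical zones")
    n_apical = third
    n_mid = third
    n_basal = rem - 2 * third  # remainder goes to the basal zone

    angles = np.arange(n_sectors) * (360.0 / n_sectors)
    s6 = _six_fold(angles)
    s4 = _four_fold(angles)

    assignment = np.empty((n_rings, n_sectors), dtype=int)
    assignment[:core] = 17
    assignment[core : core + n_apical] = 13 + s4[None, :]
    assignment[core + n_apical : core + n_apical + n_mid] = 7 + s6[None, :]
    assignment[core + n_apical + n_mid :] = 1 + s6[None, :]
    assert core + n_apical + n_mid + n_basal == n_rings
    return SegmentMask(assignment=assignment)


def segment_mean_uptake(polar: PolarMap, mask: SegmentMask) -> np.ndarray:
    """Arithmetic mean % uptake of each of the 17 segments."""
    if polar.uptake.shape != mask.assignment.shape:
        raise ValueError("polar map and segment mask dimensions differ")
    means = np.empty(N_SEGMENTS)
    for seg in range(1, N_SEGMENTS + 1):
        means[seg - 1] = polar.uptake[mask.assignment == seg].mean()
    return means


def score_segment(
    mean_pct: float,
    tracer: Tracer,
    thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
    normaldb: NormalDatabase | None = None,
    segment_id: int = 1,
) -> int:
    """Score one segment 0 (normal) to 4 (absent uptake).

    Relative uptake = mean_pct / normal mean x 100, capped at 100; the
    score is the number of threshold boundaries strictly above the
    relative uptake (equality with a boundary takes the milder score).
    """
    if not 0.0 <= mean_pct <= 100.0:
        raise ValueError("mean_pct must be in [0, 100]")
    db = normaldb if normaldb is not None else uniform_normal_db()
    relative = min(mean_pct / db.mean_for(tracer, segment_id) * 100.0, 100.0)
    return int(sum(b > relative for b in thresholds.boundaries))


@dataclass(frozen=True)
class SegmentScores:
    """17 segment scores for one tracer, with the segment mean uptakes."""

    scores: tuple[int, ...]
    tracer: Tracer
    segment_mean_uptake: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        scores = tuple(int(s) for s in self.scores)
        if len(scores) != N_SEGMENTS:
            raise ValueError("exactly 17 segment scores required")
        if any(s not in (0, 1, 2, 3, 4) for s in scores):
            raise ValueError("segment scores must be integers in 0..4")
        object.__setattr__(self, "scores", scores)
        if self.segment_mean_uptake:
            up = tuple(float(u) for u in self.segment_mean_uptake)
            if len(up) != N_SEGMENTS or any(not (0.0 <= u <= 100.0) for u in up):
                raise ValueError("segment mean uptakes must be 17 values in [0, 100]")
            object.__setattr__(self, "segment_mean_uptake", up)


def score_polar_map(
    polar: PolarMap,
    mask: SegmentMask,
    tracer: Tracer,
    thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
    normaldb: NormalDatabase | None = None,
) -> SegmentScores:
    """Score a normalized polar map segment by segment."""
    if not polar.normalized:
        raise ValueError("polar map must be normalized to % uptake before scoring")
    means = segment_mean_uptake(polar, mask)
    scores = tuple(
        score_segment(means[i], tracer, thresholds, normaldb, segment_id=i + 1)
        for i in range(N_SEGMENTS)
    )
    return SegmentScores(scores=scores, tracer=tracer, segment_mean_uptake=tuple(means))


def summed_score(scores: SegmentScores) -> int:
    """Sum of the 17 segment scores (0..68)."""
    return int(sum(scores.scores))


def summed_difference(stress: SegmentScores, rest: SegmentScores) -> int:
    """SDS: per-segment stress minus rest, clamped at zero, summed.

    Requires stress-thallium and rest-thallium score sets; a segment
    whose rest score exceeds its stress score contributes 0.
    """
    if stress.tracer != Tracer.TL_STRESS or rest.tracer != Tracer.TL_REST:
        raise ValueError("SDS requires stress-thallium and rest-thallium scores")
    return int(sum(max(s - r, 0) for s, r in zip(stress.scores, rest.scores)))


def classify_abnormal(summed: int, cutoff: int = ABNORMAL_CUTOFF) -> bool:
    """True if a summed score is abnormal (>= cutoff; default >= 4)."""
    if summed < 0:
        raise ValueError("summed score must be non-negative")
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    return summed >= cutoff


@dataclass(frozen=True)
class SummedScores:
    """Per-patient summed scores; None where the tracer was not acquired."""

    sss: int | None = None
    srs: int | None = None
    sds: int | None = None
    sbs: int | None = None

    def __post_init__(self) -> None:
        for name in ("sss", "srs", "sbs"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 4 * N_SEGMENTS:
                raise ValueError(f"{name.upper()} must lie in [0, 68]")
        if self.sds is not None:
            if self.sss is None:
                raise ValueError("SDS requires SSS")
            if not 0 <= self.sds <= self.sss:
                raise ValueError("SDS must lie in [0, SSS]")
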