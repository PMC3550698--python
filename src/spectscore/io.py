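"""File formats, run configuration and provenance headers.

Volumes are read from NIfTI (``.nii``/``.nii.gz``, voxel sizes from the
header) or ``.npz`` (keys ``counts``, ``voxel_size_mm``); a JSON sidecar
named ``<stem>.json`` may carry ``tracer_label`` and ``apex_first``.
Polar maps and cohort tables are plain CSV; score reports and fitted
models are JSON. Every tabular writer prepends ``#``-comment header
lines with the tool version, a config hash and the seed, so runs are
reproducible from the outputs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import DEFAULT_N_RINGS, DEFAULT_N_SECTORS, PolarMap, ShortAxisVolume, Tracer
from .scoring import (
    ABNORMAL_CUTOFF,
    N_SEGMENTS,
    NormalDatabase,
    SegmentScores,
    SummedScores,
    ThresholdTable,
    classify_abnormal,
    uniform_normal_db,
)

__version__ = "0.1.0"

__all__ = [
    "RunConfig",
    "load_config",
    "load_volume",
    "save_volume",
    "polar_map_to_csv",
    "polar_map_from_csv",
    "render_bullseye",
    "score_report",
    "write_score_report",
    "read_score_report",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_normal_db",
    "read_normal_db",
]


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """End-to-end run settings: polar geometry, scoring and prognosis options."""

    n_rings: int = DEFAULT_N_RINGS
    n_sectors: int = DEFAULT_N_SECTORS
    thresholds: ThresholdTable = dataclasses.field(default_factory=ThresholdTable)
    normaldb_path: str | None = None
    cutoff: int = ABNORMAL_CUTOFF
    event_class: str = "ALL"
    soft_event_policy: str = "CENSOR_AT_SOFT"
    seed: int = 0
    outdir: str = "."

    def __post_init__(self) -> None:
        if self.cutoff < 1:
            raise ValueError("cutoff must be >= 1")
        if self.n_sectors % 6 != 0 or self.n_sectors % 4 != 0 or self.n_rings < 4:
            raise ValueError("polar geometry incompatible with the 17-segment mask")

    def hash(self) -> str:
        payload = json.dumps(
            {**dataclasses.asdict(self), "thresholds": self.thresholds.boundaries},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a TOML or JSON file."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text())
    else:
        data = json.loads(path.read_text())
    if "thresholds" in data:
        data["thresholds"] = ThresholdTable(tuple(data["thresholds"]))
    return RunConfig(**data)


def _provenance_lines(config: RunConfig | None, seed: int | None) -> list[str]:
    cfg = config if config is not None else RunConfig()
    return [
        f"# spectscore {__version__}",
        f"# config_hash {cfg.hash()}",
        f"# seed {seed if seed is not None else cfg.seed}",
    ]


def load_volume(path: str | Path, tracer: Tracer | None = None) -> ShortAxisVolume:
    """Read a short-axis volume from NIfTI or .npz (with optional JSON sidecar)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    sidecar: dict = {}
    stem = path.name.removesuffix(".gz").rsplit(".", 1)[0]
    sidecar_path = path.with_name(stem + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())

    if path.suffix == ".npz":
        data = np.load(path)
        counts = data["counts"]
        voxel = tuple(float(v) for v in data["voxel_size_mm"])
    elif path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        arr = np.asarray(img.dataobj, dtype=float)
        # NIfTI stores (x, y, z); short-axis slices are along the last axis
        counts = np.transpose(arr, (2, 0, 1))
        zooms = img.header.get_zooms()[:3]
        voxel = (float(zooms[2]), float(zooms[0]), float(zooms[1]))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")

    label = sidecar.get("tracer_label")
    if tracer is None:
        tracer = Tracer(label) if label else Tracer.TL_STRESS
    return ShortAxisVolume(
        counts=counts,
        voxel_size_mm=voxel,
        apex_first=bool(sidecar.get("apex_first", True)),
        tracer=tracer,
    )


def save_volume(volume: ShortAxisVolume, path: str | Path) -> None:
    """Write a volume to .npz or NIfTI plus a JSON sidecar."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, counts=volume.counts, voxel_size_mm=np.array(volume.voxel_size_mm))
        stem = path.stem
    elif path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vz, vr, vc = volume.voxel_size_mm
        affine = np.diag([vr, vc, vz, 1.0])
        img = nib.Nifti1Image(np.transpose(volume.counts, (1, 2, 0)), affine)
        img.header.set_zooms((vr, vc, vz))
        nib.save(img, str(path))
        stem = path.name.removesuffix(".gz").rsplit(".", 1)[0]
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    sidecar = {"tracer_label": volume.tracer.value, "apex_first": volume.apex_first}
    path.with_name(stem + ".json").write_text(json.dumps(sidecar, indent=2))


def polar_map_to_csv(
    pm: PolarMap, path: str | Path, config: RunConfig | None = None, seed: int | None = None
) -> None:
    """Write a polar map as CSV rows (ring, sector, uptake_pct), one decimal %."""
    rings, sectors = np.meshgrid(np.arange(pm.n_rings), np.arange(pm.n_sectors), indexing="ij")
    df = pd.DataFrame(
        {"ring": rings.ravel(), "sector": sectors.ravel(), "uptake_pct": pm.uptake.ravel()}
    )
    lines = _provenance_lines(config, seed)
    lines.append(f"# normalized {pm.normalized} normalization_max {pm.normalization_max}")
    Path(path).write_text("\n".join(lines) + "\n" + df.to_csv(index=False, float_format="%.4f"))


def polar_map_from_csv(path: str | Path) -> PolarMap:
    header = [l for l in Path(path).read_text().splitlines() if l.startswith("#")]
    meta = {}
    for line in header:
        if "normalized" in line:
            parts = line.lstrip("# ").split()
            meta["normalized"] = parts[1] == "True"
            meta["normalization_max"] = None if parts[3] == "None" else float(parts[3])
    df = pd.read_csv(path, comment="#")
    n_rings = int(df["ring"].max()) + 1
    n_sectors = int(df["sector"].max()) + 1
    uptake = np.zeros((n_rings, n_sectors))
    uptake[df["ring"], df["sector"]] = df["uptake_pct"]
    return PolarMap(
        uptake=uptake, n_rings=n_rings, n_sectors=n_sectors,
        normalized=meta.get("normalized", False),
        normalization_max=meta.get("normalization_max"),
    )


def render_bullseye(pm: PolarMap, path: str | Path, title: str = "") -> None:
    """Render a bull's-eye plot (anterior up, septal left) to PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    theta_edges = np.linspace(0, 2 * np.pi, pm.n_sectors + 1) - np.pi / pm.n_sectors
    r_edges = np.arange(pm.n_rings + 1)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    # display: anterior (angle 0) at top, septal at left => counterclockwise from N
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(1)
    mesh = ax.pcolormesh(theta_edges, r_edges, pm.uptake, cmap="turbo", vmin=0, vmax=100)
    ax.set_yticks([])
    ax.set_xticks([])
    if title:
        ax.set_title(title)
    fig.colorbar(mesh, ax=ax, label="% uptake")
    fig.savefig(path, dpi=100)
    plt.close(fig)


def score_report(
    patient_id: str,
    per_tracer: dict[Tracer, SegmentScores],
    summed: SummedScores,
    cutoff: int = ABNORMAL_CUTOFF,
) -> dict:
    """Assemble the JSON-ready score report for one patient."""
    report: dict = {"patient_id": patient_id, "cutoff": cutoff, "tracers": {}}
    for tracer, seg in per_tracer.items():
        report["tracers"][tracer.value] = {
            "segment_scores": list(seg.scores),
            "segment_mean_uptake": [round(u, 4) for u in seg.segment_mean_uptake],
        }
    report["summed"] = {
        k.upper(): getattr(summed, k) for k in ("sss", "srs", "sds", "sbs")
    }
    report["abnormal"] = {
        k.upper(): (None if getattr(summed, k) is None else classify_abnormal(getattr(summed, k), cutoff))
        for k in ("sss", "srs", "sds", "sbs")
    }
    return report


def write_score_report(
    report: dict, path: str | Path, config: RunConfig | None = None, seed: int | None = None
) -> None:
    cfg = config if config is not None else RunConfig()
    out = {
        "tool": f"spectscore {__version__}",
        "config_hash": cfg.hash(),
        "seed": seed if seed is not None else cfg.seed,
        **report,
    }
    Path(path).write_text(json.dumps(out, indent=2) + "\n")


def read_score_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def score_report_csv_row(report: dict) -> pd.DataFrame:
    """Flatten a score report into a single CSV row."""
    row: dict = {"patient_id": report["patient_id"]}
    for key, val in report["summed"].items():
        row[key.lower()] = val
    for key, val in report["abnormal"].items():
        row[f"{key.lower()}_abnormal"] = val
    for tracer, block in report["tracers"].items():
        for i, s in enumerate(block["segment_scores"], start=1):
            row[f"{tracer.lower()}_seg{i:02d}"] = s
    return pd.DataFrame([row])


def write_cohort_csv(
    df: pd.DataFrame, path: str | Path, config: RunConfig | None = None, seed: int | None = None
) -> None:
    lines = _provenance_lines(config, seed)
    Path(path).write_text("\n".join(lines) + "\n" + df.to_csv(index=False))


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    from .prognosis import validate_cohort

    df = pd.read_csv(path, comment="#")
    return validate_cohort(df)


def write_normal_db(db: NormalDatabase, path: str | Path) -> None:
    payload = {
        tracer.value: {
            "mean": [round(float(x), 6) for x in db.means[tracer]],
            "sd": [round(float(x), 6) for x in db.sds[tracer]],
        }
        for tracer in db.means
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_normal_db(path: str | Path) -> NormalDatabase:
    data = json.loads(Path(path).read_text())
    means = {Tracer(k): np.array(v["mean"], dtype=float) for k, v in data.items()}
    sds = {Tracer(k): np.array(v["sd"], dtype=float) for k, v in data.items()}
    return NormalDatabase(means=means, sds=sds)


def resolve_normal_db(config: RunConfig) -> NormalDatabase:
    if config.normaldb_path:
        return read_normal_db(config.normaldb_path)
    return uniform_normal_db()
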