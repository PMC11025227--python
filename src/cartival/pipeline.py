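"""Per-case and cohort orchestration of the two validation tracks.

Track A (2D, "simulated photography"): extract the model surface, rectify its
pose by PCA, render a calibrated top-down silhouette, align it with the
specimen photograph (and with the gold-standard model's own render) and score
2D DSC.  Track B (3D): initialise a rigid transform from six ordered
landmarks, refine it with trimmed ICP on surface point clouds, then score 3D
DSC on the gold-standard grid and report per-case volumes.  Cohorts aggregate
per-case reports into means and the Pearson correlation of paired volumes.

Everything stochastic is seeded from the config; identical config and inputs
produce bit-identical CSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import io as cio
from .core.geometry import mask_to_mesh
from .core.types import BinarySilhouette, LabelVolume, LandmarkSet, RigidTransform
from .metrics import cartilage_volume, dsc_2d, dsc_3d, pearson_r
from .projection import CameraSpec, align_silhouettes, pca_rectify, render_silhouette
from .registration import ICPConfig, icp_refine, landmark_align, surface_cloud
from .synthetic import SyntheticCase

__all__ = ["PipelineConfig", "CaseInputs", "CaseReport", "CohortReport",
           "PipelineStageError", "run_case", "run_cohort", "write_cohort",
           "load_case_bundle"]


class PipelineStageError(RuntimeError):
    """An error attributed to a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass(frozen=True)
class PipelineConfig:
    """Single source of all pipeline tolerances and modes."""

    camera: CameraSpec = field(default_factory=CameraSpec)
    icp: ICPConfig = field(default_factory=ICPConfig)
    seed: int = 0
    label: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["camera"].get("canvas_extent_mm") is not None:
            d["camera"]["canvas_extent_mm"] = list(d["camera"]["canvas_extent_mm"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        cam = d.get("camera", {})
        if cam.get("canvas_extent_mm") is not None:
            cam = dict(cam, canvas_extent_mm=tuple(cam["canvas_extent_mm"]))
        return PipelineConfig(camera=CameraSpec(**cam),
                              icp=ICPConfig(**d.get("icp", {})),
                              seed=int(d.get("seed", 0)),
                              label=int(d.get("label", 1)))

    @staticmethod
    def from_file(path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return PipelineConfig.from_dict(data)


@dataclass(frozen=True)
class CaseInputs:
    """One case's input bundle; missing modalities yield a partial report."""

    case_id: str
    mri_volume: LabelVolume
    ct_volume: LabelVolume | None = None
    photo: BinarySilhouette | None = None
    landmarks_mri: LandmarkSet | None = None
    landmarks_ct: LandmarkSet | None = None
    truth: RigidTransform | None = None   # carried through for validation studies

    @staticmethod
    def from_synthetic(case: SyntheticCase, case_id: str = "case") -> "CaseInputs":
        return CaseInputs(case_id=case_id,
                          mri_volume=case.mri_volume,
                          ct_volume=case.ct_volume,
                          photo=case.photo,
                          landmarks_mri=case.landmarks_mri,
                          landmarks_ct=case.landmarks_ct,
                          truth=case.truth)


@dataclass(frozen=True)
class CaseReport:
    case_id: str
    dsc2d_model_vs_photo: float | None
    dsc2d_model_vs_ctmodel: float | None
    dsc3d: float | None
    volume_mri_mm3: float | None
    volume_ct_mm3: float | None
    registration_residual_mm: float | None
    alignment_choices: dict

    def __post_init__(self):
        for name in ("dsc2d_model_vs_photo", "dsc2d_model_vs_ctmodel", "dsc3d"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} out of [0, 1]: {v}")
        for name in ("volume_mri_mm3", "volume_ct_mm3"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} negative: {v}")

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "dsc2d_model_vs_photo": self.dsc2d_model_vs_photo,
            "dsc2d_model_vs_ctmodel": self.dsc2d_model_vs_ctmodel,
            "dsc3d": self.dsc3d,
            "volume_mri_mm3": self.volume_mri_mm3,
            "volume_ct_mm3": self.volume_ct_mm3,
            "registration_residual_mm": self.registration_residual_mm,
            "alignment_choices": self.alignment_choices,
        }


@dataclass(frozen=True)
class CohortReport:
    per_case: tuple[CaseReport, ...]
    mean_dsc2d_photo: float | None
    mean_dsc2d_ct: float | None
    mean_dsc3d: float | None
    pearson_r_volumes: float | None
    pearson_p: float | None
    config_hash: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "mean_dsc2d_photo": self.mean_dsc2d_photo,
            "mean_dsc2d_ct": self.mean_dsc2d_ct,
            "mean_dsc3d": self.mean_dsc3d,
            "pearson_r_volumes": self.pearson_r_volumes,
            "pearson_p": self.pearson_p,
            "per_case": [c.to_dict() for c in self.per_case],
        }


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, exc) from exc
            return False
    return _Ctx()


def run_case(inputs: CaseInputs, config: PipelineConfig | None = None) -> CaseReport:
    """Execute both validation tracks on one case.

    Track A requires the MRI volume plus a photo and/or a CT model; Track B
    requires the CT volume and both landmark sets.  Missing modalities leave
    the corresponding report fields ``None``.
    """
    config = config or PipelineConfig()
    choices: dict = {"config_hash": config.config_hash(), "seed": config.seed}

    with _stage("model-surface"):
        mesh_mri = mask_to_mesh(inputs.mri_volume, config.label)
        rect_mri, _ = pca_rectify(mesh_mri)

    with _stage("render"):
        sil_model = render_silhouette(rect_mri, config.camera)

    dsc2d_photo = None
    if inputs.photo is not None:
        with _stage("silhouette-vs-photo"):
            pair = align_silhouettes(sil_model, inputs.photo)
            dsc2d_photo = dsc_2d(pair.a, pair.b).dsc
            choices["photo_alignment"] = {"rotation_deg": pair.rotation_deg,
                                          "candidate_index": pair.candidate_index,
                                          "mode": pair.mode}

    dsc2d_ct = None
    vol_ct = None
    if inputs.ct_volume is not None:
        with _stage("gold-surface"):
            mesh_ct = mask_to_mesh(inputs.ct_volume, config.label)
            rect_ct, _ = pca_rectify(mesh_ct)
        with _stage("silhouette-vs-gold-render"):
            sil_ct = render_silhouette(rect_ct, config.camera)
            pair = align_silhouettes(sil_model, sil_ct)
            dsc2d_ct = dsc_2d(pair.a, pair.b).dsc
            choices["ct_render_alignment"] = {"rotation_deg": pair.rotation_deg,
                                              "candidate_index": pair.candidate_index,
                                              "mode": pair.mode}
        vol_ct = cartilage_volume(inputs.ct_volume, config.label)

    dsc3 = None
    resid = None
    if inputs.ct_volume is not None and inputs.landmarks_mri is not None \
            and inputs.landmarks_ct is not None:
        with _stage("registration"):
            init = landmark_align(inputs.landmarks_mri, inputs.landmarks_ct)
            src = surface_cloud(inputs.mri_volume, config.icp.sample_points,
                                seed=config.seed, label=config.label)
            dst = surface_cloud(inputs.ct_volume, config.icp.sample_points,
                                seed=config.seed + 1, label=config.label)
            icp = icp_refine(src, dst, init.transform, config.icp)
            resid = icp.diagnostics.final_rms_distance_mm
            choices["registration"] = {
                "landmark_rmsd_mm": init.rmsd_mm,
                "icp_termination": icp.diagnostics.termination,
                "icp_iterations": icp.diagnostics.n_iterations,
            }
        with _stage("dsc3d"):
            dsc3 = dsc_3d(inputs.mri_volume, inputs.ct_volume, icp.transform,
                          config.label).dsc

    vol_mri = cartilage_volume(inputs.mri_volume, config.label)
    return CaseReport(case_id=inputs.case_id,
                      dsc2d_model_vs_photo=dsc2d_photo,
                      dsc2d_model_vs_ctmodel=dsc2d_ct,
                      dsc3d=dsc3,
                      volume_mri_mm3=vol_mri,
                      volume_ct_mm3=vol_ct,
                      registration_residual_mm=resid,
                      alignment_choices=choices)


def _mean_of(reports, attr):
    vals = [getattr(r, attr) for r in reports if getattr(r, attr) is not None]
    return float(np.mean(vals)) if vals else None


def run_cohort(cases, config: PipelineConfig | None = None) -> CohortReport:
    """Run every case and aggregate (means, volume Pearson correlation).

    ``cases`` is an iterable of :class:`CaseInputs` or
    :class:`~cartival.synthetic.SyntheticCase`.  Fewer than two cases with
    paired volumes leaves the correlation fields ``None`` with a warning;
    degenerate (constant-volume) cohorts are surfaced the same way rather
    than crashing.
    """
    config = config or PipelineConfig()
    inputs = []
    for i, c in enumerate(cases):
        if isinstance(c, SyntheticCase):
            c = CaseInputs.from_synthetic(c, case_id=f"case-{i:03d}")
        inputs.append(c)
    if len(inputs) < 2:
        raise ValueError("a cohort needs at least 2 cases")
    reports = tuple(run_case(ci, config) for ci in inputs)

    vols = [(r.volume_mri_mm3, r.volume_ct_mm3) for r in reports
            if r.volume_mri_mm3 is not None and r.volume_ct_mm3 is not None]
    r_val = p_val = None
    if len(vols) < 2:
        import warnings
        warnings.warn("fewer than 2 cases with paired volumes; "
                      "correlation omitted", stacklevel=2)
    else:
        try:
            r_val, p_val = pearson_r([v[0] for v in vols], [v[1] for v in vols])
        except ValueError as e:
            import warnings
            warnings.warn(f"volume correlation undefined: {e}", stacklevel=2)
    return CohortReport(per_case=reports,
                        mean_dsc2d_photo=_mean_of(reports, "dsc2d_model_vs_photo"),
                        mean_dsc2d_ct=_mean_of(reports, "dsc2d_model_vs_ctmodel"),
                        mean_dsc3d=_mean_of(reports, "dsc3d"),
                        pearson_r_volumes=r_val,
                        pearson_p=p_val,
                        config_hash=config.config_hash(),
                        seed=config.seed)


def write_cohort(report: CohortReport, outdir, plots: bool = False) -> dict:
    """Write ``cohort.csv``, ``cohort.json`` and optional PNG plots.

    Returns the paths written.  Output bytes depend only on the report, so
    identical runs give bit-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [r.to_dict() for r in report.per_case]
    for row in rows:
        row["alignment_choices"] = json.dumps(row["alignment_choices"], sort_keys=True)
    df = pd.DataFrame(rows)
    csv_path = outdir / "cohort.csv"
    df.to_csv(csv_path, index=False)
    json_path = outdir / "cohort.json"
    json_path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    paths = {"csv": csv_path, "json": json_path}
    if plots:
        paths.update(_plot_cohort(report, outdir))
    return paths


def _plot_cohort(report: CohortReport, outdir: Path) -> dict:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ids = [r.case_id for r in report.per_case]
    fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(ids)), 4))
    width = 0.27
    xs = np.arange(len(ids))
    for off, attr, label in ((-width, "dsc2d_model_vs_photo", "2D vs photo"),
                             (0.0, "dsc2d_model_vs_ctmodel", "2D vs CT render"),
                             (width, "dsc3d", "3D")):
        vals = [getattr(r, attr) or 0.0 for r in report.per_case]
        ax.bar(xs + off, vals, width=width, label=label)
    ax.set_xticks(xs, ids, rotation=45, ha="right")
    ax.set_ylabel("DSC")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    bars = outdir / "dsc_per_case.png"
    fig.savefig(bars, dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    xv = [r.volume_ct_mm3 for r in report.per_case if r.volume_ct_mm3 is not None]
    yv = [r.volume_mri_mm3 for r in report.per_case if r.volume_ct_mm3 is not None]
    ax.scatter(xv, yv)
    lim = [0, max(xv + yv) * 1.05] if xv else [0, 1]
    ax.plot(lim, lim, "k--", lw=0.8)
    ax.set_xlabel("gold-standard volume (mm$^3$)")
    ax.set_ylabel("model volume (mm$^3$)")
    if report.pearson_r_volumes is not None:
        ax.set_title(f"r = {report.pearson_r_volumes:.3f}")
    fig.tight_layout()
    scatter = outdir / "volume_scatter.png"
    fig.savefig(scatter, dpi=120)
    plt.close(fig)
    return {"dsc_plot": bars, "volume_plot": scatter}


# -- case bundles on disk -------------------------------------------------

def load_case_bundle(case_dir) -> CaseInputs:
    """Read one case directory written by ``cartival simulate`` (or hand-made).

    Expected members: ``mri.nii.gz`` (required), ``ct.nii.gz``, ``photo.png``
    (+ sidecar), ``landmarks_mri.csv``, ``landmarks_ct.csv``, ``truth.json``;
    all but the MRI volume are optional.
    """
    case_dir = Path(case_dir)
    mri_path = case_dir / "mri.nii.gz"
    if not mri_path.exists():
        raise FileNotFoundError(f"{case_dir}: missing required mri.nii.gz")
    mri = cio.read_label_volume(mri_path, frame_id="MRI")

    def opt(name, reader, **kw):
        p = case_dir / name
        return reader(p, **kw) if p.exists() else None

    return CaseInputs(
        case_id=case_dir.name,
        mri_volume=mri,
        ct_volume=opt("ct.nii.gz", cio.read_label_volume, frame_id="CT"),
        photo=opt("photo.png", cio.read_silhouette),
        landmarks_mri=opt("landmarks_mri.csv", cio.read_landmarks, frame_id="MRI"),
        landmarks_ct=opt("landmarks_ct.csv", cio.read_landmarks, frame_id="CT"),
        truth=opt("truth.json", cio.read_transform),
    )


def write_case_bundle(case: SyntheticCase, case_dir) -> None:
    """Serialise a synthetic case as a standard on-disk bundle."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    cio.write_label_volume(case.mri_volume, case_dir / "mri.nii.gz")
    cio.write_label_volume(case.ct_volume, case_dir / "ct.nii.gz")
    cio.write_silhouette(case.photo, case_dir / "photo.png")
    cio.write_landmarks(case.landmarks_mri, case_dir / "landmarks_mri.csv")
    cio.write_landmarks(case.landmarks_ct, case_dir / "landmarks_ct.csv")
    cio.write_transform(case.truth, case_dir / "truth.json")
    (case_dir / "params.json").write_text(
        json.dumps(case.params.to_dict(), indent=2) + "\n")
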