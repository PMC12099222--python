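"""Session assembly, on-disk formats, and the end-to-end QC pipeline.

A QC session on disk is a directory of NIfTI-1 volumes with a JSON sidecar
(``session.json``) naming each scan's role.  The five required roles are
the axial T2w pair, sagittal and coronal T2w, and the short-TE thermometer
scan; IR/MESE mapping series are optional extras.  DICOM directories can be
ingested read-only (pixel data, spacing, orientation, and the imaging
center frequency from the header).

``run_qc`` executes the full per-session analysis — template registration,
label transfer, fiducial detection on all three planes, PSNR on the axial
pair, mid-slice contrast, per-plane distortion summaries, and the
thermometer reading — recording per-stage failures in the report instead of
aborting the session.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import geometry as geo
from . import metrics, segment, simulate
from .volume import LabelVolume, ScanVolume

log = logging.getLogger("phantomqc")

REQUIRED_ROLES = simulate.QC_ROLES

#: Default WM/GM mimic assignment for the contrast metric: the MnCl2 mimics
#: whose T2 bracket neonatal white matter and deep gray matter.
WM_MIMIC = "MnCl2-4"
GM_MIMIC = "MnCl2-8"


@dataclass
class QCConfig:
    """Analysis thresholds; defaults follow the published procedure."""

    outlier_mm: float = metrics.OUTLIER_DISTORTION_MM
    psnr_normalization: str = "global"  # or "masked"
    thermometer_dark_fraction: float = 0.5
    wm_mimic: str = WM_MIMIC
    gm_mimic: str = GM_MIMIC

    @classmethod
    def load(cls, path) -> "QCConfig":
        with open(path) as fh:
            if str(path).endswith((".yaml", ".yml")):
                import yaml

                data = yaml.safe_load(fh)
            else:
                data = json.load(fh)
        return cls(**data)


@dataclass
class SessionBundle:
    """All scans of one session keyed by role, plus session metadata."""

    scans: dict[str, ScanVolume]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [r for r in REQUIRED_ROLES if r not in self.scans]
        if missing:
            raise ValueError(f"session missing required scan roles: {', '.join(missing)}")
        a, b = self.scans["axial_t2w"], self.scans["axial_t2w_repeat"]
        if a.shape != b.shape or not np.allclose(a.affine, b.affine, atol=1e-6):
            raise ValueError("repeated axial pair must share one grid")


def load_session(path: str | Path) -> SessionBundle:
    """Load a session directory (NIfTI volumes + ``session.json`` sidecar)."""
    path = Path(path)
    sidecar_path = path / "session.json"
    meta: dict = {}
    roles: list[str] | None = None
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        roles = meta.get("roles")
    scans: dict[str, ScanVolume] = {}
    for nii in sorted(path.glob("*.nii.gz")) + sorted(path.glob("*.nii")):
        role = nii.name.removesuffix(".nii.gz").removesuffix(".nii")
        if roles is None or role in roles:
            scans[role] = ScanVolume.load(nii)
    return SessionBundle(scans=scans, meta=meta)


def read_dicom_series(directory: str | Path, scan_plane: str = "axial") -> ScanVolume:
    """Read a single DICOM series (read-only ingestion).

    Extracts pixel data, spacing, orientation/position, and the Larmor
    center frequency from the ImagingFrequency header field (a sidecar value
    in the session metadata overrides it).
    """
    import pydicom

    files = sorted(Path(directory).glob("*.dcm")) or sorted(Path(directory).iterdir())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM images found in {directory}")
    slices.sort(key=lambda d: float(getattr(d, "ImagePositionPatient", [0, 0, 0])[2]))
    first = slices[0]
    data = np.stack([d.pixel_array.T for d in slices], axis=-1).astype(np.float32)
    dy, dx = (float(v) for v in first.PixelSpacing)
    dz = float(getattr(first, "SpacingBetweenSlices", getattr(first, "SliceThickness", 1.0)))
    affine = np.eye(4)
    affine[:3, :3] = np.diag([dx, dy, dz])
    affine[:3, 3] = [float(v) for v in getattr(first, "ImagePositionPatient", (0, 0, 0))]
    meta = {}
    freq = getattr(first, "ImagingFrequency", None)
    if freq is not None:
        meta["larmor_freq_mhz"] = float(freq)
    return ScanVolume(data, affine, scan_plane, meta)


def _stage(report: dict, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                report["stages"][name] = {"status": "ok", "seconds": round(dt, 3)}
                log.info("stage %s ok (%.2fs)", name, dt)
                return False
            report["stages"][name] = {"status": "error", "seconds": round(dt, 3), "error": str(exc)}
            log.warning("stage %s failed: %s", name, exc)
            return True  # metric unavailable; session continues

    return _Ctx()


def run_qc(
    bundle: SessionBundle,
    template: ScanVolume | None = None,
    template_labels: LabelVolume | None = None,
    geometry: geo.PhantomGeometry | None = None,
    config: QCConfig | None = None,
) -> dict:
    """Run the full QC analysis for one session and return the report.

    Stage failures mark the affected metrics unavailable (``None``) without
    aborting the remaining stages.  The report is deterministic for fixed
    inputs (timings excluded from any comparison).
    """
    geometry = geometry or geo.PhantomGeometry()
    config = config or QCConfig()
    if template is None or template_labels is None:
        template, template_labels = simulate.make_template(geometry)

    report: dict = {
        "site": bundle.meta.get("site"),
        "software_tag": bundle.meta.get("software_tag"),
        "larmor_freq_mhz": bundle.meta.get(
            "larmor_freq_mhz", bundle.scans["axial_t2w"].meta.get("larmor_freq_mhz")
        ),
        "stages": {},
        "psnr_db": None, "mod_psnr": None, "con": None,
        "temperature_c": None, "capped": None,
        "distortion": {},
    }

    axial = bundle.scans["axial_t2w"]
    transform = labels = None
    with _stage(report, "register_template"):
        transform = segment.register_template(template, axial)
        report["registration_ncc"] = transform.objective
        report["registration_low_confidence"] = transform.low_confidence
    if transform is not None:
        with _stage(report, "transfer_labels"):
            labels = segment.transfer_labels(transform, template_labels, axial)

    if labels is not None:
        with _stage(report, "psnr"):
            res = metrics.psnr(
                axial, bundle.scans["axial_t2w_repeat"], labels.mask(),
                normalization=config.psnr_normalization,
            )
            report["psnr_db"] = res.psnr
            report["mod_psnr"] = res.mod_psnr

        with _stage(report, "contrast"):
            array_ids = [f"MnCl2-{k}" for k in range(1, geo.N_MIMICS_PER_ARRAY + 1)]
            res = metrics.contrast(
                axial, labels, config.wm_mimic, config.gm_mimic, array_ids, transform
            )
            report["con"] = res.con
            report["contrast_detail"] = asdict(res)

    design = geometry.fiducials()
    for plane, role in (("axial", "axial_t2w"), ("sagittal", "sagittal_t2w"), ("coronal", "coronal_t2w")):
        with _stage(report, f"distortion_{plane}"):
            detected = segment.detect_fiducials(bundle.scans[role], design)
            records, _ = metrics.compute_distortions(detected, design, plane, outlier_mm=config.outlier_mm)
            report["distortion"][plane] = metrics.summarize_distortions(records, plane)

    with _stage(report, "thermometer"):
        thermo_vol = bundle.scans["thermometer"]
        # register against a template rendered with the short-TE weighting so
        # the NCC metric compares matching contrasts
        thermo_template, thermo_tpl_labels = simulate.make_template(
            geometry, contrast_like=simulate.thermometer_sequence()
        )
        ttrans = segment.register_template(thermo_template, thermo_vol)
        tlabels = segment.transfer_labels(ttrans, thermo_tpl_labels, thermo_vol)
        reading = metrics.read_thermometer(
            thermo_vol, tlabels, geometry.thermometer, dark_fraction=config.thermometer_dark_fraction
        )
        report["temperature_c"] = reading.temperature
        report["capped"] = reading.capped
        report["n_dark"] = reading.n_dark

    return report


def report_row(report: dict, date: str | None = None) -> dict:
    """Flatten a session report into one long-format record row."""

    def group_mean(plane_summaries: dict, g: float):
        means = [
            s["groups"][g]["mean"]
            for s in plane_summaries.values()
            if s and s["groups"].get(g)
        ]
        return float(np.mean(means)) if means else None

    d = report.get("distortion", {})
    return {
        "site": report.get("site"),
        "date": date or report.get("date"),
        "software_tag": report.get("software_tag"),
        "psnr_db": report.get("psnr_db"),
        "mod_psnr": report.get("mod_psnr"),
        "con": report.get("con"),
        "temperature_c": report.get("temperature_c"),
        "capped": report.get("capped"),
        "larmor_mhz": report.get("larmor_freq_mhz"),
        "dist_r0_mm": group_mean(d, 0.0),
        "dist_r50_mm": group_mean(d, 50.0),
        "dist_r70_mm": group_mean(d, 70.7),
    }
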