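"""Session-level QC metrics: PSNR, contrast, geometric distortion, temperature.

* **PSNR** between the two repeated axial scans, each normalized to a
  maximum of 1, with the mean squared error taken over the phantom mask:
  ``PSNR = 10 log10(1 / MSE)``; for near-normal statistics downstream the
  transform ``modPSNR = 10^(PSNR/10)`` is also carried.
* **Contrast** ``Con = (S_WM - S_GM) / S_ref`` from mid-slice-cropped mimic
  labels, where S_ref is the mean of the per-mimic mean intensities of the
  whole array, cancelling global intensity scale factors.
* **Distortion**: detected fiducial centroids are rigidly aligned onto the
  exact design positions (Kabsch), the per-fiducial residual
  ``delta = reference - aligned`` is the distortion, displacements beyond
  20 mm are excluded as segmentation/registration outliers, and in-plane
  magnitudes are summarized by design radius group {0, 50, 70.7} mm.
* **Temperature** from the LCMRV thermometer: elements past their phase
  transition are dark on the short-TE scan; the count of dark elements maps
  to degrees C, saturating at the 24.5 deg C maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry as geo
from .segment import RigidTransform, mid_slice_crop
from .volume import LabelVolume, ScanVolume

OUTLIER_DISTORTION_MM = 20.0
RADIUS_GROUPS_MM = (0.0, 50.0, 70.7)


# ---------------------------------------------------------------------------
# PSNR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PsnrResult:
    psnr: float  # dB
    mod_psnr: float  # 10^(PSNR/10)
    n_voxels: int


def psnr(
    img_a: ScanVolume, img_b: ScanVolume, mask: np.ndarray | LabelVolume,
    normalization: str = "global",
) -> PsnrResult:
    """Peak SNR between two repeated scans over a mask.

    Each image is divided by its own maximum intensity (``normalization``:
    "global" uses the whole volume's maximum, "masked" the maximum within
    the mask), then ``PSNR = 10 log10(1 / MSE)`` over mask voxels.
    """
    if img_a.shape != img_b.shape or not np.allclose(img_a.affine, img_b.affine, atol=1e-6):
        raise ValueError("images must share one grid")
    m = mask.mask() if isinstance(mask, LabelVolume) else np.asarray(mask, dtype=bool)
    if m.shape != img_a.shape:
        raise ValueError("mask grid mismatch")
    if not m.any():
        raise ValueError("mask is empty")
    if normalization not in ("global", "masked"):
        raise ValueError("normalization must be 'global' or 'masked'")
    a = np.asarray(img_a.data, dtype=np.float64)
    b = np.asarray(img_b.data, dtype=np.float64)
    a = a / (a[m].max() if normalization == "masked" else a.max())
    b = b / (b[m].max() if normalization == "masked" else b.max())
    mse = float(np.mean((a[m] - b[m]) ** 2))
    if mse == 0.0:
        raise ValueError("identical inputs: PSNR is infinite")
    value = 10.0 * np.log10(1.0 / mse)
    return PsnrResult(psnr=float(value), mod_psnr=float(10.0 ** (value / 10.0)), n_voxels=int(m.sum()))


# ---------------------------------------------------------------------------
# Contrast
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContrastResult:
    s_wm: float
    s_gm: float
    s_ref: float
    con: float


def contrast(
    volume: ScanVolume,
    labels: LabelVolume,
    wm_mimic: str,
    gm_mimic: str,
    array_mimics: list[str],
    transform: RigidTransform,
    mimic_centers: dict[str, np.ndarray] | None = None,
) -> ContrastResult:
    """Simulated WM/GM contrast from mimic intensities.

    Each mimic's label is cropped to the single slice holding its (warped)
    design center before averaging, so the thick-slice partial volume at the
    sphere poles does not dilute the mean.  ``mimic_centers`` maps feature
    id to design-space center; by default the frozen design template is used.
    """
    if mimic_centers is None:
        mimic_centers = {m.feature_id: np.asarray(m.center) for m in geo.PhantomGeometry().all_mimics()}
    means: dict[str, float] = {}
    for fid in array_mimics:
        cropped = mid_slice_crop(labels, mimic_centers[fid], transform)
        sel = cropped.feature_mask(fid)
        if not sel.any():
            raise ValueError(f"empty mimic label after mid-slice crop: {fid}")
        means[fid] = float(volume.data[sel].mean())
    s_wm = means[wm_mimic]
    s_gm = means[gm_mimic]
    s_ref = float(np.mean(list(means.values())))
    if s_ref <= 0:
        raise ValueError("non-positive reference intensity")
    return ContrastResult(s_wm=s_wm, s_gm=s_gm, s_ref=s_ref, con=(s_wm - s_gm) / s_ref)


# ---------------------------------------------------------------------------
# Geometric distortion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistortionRecord:
    fiducial_id: int
    delta: tuple[float, float, float]  # reference - aligned acquired, mm
    inplane_mag: float
    radius_group: float
    excluded: bool


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid alignment ``R P + t ~ Q`` (Kabsch algorithm).

    Centroids are removed, the rotation comes from the SVD of the cross
    covariance with a determinant correction to exclude reflections, and the
    translation re-centers the rotated source on the target centroid.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 point pairs")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, s, Vt = np.linalg.svd(H)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return R, t


def compute_distortions(
    detected: list[tuple[int, np.ndarray]],
    design: list[geo.Fiducial],
    scan_plane: str,
    outlier_mm: float = OUTLIER_DISTORTION_MM,
) -> tuple[list[DistortionRecord], RigidTransform]:
    """Per-fiducial distortion after rigid alignment to design space.

    The detected centroids are aligned onto the design positions with the
    Kabsch algorithm (absorbing phantom misplacement); each matched fiducial
    then contributes ``delta = design - aligned``.  Records with 3D
    ``|delta|`` beyond ``outlier_mm`` are marked excluded.  The radius group
    is the nearest of {0, 50, 70.7} mm from the *design* position's in-plane
    radius, so grouping is stable under distortion.
    """
    if len(detected) < 4:
        raise ValueError("need at least 4 matched fiducials")
    by_id = {f.id: np.asarray(f.design_position, dtype=float) for f in design}
    ids = [i for i, _ in detected]
    if any(i not in by_id for i in ids):
        raise ValueError("detected fiducial id not in design list")
    P = np.array([c for _, c in detected], dtype=float)
    Q = np.array([by_id[i] for i in ids])
    R, t = kabsch(P, Q)
    aligned = P @ R.T + t
    ax = geo.inplane_axes(scan_plane)

    records = []
    for i, q, a in zip(ids, Q, aligned):
        delta = q - a
        mag3d = float(np.linalg.norm(delta))
        group = RADIUS_GROUPS_MM[int(np.argmin([abs(geo.in_plane_radius(q, scan_plane) - g) for g in RADIUS_GROUPS_MM]))]
        records.append(
            DistortionRecord(
                fiducial_id=int(i),
                delta=tuple(float(v) for v in delta),
                inplane_mag=float(np.hypot(delta[ax[0]], delta[ax[1]])),
                radius_group=group,
                excluded=mag3d > outlier_mm,
            )
        )
    return records, RigidTransform(R, t)


def summarize_distortions(records: list[DistortionRecord], scan_plane: str) -> dict:
    """Mean and range of in-plane distortion magnitude per radius group.

    Excluded records never enter any summary.  Groups with no surviving
    fiducials are reported as absent (None).
    """
    kept = [r for r in records if not r.excluded]
    if not kept:
        raise ValueError("no non-excluded distortion records")
    out: dict = {"scan_plane": scan_plane, "groups": {}, "n_excluded": len(records) - len(kept)}
    for g in RADIUS_GROUPS_MM:
        mags = [r.inplane_mag for r in kept if r.radius_group == g]
        out["groups"][g] = (
            None
            if not mags
            else {"mean": float(np.mean(mags)), "min": float(np.min(mags)), "max": float(np.max(mags)), "n": len(mags)}
        )
    ax = geo.inplane_axes(scan_plane)
    out["per_fiducial"] = [
        {
            "fiducial_id": r.fiducial_id,
            "delta_mm": list(r.delta),
            "inplane_mag_mm": r.inplane_mag,
            "radius_group_mm": r.radius_group,
        }
        for r in kept
    ]
    out["inplane_axes"] = ax
    return out


# ---------------------------------------------------------------------------
# Thermometer
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TemperatureReading:
    n_dark: int
    temperature: float  # deg C
    capped: bool  # at the 24.5 deg C maximum
    capped_low: bool = False  # all elements bright: at/below range minimum


def read_thermometer(
    volume: ScanVolume,
    thermo_labels: LabelVolume,
    spec: geo.ThermometerSpec | None = None,
    dark_fraction: float = 0.5,
) -> TemperatureReading:
    """Read the LCMRV thermometer from a short-TE scan.

    Each element is classified dark/bright by comparing its mean intensity
    to ``dark_fraction`` x the fill-solution mean (a threshold between the
    fill level and zero); the dark count maps through the calibration to
    degrees C.  Readings at the thermometer maximum are capped at 24.5 degC.
    """
    spec = spec or geo.ThermometerSpec()
    n_elements = len(spec.element_transition_temps)
    try:
        fill_mean = float(volume.data[thermo_labels.feature_mask("fill")].mean())
    except KeyError:
        raise ValueError("thermometer labels must include the fill-solution label")
    threshold = dark_fraction * fill_mean
    n_dark = 0
    for k in range(1, n_elements + 1):
        fid = f"thermo-{k}"
        try:
            sel = thermo_labels.feature_mask(fid)
        except KeyError:
            raise ValueError(f"missing thermometer element label: {fid}")
        if not sel.any():
            raise ValueError(f"empty thermometer element label: {fid}")
        if float(volume.data[sel].mean()) < threshold:
            n_dark += 1
    temp = spec.temperature_from_n_dark(n_dark)
    capped = n_dark == n_elements
    if capped:
        temp = spec.max_reportable
    return TemperatureReading(
        n_dark=n_dark, temperature=float(temp), capped=capped, capped_low=n_dark == 0
    )
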