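"""Synthetic phantom scan sessions with known ground truth.

The simulator renders the design-space geometry into scan volumes using the
standard spin-echo signal equations, after displacing every feature by a
session-level rigid misplacement plus a smooth spatial distortion field, and
finally adding seeded Gaussian noise.  Because the applied misplacement,
distortion, noise level, and temperature are all explicit inputs, every QC
metric computed downstream has an exact oracle.

Signal models (times in seconds, outputs in arbitrary units):

* T2-weighted (fast) spin echo:  ``S = PD (1 - exp(-TR/T1)) exp(-TE/T2)``.
  The nominal effective TE is used directly; echo-train magnetization
  transfer and diffusion weighting are not modelled.
* Inversion recovery (phase-corrected, real-valued, signed):
  ``S = M0 (1 - 2 exp(-TI/T1) + exp(-TR/T1))``.
* Multi-echo spin echo: ``S = M0 exp(-TE/T2)``.
* The short-TE FISP thermometer scan reuses the spin-echo weighting; what
  matters for the reading is that liquid-crystal elements past their phase
  transition are rendered signal-free (dark).

Features are rendered with 3x3x3 per-voxel supersampling so rasterized
sphere centroids are unbiased well below the voxel size.  Distortion is
applied by displacing feature centers by the field evaluated at the design
position, which keeps the distortion oracle exact; the smoothness of the
field makes the neglected within-sphere variation negligible at the default
2.5 mm cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence
import json

import numpy as np

from . import geometry as geo
from .volume import LabelVolume, ScanVolume, center_affine

# Larmor-frequency temperature coefficient of the permanent-magnet system,
# MHz per deg C (shared by the simulator and the regression models).
LARMOR_TEMP_SLOPE_MHZ_PER_C = -0.0014
DEFAULT_SITE_BASELINE_MHZ = 2.72
DEFAULT_REF_TEMP_C = 20.0

# Integer label ids: fiducials 1-15, then per-array blocks, thermometer, fill.
FILL_LABEL = 90
_LABEL_BLOCKS = {"NiCl2": 100, "PVP": 200, "MnCl2": 300, "thermo": 400}


# ---------------------------------------------------------------------------
# Signal equations
# ---------------------------------------------------------------------------


def fse_signal(pd: float, t1: float, t2: float, tr: float, te_eff: float):
    """Saturation-recovery x T2-decay weighting of a (fast) spin echo."""
    pd, t1, t2, tr, te_eff = (np.asarray(v, dtype=float) for v in (pd, t1, t2, tr, te_eff))
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise ValueError("relaxation times must be positive")
    if np.any(tr <= 0) or np.any(te_eff < 0):
        raise ValueError("TR must be positive and TE non-negative")
    return pd * (1.0 - np.exp(-tr / t1)) * np.exp(-te_eff / t2)


def ir_signal(m0: float, t1: float, ti: float, tr: float):
    """Signed inversion-recovery signal (phase-corrected real-valued data)."""
    m0, t1, ti, tr = (np.asarray(v, dtype=float) for v in (m0, t1, ti, tr))
    if np.any(t1 <= 0) or np.any(ti <= 0) or np.any(tr <= 0):
        raise ValueError("T1, TI and TR must be positive")
    return m0 * (1.0 - 2.0 * np.exp(-ti / t1) + np.exp(-tr / t1))


def mese_signal(m0: float, t2: float, te: float):
    """Mono-exponential T2 decay of a multi-echo spin-echo train."""
    m0, t2, te = (np.asarray(v, dtype=float) for v in (m0, t2, te))
    if np.any(t2 <= 0) or np.any(te < 0):
        raise ValueError("T2 must be positive and TE non-negative")
    return m0 * np.exp(-te / t2)


def larmor_frequency(
    temperature_c: float,
    site_baseline_mhz: float = DEFAULT_SITE_BASELINE_MHZ,
    ref_temp_c: float = DEFAULT_REF_TEMP_C,
) -> float:
    """Larmor center frequency at a phantom/room temperature.

    Permanent magnets lose field with temperature; the linear model uses a
    shared slope with a site-specific baseline frequency at ``ref_temp_c``.
    """
    return site_baseline_mhz + LARMOR_TEMP_SLOPE_MHZ_PER_C * (temperature_c - ref_temp_c)


# ---------------------------------------------------------------------------
# Sequence and ground-truth descriptions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceParams:
    """Acquisition parameters of one scan (times in ms, sizes in mm/voxels)."""

    kind: str  # T2w-FSE | IR-TSE | MESE | FISP-thermometer
    tr_ms: float
    te_ms: float | tuple[float, ...] = 0.0
    ti_ms: tuple[float, ...] = ()
    scan_plane: str = "axial"
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 5.0)
    matrix: tuple[int, int, int] = (120, 120, 36)

    def __post_init__(self):
        if self.tr_ms <= 0:
            raise ValueError("TR must be positive")
        if self.kind == "IR-TSE" and not self.ti_ms:
            raise ValueError("IR sequence requires a TI list")
        if self.kind == "MESE":
            tes = np.atleast_1d(self.te_ms)
            if np.any(np.diff(tes) <= 0):
                raise ValueError("MESE echo list must be strictly increasing")
        if self.scan_plane not in geo.SCAN_PLANES:
            raise ValueError(f"unknown scan plane: {self.scan_plane!r}")


def t2w_sequence(scan_plane: str = "axial") -> SequenceParams:
    """Default anisotropic T2w FSE protocol (fine in-plane, 5 mm slices)."""
    vox = [1.5, 1.5, 1.5]
    mat = [120, 120, 120]
    ax = geo.slice_axis(scan_plane)
    vox[ax] = 5.0
    mat[ax] = 36
    return SequenceParams(
        kind="T2w-FSE", tr_ms=2200.0, te_ms=180.0, scan_plane=scan_plane,
        voxel_size=tuple(vox), matrix=tuple(mat),
    )


def thermometer_sequence() -> SequenceParams:
    """Short-TE gradient-echo (FISP) scan for the LCMRV thermometer."""
    return SequenceParams(
        kind="FISP-thermometer", tr_ms=120.0, te_ms=5.0, scan_plane="axial",
        voxel_size=(1.5, 1.5, 5.0), matrix=(120, 120, 36),
    )


#: TI schedule of the T1-mapping protocol: 20 inversion times spaced
#: logarithmically between 25 and 4000 ms, TR 5 s.
IR_TI_SCHEDULE_MS = tuple(float(x) for x in np.geomspace(25.0, 4000.0, 20))
IR_TR_MS = 5000.0
#: TE schedule of the T2-mapping protocol: 16 echoes, first at 9 ms,
#: 5.4 ms spacing, TR 3 s.
MESE_TE_SCHEDULE_MS = tuple(9.0 + 5.4 * k for k in range(16))
MESE_TR_MS = 3000.0


# ---------------------------------------------------------------------------
# Distortion fields
# ---------------------------------------------------------------------------


DistortionField = Callable[[np.ndarray], np.ndarray]


def zero_field(points: np.ndarray) -> np.ndarray:
    return np.zeros_like(np.atleast_2d(points), dtype=float)


def radial_field(amplitude_mm: float, order: int = 2, cap_mm: float = 2.5) -> DistortionField:
    """Smooth radial distortion ``d(p) = a (|p|/R)^order p/|p|``, capped.

    Positive amplitude pushes features outward (barrel-like), negative pulls
    them inward (pincushion-like).  The magnitude cap mirrors the scale of
    distortions expected on these systems.
    """

    def field(points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        r = np.linalg.norm(p, axis=1, keepdims=True)
        unit = np.divide(p, r, out=np.zeros_like(p), where=r > 0)
        mag = amplitude_mm * (r / geo.SHELL_RADIUS_MM) ** order
        mag = np.clip(mag, -cap_mm, cap_mm)
        return unit * mag

    return field


def linear_field(matrix: np.ndarray, cap_mm: float = 2.5) -> DistortionField:
    """Low-order polynomial (affine) distortion ``d(p) = A p``, capped."""
    A = np.asarray(matrix, dtype=float).reshape(3, 3)

    def field(points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        d = p @ A.T
        mag = np.linalg.norm(d, axis=1, keepdims=True)
        scale = np.minimum(1.0, np.divide(cap_mm, mag, out=np.ones_like(mag), where=mag > 0))
        return d * scale

    return field


@dataclass
class SessionGroundTruth:
    """Everything the simulator knows that an analyst must recover."""

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    distortion: DistortionField | None = None
    noise_sigma: float = 0.0  # fraction of mean fill intensity
    temperature_c: float = 20.0
    site_baseline_mhz: float = DEFAULT_SITE_BASELINE_MHZ
    ref_temp_c: float = DEFAULT_REF_TEMP_C
    software_tag: str = "sim-1.0"
    site_id: str = "SIM01"

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    def rotation_matrix(self) -> np.ndarray:
        rx, ry, rz = np.deg2rad(self.rotation_deg)
        cx, sx, cy, sy, cz, sz = np.cos(rx), np.sin(rx), np.cos(ry), np.sin(ry), np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Rz @ Ry @ Rx

    def displace(self, points: np.ndarray) -> np.ndarray:
        """Apparent position of design-space points in this session."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = p @ self.rotation_matrix().T + np.asarray(self.translation_mm, dtype=float)
        if self.distortion is not None:
            out = out + self.distortion(p)
        return out

    def larmor_mhz(self) -> float:
        return larmor_frequency(self.temperature_c, self.site_baseline_mhz, self.ref_temp_c)


# ---------------------------------------------------------------------------
# Relaxation tables
# ---------------------------------------------------------------------------


def default_relax_table(
    geometry: geo.PhantomGeometry, temperature_c: float = 20.0
) -> dict[str, tuple[float, float, float] | None]:
    """Map feature id -> (PD, T1 s, T2 s); None marks signal-free features.

    Thermometer elements start bright (fill-like); :func:`rasterize_phantom`
    switches elements past their transition to signal-free based on the
    session temperature.
    """
    table: dict[str, tuple[float, float, float] | None] = {
        "fill": (1.0, geo.FILL_T1_S, geo.FILL_T2_S)
    }
    for f in geometry.fiducials():
        table[f.feature_id] = None  # solid spheres: no signal
    for m in geometry.all_mimics():
        table[m.feature_id] = (1.0, m.t1_ref, m.t2_ref)
    for k in range(1, len(geometry.thermometer.element_transition_temps) + 1):
        table[f"thermo-{k}"] = (1.0, geo.FILL_T1_S, geo.FILL_T2_S)
    return table


def feature_label_id(feature_id: str) -> int:
    """Deterministic integer label for a phantom feature id."""
    if feature_id == "fill":
        return FILL_LABEL
    kind, _, idx = feature_id.partition("-")
    if kind == "fiducial":
        return int(idx)
    return _LABEL_BLOCKS[kind] + int(idx)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

_SUPERSAMPLE = 3


def _grid_from_sequence(seq: SequenceParams) -> tuple[np.ndarray, np.ndarray]:
    affine = center_affine(seq.matrix, seq.voxel_size)
    return np.zeros(seq.matrix, dtype=np.float64), affine


def _sphere_fractions(shape, affine, center, radius, axis_coords):
    """Per-voxel occupancy fraction of a sphere, supersampled locally."""
    voxel = np.diag(affine[:3, :3])
    origin = affine[:3, 3]
    lo_idx = np.maximum(0, np.floor((center - radius - origin) / voxel - 1).astype(int))
    hi_idx = np.minimum(np.asarray(shape) - 1, np.ceil((center + radius - origin) / voxel + 1).astype(int))
    if np.any(lo_idx > hi_idx):
        return None
    sl = tuple(slice(lo, hi + 1) for lo, hi in zip(lo_idx, hi_idx))
    # supersampled offsets within a voxel, centered
    offs = (np.arange(_SUPERSAMPLE) + 0.5) / _SUPERSAMPLE - 0.5
    frac = np.zeros([hi - lo + 1 for lo, hi in zip(lo_idx, hi_idx)], dtype=np.float64)
    ax = [axis_coords[d][sl[d]] for d in range(3)]
    for ox in offs:
        dx2 = (ax[0] + ox * voxel[0] - center[0]) ** 2
        for oy in offs:
            dy2 = (ax[1] + oy * voxel[1] - center[1]) ** 2
            for oz in offs:
                dz2 = (ax[2] + oz * voxel[2] - center[2]) ** 2
                inside = (
                    dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
                ) <= radius**2
                frac += inside
    frac /= _SUPERSAMPLE**3
    return sl, frac


def _axis_coords(shape, affine):
    voxel = np.diag(affine[:3, :3])
    origin = affine[:3, 3]
    return [origin[d] + voxel[d] * np.arange(shape[d]) for d in range(3)]


def _sequence_signal(seq: SequenceParams, pd: float, t1: float, t2: float) -> float:
    tr = seq.tr_ms / 1000.0
    if seq.kind in ("T2w-FSE", "FISP-thermometer"):
        te = float(np.atleast_1d(seq.te_ms)[0]) / 1000.0
        return float(fse_signal(pd, t1, t2, tr, te))
    if seq.kind == "MESE":
        te = float(np.atleast_1d(seq.te_ms)[0]) / 1000.0
        return float(mese_signal(pd, t2, te))
    if seq.kind == "IR-TSE":
        ti = float(seq.ti_ms[0]) / 1000.0
        return float(ir_signal(pd, t1, ti, tr))
    raise ValueError(f"unknown sequence kind: {seq.kind!r}")


def _session_features(geometry: geo.PhantomGeometry, truth: SessionGroundTruth):
    """(feature_id, displaced center, radius) for every rendered feature."""
    feats: list[tuple[str, np.ndarray, float]] = []
    fid_r = geometry.fiducial_diameter / 2.0
    mim_r = geometry.mimic_inner_diameter / 2.0
    for f in geometry.fiducials():
        feats.append((f.feature_id, np.asarray(f.design_position, dtype=float), fid_r))
    for m in geometry.all_mimics():
        feats.append((m.feature_id, np.asarray(m.center, dtype=float), mim_r))
    for k, pos in enumerate(geometry.thermometer.element_positions, start=1):
        feats.append((f"thermo-{k}", np.asarray(pos, dtype=float), geo.THERMOMETER_ELEMENT_RADIUS_MM))
    ids = [f[0] for f in feats]
    centers = truth.displace(np.array([f[1] for f in feats]))
    radii = [f[2] for f in feats]
    return list(zip(ids, centers, radii))


def rasterize_phantom(
    geometry: geo.PhantomGeometry,
    seq: SequenceParams,
    truth: SessionGroundTruth,
    relax_table: dict | None = None,
    seed: int | None = 0,
    with_labels: bool = False,
):
    """Render one scan volume (optionally with ground-truth labels).

    Each voxel's noiseless intensity is the sequence signal of the feature
    occupying it (fill solution inside the shell, zero outside; solid
    fiducials and transitioned thermometer elements signal-free), with
    partial-volume mixing from supersampled occupancy fractions.  Feature
    positions are displaced by the session's rigid misplacement plus the
    smooth distortion field evaluated at each design center.  Independent
    additive Gaussian noise with SD ``noise_sigma x mean fill intensity`` is
    then applied (clipped at zero); the seed fully determines the output.
    """
    relax_table = relax_table if relax_table is not None else default_relax_table(geometry)
    data, affine = _grid_from_sequence(seq)
    coords = _axis_coords(data.shape, affine)

    # Shell: fill-solution interior displaced by the rigid part only.
    shell_center = truth.displace(np.zeros((1, 3)))[0]
    if "fill" not in relax_table:
        raise KeyError("relax_table missing entry for 'fill'")
    fill_signal = _sequence_signal(seq, *relax_table["fill"])
    dx2 = (coords[0] - shell_center[0]) ** 2
    dy2 = (coords[1] - shell_center[1]) ** 2
    dz2 = (coords[2] - shell_center[2]) ** 2
    r = np.sqrt(dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :])
    voxel_scale = float(np.mean(np.diag(affine[:3, :3])))
    shell_frac = np.clip((geo.SHELL_RADIUS_MM - r) / voxel_scale + 0.5, 0.0, 1.0)
    data[:] = fill_signal * shell_frac
    labels = np.zeros(data.shape, dtype=np.int16) if with_labels else None
    legend = {FILL_LABEL: "fill"} if with_labels else None
    if with_labels:
        labels[shell_frac > 0.5] = FILL_LABEL

    transitions = dict(
        zip(
            (f"thermo-{k}" for k in range(1, len(geometry.thermometer.element_transition_temps) + 1)),
            geometry.thermometer.element_transition_temps,
        )
    )
    for feature_id, center, radius in _session_features(geometry, truth):
        if feature_id not in relax_table:
            raise KeyError(f"relax_table missing entry for {feature_id!r}")
        params = relax_table[feature_id]
        if feature_id in transitions and truth.temperature_c >= transitions[feature_id]:
            params = None  # liquid crystal past transition: dark
        hit = _sphere_fractions(data.shape, affine, center, radius, coords)
        if hit is None:
            continue
        sl, frac = hit
        signal = 0.0 if params is None else _sequence_signal(seq, *params)
        data[sl] = data[sl] * (1.0 - frac) + frac * signal
        if with_labels:
            labels[sl][frac > 0.5] = feature_label_id(feature_id)
            legend[feature_label_id(feature_id)] = feature_id

    mean_fill = fill_signal
    if truth.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data += rng.normal(0.0, truth.noise_sigma * mean_fill, size=data.shape)
        np.clip(data, 0.0, None, out=data)

    meta = {
        "kind": seq.kind,
        "tr_ms": seq.tr_ms,
        "te_ms": seq.te_ms if np.isscalar(seq.te_ms) else list(seq.te_ms),
        "ti_ms": list(seq.ti_ms),
        "site": truth.site_id,
        "software_tag": truth.software_tag,
        "larmor_freq_mhz": truth.larmor_mhz(),
        "noise_sigma": truth.noise_sigma,
        "seed": seed,
    }
    vol = ScanVolume(data, affine, seq.scan_plane, meta)
    if with_labels:
        return vol, LabelVolume(labels, affine, legend, seq.scan_plane)
    return vol


def add_noise(volume: ScanVolume, noise_sigma: float, mean_fill: float, seed: int) -> ScanVolume:
    """Fresh additive Gaussian noise on a noiseless volume (clipped at 0)."""
    rng = np.random.default_rng(seed)
    data = volume.data + rng.normal(0.0, noise_sigma * mean_fill, size=volume.data.shape)
    meta = dict(volume.meta)
    meta.update(noise_sigma=noise_sigma, seed=seed)
    return ScanVolume(np.clip(data, 0.0, None), volume.affine.copy(), volume.scan_plane, meta)


def make_template(
    geometry: geo.PhantomGeometry | None = None,
    voxel_mm: float = 1.0,
    contrast_like: SequenceParams | None = None,
) -> tuple[ScanVolume, LabelVolume]:
    """Noiseless, undistorted isotropic rendering with rasterized labels.

    The analogue of a high-field, high-resolution template scan with
    manually segmented features: the reference both for registration-based
    label transfer and for the design-space feature positions.  Pass
    ``contrast_like`` to render the template with another sequence's
    weighting (e.g. the short-TE thermometer scan) so the registration
    similarity metric compares like with like.
    """
    geometry = geometry or geo.PhantomGeometry()
    n = int(np.ceil(184.0 / voxel_mm))
    base = contrast_like or SequenceParams(kind="T2w-FSE", tr_ms=2200.0, te_ms=180.0)
    seq = SequenceParams(
        kind=base.kind, tr_ms=base.tr_ms, te_ms=base.te_ms, ti_ms=base.ti_ms,
        scan_plane="axial", voxel_size=(voxel_mm,) * 3, matrix=(n, n, n),
    )
    truth = SessionGroundTruth(temperature_c=-273.0)  # below all transitions: all elements bright
    return rasterize_phantom(geometry, seq, truth, seed=None, with_labels=True)


# ---------------------------------------------------------------------------
# Sessions
# ---------------------------------------------------------------------------

QC_ROLES = ("axial_t2w", "axial_t2w_repeat", "sagittal_t2w", "coronal_t2w", "thermometer")


def default_protocol() -> dict[str, SequenceParams]:
    """The five-scan QC protocol: three orthogonal T2w scans, a repeated
    axial T2w for PSNR, and the short-TE thermometer scan."""
    return {
        "axial_t2w": t2w_sequence("axial"),
        "axial_t2w_repeat": t2w_sequence("axial"),
        "sagittal_t2w": t2w_sequence("sagittal"),
        "coronal_t2w": t2w_sequence("coronal"),
        "thermometer": thermometer_sequence(),
    }


def simulate_session(
    geometry: geo.PhantomGeometry | None = None,
    truth: SessionGroundTruth | None = None,
    protocol: dict[str, SequenceParams] | None = None,
    seed: int = 0,
    relax_table: dict | None = None,
) -> tuple[dict[str, ScanVolume], dict]:
    """Simulate one QC session: role -> volume, plus a JSON-able sidecar.

    The repeated axial scan shares the noiseless rendering of the first
    axial scan and differs only in its noise realization.  Per-scan seeds
    are derived deterministically from the session seed.
    """
    geometry = geometry or geo.PhantomGeometry()
    truth = truth or SessionGroundTruth()
    protocol = protocol or default_protocol()
    if not protocol:
        raise ValueError("protocol must be nonempty")
    relax_table = relax_table if relax_table is not None else default_relax_table(geometry)

    ss = np.random.SeedSequence(seed)
    scan_seeds = [int(s) % (2**31) for s in ss.generate_state(len(protocol) + 1)]

    scans: dict[str, ScanVolume] = {}
    noiseless = truth if truth.noise_sigma == 0 else replace(truth, noise_sigma=0.0)
    axial_clean = None
    for k, (role, seq) in enumerate(protocol.items()):
        if role == "axial_t2w_repeat" and axial_clean is not None:
            clean = axial_clean
        else:
            clean = rasterize_phantom(geometry, seq, noiseless, relax_table, seed=None)
            if role == "axial_t2w":
                axial_clean = clean
        if truth.noise_sigma > 0:
            fill_signal = _sequence_signal(seq, *relax_table["fill"])
            vol = add_noise(clean, truth.noise_sigma, fill_signal, scan_seeds[k])
        else:
            vol = ScanVolume(clean.data.copy(), clean.affine.copy(), clean.scan_plane, dict(clean.meta))
        vol.meta.update(role=role, site=truth.site_id, software_tag=truth.software_tag,
                        larmor_freq_mhz=truth.larmor_mhz())
        scans[role] = vol

    sidecar = {
        "site": truth.site_id,
        "software_tag": truth.software_tag,
        "larmor_freq_mhz": truth.larmor_mhz(),
        "temperature_truth_c": truth.temperature_c,
        "noise_sigma": truth.noise_sigma,
        "seed": seed,
        "roles": list(scans),
    }
    return scans, sidecar


def write_session(scans: dict[str, ScanVolume], sidecar: dict, out_dir: str | Path) -> Path:
    """Write a simulated session as NIfTI volumes plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for role, vol in scans.items():
        vol.save(out / f"{role}.nii.gz")
    with open(out / "session.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return out
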