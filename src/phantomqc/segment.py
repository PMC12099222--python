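"""Feature localization: template registration, label transfer, fiducials.

Two complementary strategies, mirroring how phantom features are found on
real scans:

* mimics, fill mask and thermometer elements come from *label transfer*: a
  high-resolution template rendering with known labels is rigidly registered
  to the acquired volume (normalized cross-correlation, center-of-mass
  initialization, multi-resolution gradient descent via SimpleITK) and the
  template labels are resampled nearest-neighbor onto the acquired grid;
* fiducial spheres are found *independently of the template* by a classical
  detector (Otsu threshold inside the phantom mask on the inverted image,
  connected components, size/shape gating near the 10 mm design diameter),
  because a template-constrained position would inherit the registration's
  global transform and hide exactly the distortions the fiducials measure.
  Detected centroids are intensity-weighted centers of gravity in world
  millimeters, assigned to design ids by optimal (Hungarian) matching after
  a coarse rigid pre-alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from . import geometry as geo
from .volume import LabelVolume, ScanVolume

#: Registration objective (NCC) below which the result is flagged.
LOW_CONFIDENCE_NCC = 0.6


@dataclass(frozen=True)
class RigidTransform:
    """Rigid map ``p_design = R @ p_acquired + t`` (world mm).

    ``register_template`` returns transforms in this orientation: they carry
    points from the acquired volume's world space into the template/design
    space, which is the direction both label resampling and design-space
    analysis need.
    """

    rotation: np.ndarray
    translation: np.ndarray
    objective: float | None = None
    low_confidence: bool = False

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(R @ R.T - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation not orthonormal (err={err:.2e})")
        if err > 1e-12:  # re-orthonormalize tiny numerical drift
            U, _, Vt = np.linalg.svd(R)
            R = U @ Vt
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det=+1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return p @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation, self.objective, self.low_confidence)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def rotation_angles_deg(self) -> np.ndarray:
        """Euler angles (x, y, z, degrees) of the rotation, for reporting."""
        R = self.rotation
        ry = np.arcsin(np.clip(-R[2, 0], -1, 1))
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
        return np.rad2deg([rx, ry, rz])


def _to_sitk(volume: ScanVolume) -> sitk.Image:
    # package affines are axis-aligned: diagonal spacing + origin
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(volume.data, (2, 1, 0)), dtype=np.float64))
    img.SetSpacing(tuple(float(v) for v in np.diag(volume.affine[:3, :3])))
    img.SetOrigin(tuple(float(v) for v in volume.affine[:3, 3]))
    return img


def register_template(template: ScanVolume, target: ScanVolume) -> RigidTransform:
    """Rigid registration of the template onto an acquired volume.

    Maximizes normalized cross-correlation over the six rigid parameters,
    starting from a moments (center-of-mass) initialization, coarse-to-fine.
    Returns the acquired-to-template transform with the achieved NCC as its
    objective; results with NCC below ``LOW_CONFIDENCE_NCC`` are flagged
    rather than rejected.
    """
    fixed = _to_sitk(target)
    moving = _to_sitk(template)
    initial = sitk.CenteredTransformInitializer(
        fixed, moving, sitk.Euler3DTransform(), sitk.CenteredTransformInitializerFilter.MOMENTS
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-5, numberOfIterations=300,
        gradientMagnitudeTolerance=1e-7,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([3.0, 1.5, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(initial, inPlace=False)
    result = reg.Execute(fixed, moving)
    ncc = -float(reg.GetMetricValue())  # ITK minimizes the negative NCC

    res = result.Downcast() if hasattr(result, "Downcast") else result
    if isinstance(res, sitk.CompositeTransform):
        if res.GetNumberOfTransforms() != 1:
            res.FlattenTransform()
        res = res.GetNthTransform(res.GetNumberOfTransforms() - 1)
        res = res.Downcast() if hasattr(res, "Downcast") else res
    euler = sitk.Euler3DTransform(res)
    M = np.asarray(euler.GetMatrix(), dtype=float).reshape(3, 3)
    c = np.asarray(euler.GetCenter(), dtype=float)
    t = np.asarray(euler.GetTranslation(), dtype=float)
    translation = c + t - M @ c  # p' = M (p - c) + c + t
    return RigidTransform(M, translation, objective=ncc, low_confidence=ncc < LOW_CONFIDENCE_NCC)


def _index_transform(transform: RigidTransform, source_affine: np.ndarray, target_affine: np.ndarray):
    """Matrix/offset mapping target voxel indices to source voxel indices."""
    T = np.linalg.inv(source_affine) @ transform.matrix() @ target_affine
    return T[:3, :3], T[:3, 3]


def transfer_labels(
    transform: RigidTransform, template_labels: LabelVolume, target: ScanVolume
) -> LabelVolume:
    """Resample template labels onto the target grid (nearest neighbor).

    The legend is preserved; entries whose label ends up with empty support
    on the target grid are reported in ``meta`` rather than silently lost.
    """
    M, offset = _index_transform(transform, template_labels.affine, target.affine)
    out = ndimage.affine_transform(
        template_labels.labels, M, offset=offset, output_shape=target.shape,
        order=0, mode="constant", cval=0, prefilter=False,
    )
    result = LabelVolume(out.astype(np.int16), target.affine.copy(), dict(template_labels.legend), target.scan_plane)
    present = set(np.unique(out))
    result.missing = sorted(
        fid for lid, fid in template_labels.legend.items() if lid not in present
    )
    return result


def phantom_mask(volume: ScanVolume) -> np.ndarray:
    """Foreground mask of the phantom: Otsu, largest component, holes filled."""
    thr = threshold_otsu(volume.data)
    fg = volume.data > thr
    lab = cc_label(fg)
    if lab.max() == 0:
        raise ValueError("no foreground found")
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    mask = lab == np.argmax(sizes)
    return ndimage.binary_fill_holes(mask)


def detect_fiducials(
    volume: ScanVolume,
    design: list[geo.Fiducial] | None = None,
    min_volume_mm3: float = 200.0,
    max_volume_mm3: float = 1400.0,
    max_extent_mm: float = 22.0,
) -> list[tuple[int, np.ndarray]]:
    """Detect the dark fiducial spheres and assign design ids.

    Returns ``[(fiducial_id, centroid_mm), ...]`` sorted by id, at most one
    entry per id.  Raises if fewer than four fiducials are found (a rigid
    alignment would be underdetermined).
    """
    design = design or geo.design_fiducial_coordinates()
    mask = phantom_mask(volume)
    # avoid the partial-volume rim at the shell boundary
    interior = ndimage.binary_erosion(mask, iterations=2)
    vals = volume.data[interior]
    # The fill solution dominates the interior, so its level is the median;
    # signal-free spheres sit near zero.  A half-fill threshold separates
    # them robustly (a global Otsu would split fill from bright mimics
    # instead, the dark class being far too small to drive the histogram).
    fill_level = float(np.median(vals))
    thr = 0.5 * fill_level
    dark = (volume.data < thr) & interior

    voxel = volume.voxel_size
    voxel_vol = float(np.prod(voxel))
    lab = cc_label(dark)
    weights = np.clip(fill_level - volume.data, 0.0, None)

    centroids = []
    for region in regionprops(lab):
        vol_mm3 = region.num_pixels * voxel_vol
        if not (min_volume_mm3 <= vol_mm3 <= max_volume_mm3):
            continue
        lo = np.array(region.bbox[:3])
        hi = np.array(region.bbox[3:])
        extent_mm = (hi - lo) * voxel
        if np.any(extent_mm > max_extent_mm):
            continue
        sel = lab == region.label
        idx = np.argwhere(sel).astype(float)
        w = weights[sel]
        if w.sum() <= 0:
            continue
        com_idx = (idx * w[:, None]).sum(axis=0) / w.sum()
        centroids.append(volume.index_to_world(com_idx)[0])

    if len(centroids) < 4:
        raise ValueError(f"only {len(centroids)} fiducial candidates detected (need >= 4)")

    detected = np.array(centroids)
    design_pts = np.array([f.design_position for f in design])
    design_ids = [f.id for f in design]

    # coarse pre-alignment: centroid shift, then two rounds of optimal
    # matching refined by a rigid (Kabsch) fit on the current matches
    shift = design_pts.mean(axis=0) - detected.mean(axis=0)
    aligned = detected + shift
    pairs: list[tuple[int, int]] = []
    for _ in range(2):
        cost = np.linalg.norm(aligned[:, None, :] - design_pts[None, :, :], axis=2)
        rows, cols = linear_sum_assignment(cost)
        pairs = list(zip(rows, cols))
        if len(pairs) >= 3:
            from .metrics import kabsch  # deferred: metrics imports this module's types

            R, t = kabsch(detected[[r for r, _ in pairs]], design_pts[[c for _, c in pairs]])
            aligned = detected @ R.T + t

    out = [(design_ids[c], detected[r]) for r, c in pairs]
    ids = [i for i, _ in out]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate fiducial id assignment")
    return sorted(out, key=lambda x: x[0])


def mid_slice_crop(
    labels: LabelVolume, feature_center, transform: RigidTransform
) -> LabelVolume:
    """Keep only label voxels in the slice containing a feature's center.

    ``feature_center`` is the design-space center; it is warped into the
    acquired grid through the inverse of the acquired-to-design transform,
    and only the single slice along the low-resolution (slice) axis that
    contains the warped center is retained.
    """
    voxel = np.linalg.norm(labels.affine[:3, :3], axis=0)
    ax = int(np.argmax(voxel))
    center_acq = transform.inverse().apply(feature_center)[0]
    inv = np.linalg.inv(labels.affine)
    idx = (inv[:3, :3] @ center_acq + inv[:3, 3])
    k = int(np.round(idx[ax]))
    if not 0 <= k < labels.labels.shape[ax]:
        raise ValueError("warped feature center lies outside the label grid")
    out = np.zeros_like(labels.labels)
    sl = [slice(None)] * 3
    sl[ax] = slice(k, k + 1)
    out[tuple(sl)] = labels.labels[tuple(sl)]
    return LabelVolume(out, labels.affine.copy(), dict(labels.legend), labels.scan_plane)
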