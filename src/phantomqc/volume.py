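"""In-memory containers for 3D scan and label volumes.

A :class:`ScanVolume` is a non-negative intensity grid together with an
invertible 4x4 grid-to-world affine (millimeters), a scan-plane tag, and
free-form acquisition metadata.  Data axes are world-aligned (index axis 0
is x, 1 is y, 2 is z); the scan plane only determines which axis carries the
coarse slice spacing.  Volumes round-trip through NIfTI-1 via nibabel with a
JSON sidecar for the metadata nibabel cannot carry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


def center_affine(shape, voxel_size) -> np.ndarray:
    """Axis-aligned affine placing the grid center at the world origin."""
    shape = np.asarray(shape, dtype=float)
    voxel = np.asarray(voxel_size, dtype=float)
    aff = np.eye(4)
    aff[:3, :3] = np.diag(voxel)
    aff[:3, 3] = -voxel * (shape - 1) / 2.0
    return aff


@dataclass
class ScanVolume:
    """A 3D intensity volume with spatial and acquisition metadata."""

    data: np.ndarray
    affine: np.ndarray
    scan_plane: str = "axial"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ScanVolume data must be 3D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inv = np.linalg.inv(self.affine[:3, :3])
        return (pts - self.affine[:3, 3]) @ inv.T

    def world_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinate of every voxel along each axis (broadcastable)."""
        axes = []
        for ax in range(3):
            n = self.data.shape[ax]
            idx = np.zeros((n, 3))
            idx[:, ax] = np.arange(n)
            coords = self.index_to_world(idx)[:, ax] - self.affine[:3, 3][ax] + self.affine[:3, 3][ax]
            shape = [1, 1, 1]
            shape[ax] = n
            axes.append(coords.reshape(shape))
        # affine is axis-aligned in this package, so per-axis coords suffice
        return axes[0], axes[1], axes[2]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        nib.save(img, str(path))
        sidecar = dict(self.meta)
        sidecar["scan_plane"] = self.scan_plane
        with open(_sidecar_path(path), "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "ScanVolume":
        path = Path(path)
        img = nib.load(str(path))
        meta: dict = {}
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = json.load(fh)
        plane = meta.pop("scan_plane", "axial")
        return cls(np.asarray(img.dataobj, dtype=np.float32), img.affine, plane, meta)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".json")
    return path.with_suffix(".json")


@dataclass
class LabelVolume:
    """Integer feature labels on a ScanVolume grid.

    ``legend`` maps each positive label id to a phantom feature id string
    (e.g. ``"fiducial-03"``, ``"MnCl2-4"``, ``"fill"``); 0 is background.
    """

    labels: np.ndarray
    affine: np.ndarray
    legend: dict[int, str]
    scan_plane: str = "axial"

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        if self.labels.min() < 0:
            raise ValueError("label ids must be non-negative")
        self.legend = {int(k): str(v) for k, v in self.legend.items()}

    def mask(self, *label_ids: int) -> np.ndarray:
        if not label_ids:
            return self.labels > 0
        return np.isin(self.labels, label_ids)

    def id_of(self, feature_id: str) -> int:
        for k, v in self.legend.items():
            if v == feature_id:
                return k
        raise KeyError(f"feature {feature_id!r} not in legend")

    def feature_mask(self, feature_id: str) -> np.ndarray:
        return self.labels == self.id_of(feature_id)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        img = nib.Nifti1Image(np.asarray(self.labels, dtype=np.int16), self.affine)
        nib.save(img, str(path))
        with open(_sidecar_path(path), "w") as fh:
            json.dump({"legend": self.legend, "scan_plane": self.scan_plane}, fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "LabelVolume":
        path = Path(path)
        img = nib.load(str(path))
        with open(_sidecar_path(path)) as fh:
            side = json.load(fh)
        legend = {int(k): v for k, v in side["legend"].items()}
        return cls(np.asarray(img.dataobj, dtype=np.int16), img.affine, legend, side.get("scan_plane", "axial"))
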