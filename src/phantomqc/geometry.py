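"""Design-space geometry of the 170 mm multi-compartment QC phantom.

This module is the single source of truth for where every physical feature of
the phantom sits in "design space": a right-handed, millimeter coordinate
frame with its origin at the center of the plate stack, +x left-to-right,
+y posterior-to-anterior, +z inferior-to-superior.  The simulator renders
scans from these coordinates, the segmentation module transfers labels keyed
to them, and the distortion analysis registers detected fiducial centroids
back onto them.

The phantom combines a relaxometry/diffusion system phantom with a diffusion
array, shrunk to a 170 mm shell:

* 15 solid fiducial spheres (10 mm diameter) arranged as a cross of five on
  each of three plates, 50 mm center-to-center along every axis.  They are
  signal-free and provide negative contrast against the CuSO4 fill solution;
  their imaged centroids measure geometric distortion.
* three quantitative arrays of 14 tissue-mimic spheres each (18 mm inner
  diameter): NiCl2 (T1 array), MnCl2 (T2 array), and PVP in water (ADC
  array).
* a liquid-crystal MR-visible (LCMRV) thermometer: ten elements whose phase
  transitions sit at whole-degree steps from 15 to 24 deg C.  Elements past
  their transition turn dark on short-TE images; counting dark elements
  reads the phantom temperature, capped at 24.5 deg C.

Exact per-mimic concentrations and the angular placement of mimics on each
plate are not part of the published phantom description; the layout below is
a frozen, deterministic template and all downstream analysis depends only on
its self-consistency with the simulator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

# ---------------------------------------------------------------------------
# Physical design constants (mm, mM, % w/w, deg C)
# ---------------------------------------------------------------------------

SHELL_DIAMETER_MM = 170.0
SHELL_RADIUS_MM = SHELL_DIAMETER_MM / 2.0
FIDUCIAL_DIAMETER_MM = 10.0
MIMIC_INNER_DIAMETER_MM = 18.0
FIDUCIAL_SPACING_MM = 50.0
PLATE_OFFSETS_MM = (-50.0, 0.0, 50.0)
FILL_CUSO4_CONC_MM = 2.9

ARRAYS = ("T1-NiCl2", "T2-MnCl2", "ADC-PVP")
N_MIMICS_PER_ARRAY = 14

NICL2_CONC_RANGE_MM = (0.29, 65.3)
MNCL2_CONC_RANGE_MM = (0.0113, 1.5996)
PVP_CONC_RANGE_PCT = (0.0, 50.0)
# ADC falls as PVP concentration rises: 2.00e-3 mm^2/s for pure water down to
# 0.27e-3 mm^2/s at 50% w/w PVP.
ADC_RANGE_MM2_S = (2.00e-3, 0.27e-3)

THERMOMETER_TRANSITIONS_C = tuple(float(t) for t in range(15, 25))
THERMOMETER_MAX_C = 24.5
THERMOMETER_ELEMENT_RADIUS_MM = 3.0

#: Default relaxivities (mM^-1 s^-1) and zero-concentration rates (s^-1) used
#: to derive the reference T1/T2 of each doped mimic: R = R0 + r * C.
DEFAULT_RELAXIVITY = {
    "T1-NiCl2": {"r1": 0.624, "r2": 0.549, "R1_0": 0.3, "R2_0": 0.5},
    "T2-MnCl2": {"r1": 21.9, "r2": 34.6, "R1_0": 0.3, "R2_0": 3.0},
}

#: Fill solution (2.9 mM CuSO4) reference relaxation times, seconds.
FILL_T1_S = 0.25
FILL_T2_S = 0.20

SCAN_PLANES = ("axial", "sagittal", "coronal")
#: In-plane axis indices per scan plane (the remaining axis is the slice axis).
_INPLANE_AXES = {"axial": (0, 1), "sagittal": (1, 2), "coronal": (0, 2)}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fiducial:
    """A solid fiducial sphere at an exactly known design position."""

    id: int
    plate: int
    design_position: tuple[float, float, float]

    @property
    def feature_id(self) -> str:
        return f"fiducial-{self.id:02d}"


@dataclass(frozen=True)
class MimicSpec:
    """One tissue-mimic sphere of a quantitative array."""

    array: str
    index: int
    concentration: float
    center: tuple[float, float, float]
    t1_ref: float
    t2_ref: float
    adc_ref: float | None = None

    @property
    def feature_id(self) -> str:
        short = {"T1-NiCl2": "NiCl2", "T2-MnCl2": "MnCl2", "ADC-PVP": "PVP"}[self.array]
        return f"{short}-{self.index}"


@dataclass(frozen=True)
class ThermometerSpec:
    """The LCMRV thermometer: element positions and transition temperatures."""

    element_transition_temps: tuple[float, ...] = THERMOMETER_TRANSITIONS_C
    max_reportable: float = THERMOMETER_MAX_C
    element_positions: tuple[tuple[float, float, float], ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        temps = self.element_transition_temps
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("transition temperatures must be strictly increasing")
        if self.element_positions is None:
            object.__setattr__(
                self, "element_positions", _default_thermometer_positions(len(temps))
            )
        if len(self.element_positions) != len(temps):
            raise ValueError("one position per thermometer element required")

    def n_dark(self, temperature_c: float) -> int:
        """Number of elements past their phase transition at a temperature."""
        return int(sum(temperature_c >= t for t in self.element_transition_temps))

    def temperature_from_n_dark(self, n_dark: int) -> float:
        """Calibration: n dark elements -> reported temperature (deg C).

        One dark element corresponds to 15.5 deg C and each further element
        adds one degree, so ``T = 14.5 + n_dark``; with all ten elements dark
        the reading saturates at the 24.5 deg C maximum.
        """
        if not 0 <= n_dark <= len(self.element_transition_temps):
            raise ValueError(f"n_dark out of range: {n_dark}")
        return 14.5 + n_dark


def _default_thermometer_positions(n: int) -> tuple[tuple[float, float, float], ...]:
    # A row of small elements on the central plate, posterior of the mimic
    # rings, resolved in-plane on anisotropic axial scans.
    xs = np.linspace(-27.0, 27.0, n)
    return tuple((float(x), -72.0, 0.0) for x in xs)


@dataclass(frozen=True)
class PhantomGeometry:
    """Complete design-space description of the phantom."""

    shell_diameter: float = SHELL_DIAMETER_MM
    fiducial_diameter: float = FIDUCIAL_DIAMETER_MM
    mimic_inner_diameter: float = MIMIC_INNER_DIAMETER_MM
    plate_offsets: tuple[float, float, float] = PLATE_OFFSETS_MM
    fill_solution_conc: float = FILL_CUSO4_CONC_MM
    thermometer: ThermometerSpec = field(default_factory=ThermometerSpec)

    def __post_init__(self):
        if self.shell_diameter != 170.0:
            raise ValueError("phantom shell diameter is fixed at 170 mm")
        if len(self.plate_offsets) != 3:
            raise ValueError("exactly three plates")

    @property
    def shell_radius(self) -> float:
        return self.shell_diameter / 2.0

    def fiducials(self) -> list[Fiducial]:
        return design_fiducial_coordinates(self)

    def mimics(self, array: str) -> list[MimicSpec]:
        return mimic_table(array, geometry=self)

    def all_mimics(self) -> list[MimicSpec]:
        return [m for a in ARRAYS for m in self.mimics(a)]

    def features_json(self) -> list[dict]:
        """Exportable feature list: id, type, center, size, concentration."""
        out: list[dict] = []
        for f in self.fiducials():
            out.append(
                {
                    "id": f.feature_id,
                    "type": "fiducial",
                    "center": list(f.design_position),
                    "size_mm": self.fiducial_diameter,
                    "concentration": None,
                }
            )
        for m in self.all_mimics():
            out.append(
                {
                    "id": m.feature_id,
                    "type": "mimic",
                    "array": m.array,
                    "center": list(m.center),
                    "size_mm": self.mimic_inner_diameter,
                    "concentration": m.concentration,
                    "t1_ref_s": m.t1_ref,
                    "t2_ref_s": m.t2_ref,
                    "adc_ref": m.adc_ref,
                }
            )
        for k, (pos, temp) in enumerate(
            zip(self.thermometer.element_positions, self.thermometer.element_transition_temps),
            start=1,
        ):
            out.append(
                {
                    "id": f"thermo-{k}",
                    "type": "thermometer-element",
                    "center": list(pos),
                    "size_mm": 2 * THERMOMETER_ELEMENT_RADIUS_MM,
                    "transition_temp_c": temp,
                }
            )
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.features_json(), fh, indent=1)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def design_fiducial_coordinates(geometry: PhantomGeometry | None = None) -> list[Fiducial]:
    """Design positions of the 15 fiducial spheres.

    Each of the three plates (axial offsets -50, 0, +50 mm) carries a cross
    of five spheres: the plate center plus four arms offset +/-50 mm along
    the in-plane axes.  Ordering is deterministic by (plate, local position).
    """
    geometry = geometry or PhantomGeometry()
    s = FIDUCIAL_SPACING_MM
    arms = [(0.0, 0.0), (s, 0.0), (-s, 0.0), (0.0, s), (0.0, -s)]
    out: list[Fiducial] = []
    fid = 1
    for plate, z in enumerate(geometry.plate_offsets, start=1):
        for dx, dy in arms:
            out.append(Fiducial(id=fid, plate=plate, design_position=(dx, dy, float(z))))
            fid += 1
    return out


def in_plane_radius(position: Sequence[float], scan_plane: str) -> float:
    """Euclidean norm of a position's two in-plane components for a scan plane.

    axial -> (x, y); sagittal -> (y, z); coronal -> (x, z).
    """
    if scan_plane not in _INPLANE_AXES:
        raise ValueError(f"unknown scan plane: {scan_plane!r}")
    i, j = _INPLANE_AXES[scan_plane]
    p = np.asarray(position, dtype=float)
    return float(np.hypot(p[i], p[j]))


def inplane_axes(scan_plane: str) -> tuple[int, int]:
    """Indices of the in-plane axes for a scan plane."""
    if scan_plane not in _INPLANE_AXES:
        raise ValueError(f"unknown scan plane: {scan_plane!r}")
    return _INPLANE_AXES[scan_plane]


def slice_axis(scan_plane: str) -> int:
    """Index of the through-plane (slice) axis for a scan plane."""
    i, j = inplane_axes(scan_plane)
    return ({0, 1, 2} - {i, j}).pop()


def _mimic_centers(z: float) -> list[tuple[float, float, float]]:
    """Frozen in-plane template of the 14 mimic positions on one plate.

    Six mimics on an inner ring (r = 28 mm) and eight on an outer ring
    (r = 55 mm), both angularly offset from the fiducial cross arms so that
    every sphere keeps clearance from the fiducials (r = 50 mm on the axes)
    and stays fully inside the shell even on the +/-50 mm plates.
    """
    centers = []
    for k in range(6):  # indices 1-6
        a = np.deg2rad(30.0 + 60.0 * k)
        centers.append((28.0 * np.cos(a), 28.0 * np.sin(a), z))
    for k in range(8):  # indices 7-14
        a = np.deg2rad(22.5 + 45.0 * k)
        centers.append((55.0 * np.cos(a), 55.0 * np.sin(a), z))
    return [(float(x), float(y), float(zz)) for x, y, zz in centers]


def _geomspace_concentrations(lo: float, hi: float, n: int) -> np.ndarray:
    return np.geomspace(lo, hi, n)


def mimic_table(array: str, geometry: PhantomGeometry | None = None) -> list[MimicSpec]:
    """The 14 mimic specs of one quantitative array, ordered by concentration.

    Doped-array concentrations are geometrically spaced between the design
    extremes (the published range endpoints); per-mimic reference T1/T2
    follow the linear relaxation-rate model ``R = R0 + r * C`` with the
    default relaxivities.  PVP concentrations are linearly spaced 0-50% w/w
    with geometrically interpolated ADC and long water-like relaxation times.
    """
    geometry = geometry or PhantomGeometry()
    plate_of = {"T1-NiCl2": 0, "ADC-PVP": 1, "T2-MnCl2": 2}
    if array not in plate_of:
        raise ValueError(f"unknown array: {array!r}")
    z = geometry.plate_offsets[plate_of[array]]
    centers = _mimic_centers(float(z))
    n = N_MIMICS_PER_ARRAY

    specs: list[MimicSpec] = []
    if array == "ADC-PVP":
        concs = np.linspace(*PVP_CONC_RANGE_PCT, n)
        adcs = _geomspace_concentrations(*ADC_RANGE_MM2_S, n)
        # Long, slowly varying relaxation times: pure water down to dense PVP.
        t1s = np.geomspace(3.5, 1.0, n)
        t2s = np.geomspace(1.8, 0.5, n)
        for i in range(n):
            specs.append(
                MimicSpec(array, i + 1, float(concs[i]), centers[i], float(t1s[i]), float(t2s[i]), float(adcs[i]))
            )
        return specs

    rng = NICL2_CONC_RANGE_MM if array == "T1-NiCl2" else MNCL2_CONC_RANGE_MM
    concs = _geomspace_concentrations(rng[0], rng[1], n)
    rel = DEFAULT_RELAXIVITY[array]
    for i in range(n):
        c = float(concs[i])
        t1 = 1.0 / (rel["R1_0"] + rel["r1"] * c)
        t2 = 1.0 / (rel["R2_0"] + rel["r2"] * c)
        # Physically T2 <= T1; clamp the reference table where the simple
        # linear-rate extrapolation would cross.
        t2 = min(t1, t2)
        specs.append(MimicSpec(array, i + 1, c, centers[i], t1, t2, None))
    return specs
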