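"""Digital NU4-style image-quality phantom.

The phantom is a 30 mm diameter cylinder with three axial sections:

* a 20 mm rod section at the bottom: five fillable rods (1-5 mm
  diameter) at the uniform concentration, drilled into a cold
  (non-radioactive, water-equivalent) solid;
* a uniform hot section filled at a single activity concentration;
* within the top 15 mm of the uniform section, two cold chambers
  (8 mm inner / 10 mm outer diameter) filled with air and
  non-radioactive water respectively.

The activity concentration is derived from the total filled activity
(default 3.7 MBq) and the analytic fillable volume, so that the
voxelized phantom conserves the total to within voxelization error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants


# integer codes for RegionLabels volumes
LABEL_NAMES = {
    0: "background",
    1: "uniform",
    2: "rod_1",
    3: "rod_2",
    4: "rod_3",
    5: "rod_4",
    6: "rod_5",
    7: "cold_air",
    8: "cold_water",
    9: "wall",
}
LABEL_CODES = {name: code for code, name in LABEL_NAMES.items()}


class GeometryError(ValueError):
    """Raised when a phantom cannot be placed on the requested grid."""


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid: counts and voxel size in mm."""

    nx: int = 128
    ny: int = 128
    nz: int = 159
    dx: float = 0.776
    dy: float = 0.776
    dz: float = 0.796

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("voxel counts must be >= 1")
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("voxel sizes must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def voxel_volume_mm3(self) -> float:
        return self.dx * self.dy * self.dz

    def axis_coords(self, axis: str) -> np.ndarray:
        """Voxel-center coordinates in mm, centered on the grid origin."""
        n = {"x": self.nx, "y": self.ny, "z": self.nz}[axis]
        d = {"x": self.dx, "y": self.dy, "z": self.dz}[axis]
        return (np.arange(n) - (n - 1) / 2.0) * d


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and fill of the image-quality phantom."""

    body_diameter_mm: float = 30.0
    rod_region_length_mm: float = 20.0
    uniform_region_length_mm: float = 30.0
    rod_diameters_mm: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    rod_pitch_radius_mm: float = 7.0
    cold_chamber_inner_mm: float = 8.0
    cold_chamber_outer_mm: float = 10.0
    cold_chamber_length_mm: float = 15.0
    cold_chamber_offset_mm: float = 7.5
    total_activity_MBq: float = 3.7
    uniform_activity_conc: float | None = None  # Bq/mL; derived if None
    mu_water_per_mm: float = constants.MU_WATER_511_PER_MM
    mu_air_per_mm: float = constants.MU_AIR_511_PER_MM
    mu_wall_per_mm: float = constants.MU_WALL_511_PER_MM

    def __post_init__(self) -> None:
        if list(self.rod_diameters_mm) != sorted(self.rod_diameters_mm) or len(
            set(self.rod_diameters_mm)
        ) != len(self.rod_diameters_mm):
            raise ValueError("rod diameters must be strictly increasing")
        if self.cold_chamber_inner_mm >= self.cold_chamber_outer_mm:
            raise ValueError("chamber inner diameter must be < outer diameter")
        if self.total_activity_MBq < 0:
            raise ValueError("total activity must be >= 0")

    @property
    def length_mm(self) -> float:
        return self.rod_region_length_mm + self.uniform_region_length_mm

    def fillable_volume_mm3(self) -> float:
        """Analytic volume of all radioactive compartments, in mm^3."""
        r_body = self.body_diameter_mm / 2.0
        v_uniform = np.pi * r_body**2 * self.uniform_region_length_mm
        r_out = self.cold_chamber_outer_mm / 2.0
        v_chambers = 2.0 * np.pi * r_out**2 * self.cold_chamber_length_mm
        v_rods = sum(
            np.pi * (d / 2.0) ** 2 * self.rod_region_length_mm
            for d in self.rod_diameters_mm
        )
        return float(v_uniform - v_chambers + v_rods)

    def activity_concentration(self) -> float:
        """Uniform-fill activity concentration in Bq/mL."""
        if self.uniform_activity_conc is not None:
            return self.uniform_activity_conc
        v_mL = self.fillable_volume_mm3() / 1000.0
        return self.total_activity_MBq * 1e6 / v_mL


@dataclass
class ActivityMap:
    """Activity-concentration volume in Bq/mL on a grid."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activity values must be finite")
        if np.any(self.values < 0):
            raise ValueError("activity values must be non-negative")

    def total_activity_Bq(self) -> float:
        return float(self.values.sum() * self.grid.voxel_volume_mm3 / 1000.0)


@dataclass
class MuMap:
    """Linear attenuation coefficients (1/mm at 511 keV) on a grid."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("mu values must be finite and non-negative")


@dataclass
class RegionLabels:
    """Integer label volume; codes follow :data:`LABEL_NAMES`."""

    values: np.ndarray
    grid: GridSpec
    #: rod diameters too coarse to be resolved on the grid (< 2 voxels across)
    sub_resolution_rods_mm: tuple[float, ...] = ()

    def mask(self, name: str) -> np.ndarray:
        return self.values == LABEL_CODES[name]


@dataclass(frozen=True)
class NU4Geometry:
    """Placement of the phantom on the grid, for VOI construction.

    ``z`` ranges are in grid coordinates (mm, grid-centered); rod
    centers are in-plane ``(x, y)`` mm.
    """

    rod_centers_mm: dict[float, tuple[float, float]]
    rod_z_mm: tuple[float, float]
    uniform_z_mm: tuple[float, float]
    chamber_z_mm: tuple[float, float]
    chamber_centers_mm: dict[str, tuple[float, float]]
    body_radius_mm: float


def build_nu4_phantom(
    spec: PhantomSpec | None = None, grid: GridSpec | None = None
) -> tuple[ActivityMap, MuMap, RegionLabels, NU4Geometry]:
    """Voxelize the image-quality phantom onto a grid.

    Returns the activity map (Bq/mL), the 511 keV attenuation map,
    region labels, and the placement geometry used for VOI
    construction downstream.
    """
    spec = spec or PhantomSpec()
    grid = grid or GridSpec()

    r_body = spec.body_diameter_mm / 2.0
    fov_x = grid.nx * grid.dx
    fov_y = grid.ny * grid.dy
    if fov_x < spec.body_diameter_mm or fov_y < spec.body_diameter_mm:
        raise GeometryError(
            f"grid FOV {fov_x:.1f}x{fov_y:.1f} mm cannot contain the "
            f"{spec.body_diameter_mm:.1f} mm phantom body"
        )
    if grid.nz * grid.dz < spec.length_mm:
        raise GeometryError(
            f"grid z extent {grid.nz * grid.dz:.1f} mm cannot contain the "
            f"{spec.length_mm:.1f} mm phantom"
        )

    x = grid.axis_coords("x")[:, None, None]
    y = grid.axis_coords("y")[None, :, None]
    z = grid.axis_coords("z")[None, None, :]
    r2 = x**2 + y**2

    # In-plane coverage fractions (4x4 subsampling) and exact z-interval
    # overlaps give the activity map sub-voxel accuracy at region edges,
    # so the voxel sum conserves the analytic total well within 1%.
    # Labels and the mu-map use plain voxel-center membership.
    sub = (np.arange(4) - 1.5) / 4.0
    xs = grid.axis_coords("x")[:, None, None, None] + sub[None, None, :, None] * grid.dx
    ys = grid.axis_coords("y")[None, :, None, None] + sub[None, None, None, :] * grid.dy

    def disc_frac(cx: float, cy: float, radius: float) -> np.ndarray:
        inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2
        return inside.mean(axis=(2, 3))

    zc = grid.axis_coords("z")

    def z_frac(z_lo: float, z_hi: float) -> np.ndarray:
        lo = np.maximum(zc - grid.dz / 2.0, z_lo)
        hi = np.minimum(zc + grid.dz / 2.0, z_hi)
        return np.clip(hi - lo, 0.0, None) / grid.dz

    # phantom occupies z in [z0, z0 + length), centered on the grid
    z0 = -spec.length_mm / 2.0
    z_rod = (z0, z0 + spec.rod_region_length_mm)
    z_unif = (z_rod[1], z0 + spec.length_mm)
    z_cham = (z_unif[1] - spec.cold_chamber_length_mm, z_unif[1])

    in_body = r2 <= r_body**2
    in_rod_sec = in_body & (z >= z_rod[0]) & (z < z_rod[1])
    in_unif_sec = in_body & (z >= z_unif[0]) & (z < z_unif[1])

    labels = np.zeros(grid.shape, dtype=np.int8)
    labels[in_rod_sec] = LABEL_CODES["wall"]  # cold solid around the rods
    labels[in_unif_sec] = LABEL_CODES["uniform"]

    # rods, evenly spaced on a pitch circle
    rod_centers: dict[float, tuple[float, float]] = {}
    sub_res: list[float] = []
    n_rods = len(spec.rod_diameters_mm)
    for i, d in enumerate(spec.rod_diameters_mm):
        ang = np.pi / 2.0 + 2.0 * np.pi * i / n_rods
        cx = spec.rod_pitch_radius_mm * np.cos(ang)
        cy = spec.rod_pitch_radius_mm * np.sin(ang)
        rod_centers[d] = (float(cx), float(cy))
        in_rod = ((x - cx) ** 2 + (y - cy) ** 2 <= (d / 2.0) ** 2) & (
            (z >= z_rod[0]) & (z < z_rod[1])
        )
        labels[in_rod] = LABEL_CODES[f"rod_{i + 1}"]
        if d < 2.0 * min(grid.dx, grid.dy):
            sub_res.append(d)

    # cold chambers in the top of the uniform section
    off = spec.cold_chamber_offset_mm
    r_in = spec.cold_chamber_inner_mm / 2.0
    r_out = spec.cold_chamber_outer_mm / 2.0
    in_cham_z = (z >= z_cham[0]) & (z < z_cham[1])
    chamber_centers = {"air": (-off, 0.0), "water": (off, 0.0)}
    for name, (cx, cy) in chamber_centers.items():
        rr2 = (x - cx) ** 2 + (y - cy) ** 2
        labels[(rr2 <= r_out**2) & in_cham_z] = LABEL_CODES["wall"]
        labels[(rr2 <= r_in**2) & in_cham_z] = LABEL_CODES[f"cold_{name}"]

    conc = spec.activity_concentration()
    hot = np.isin(
        labels,
        [LABEL_CODES["uniform"]] + [LABEL_CODES[f"rod_{i + 1}"] for i in range(n_rods)],
    )
    # fractional-coverage activity: uniform section minus chamber
    # outer cylinders, plus the rods
    fill = disc_frac(0.0, 0.0, r_body)[:, :, None] * z_frac(*z_unif)[None, None, :]
    fill -= sum(
        disc_frac(cx, cy, r_out)[:, :, None] * z_frac(*z_cham)[None, None, :]
        for cx, cy in chamber_centers.values()
    )
    fill += sum(
        disc_frac(cx, cy, d / 2.0)[:, :, None] * z_frac(*z_rod)[None, None, :]
        for d, (cx, cy) in rod_centers.items()
    )
    activity = conc * np.clip(fill, 0.0, 1.0)

    mu = np.full(grid.shape, spec.mu_air_per_mm)
    mu[labels == LABEL_CODES["wall"]] = spec.mu_wall_per_mm
    mu[hot | (labels == LABEL_CODES["cold_water"])] = spec.mu_water_per_mm
    mu[labels == LABEL_CODES["cold_air"]] = spec.mu_air_per_mm

    geometry = NU4Geometry(
        rod_centers_mm=rod_centers,
        rod_z_mm=z_rod,
        uniform_z_mm=z_unif,
        chamber_z_mm=z_cham,
        chamber_centers_mm=chamber_centers,
        body_radius_mm=r_body,
    )
    return (
        ActivityMap(activity, grid),
        MuMap(mu, grid),
        RegionLabels(labels, grid, tuple(sub_res)),
        geometry,
    )


def tumor_volume_caliper(width_mm: float, length_mm: float) -> float:
    """Caliper tumor volume, mm^3: width^2 x length x 0.4."""
    if width_mm <= 0 or length_mm <= 0:
        raise ValueError("caliper dimensions must be positive")
    return width_mm**2 * length_mm * 0.4
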