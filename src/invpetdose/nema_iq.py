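"""NEMA NU4-2008 style image-quality metrics.

Three metrics, all invariant under global positive rescaling of the
image:

* non-uniformity NU = 100 x SD/mean over a 22.5 mm x 10 mm
  cylindrical VOI centered in the uniform region (population SD);
* recovery coefficient RC per rod = peak voxel value within a
  circular ROI of twice the rod diameter, on the axial average over
  the central 10 mm of the rod section, divided by the true
  concentration;
* spill-over ratio SOR = mean in a 4 mm x 7.5 mm VOI inside each
  cold chamber divided by the uniform-VOI mean (negatives from
  analytic reconstructions pass through unclamped).

VOI membership is by voxel-center inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import GridSpec, NU4Geometry


@dataclass(frozen=True)
class CylinderVOI:
    """Axis-aligned (z) cylinder in image coordinates (mm)."""

    center_mm: tuple[float, float, float]
    diameter_mm: float
    length_mm: float

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0 or self.length_mm <= 0:
            raise ValueError("VOI diameter and length must be positive")


def cylinder_voi_mask(grid: GridSpec, voi: CylinderVOI) -> np.ndarray:
    """Boolean voxel mask; a voxel belongs iff its center is inside."""
    cx, cy, cz = voi.center_mm
    r = voi.diameter_mm / 2.0
    if (
        abs(cx) + r > grid.nx * grid.dx / 2.0
        or abs(cy) + r > grid.ny * grid.dy / 2.0
        or abs(cz) + voi.length_mm / 2.0 > grid.nz * grid.dz / 2.0
    ):
        raise ValueError("VOI extends outside the grid")
    x = grid.axis_coords("x")[:, None, None]
    y = grid.axis_coords("y")[None, :, None]
    z = grid.axis_coords("z")[None, None, :]
    mask = ((x - cx) ** 2 + (y - cy) ** 2 <= r**2) & (
        np.abs(z - cz) <= voi.length_mm / 2.0
    )
    if not mask.any():
        raise ValueError("VOI mask is empty on this grid")
    return mask


@dataclass
class NUResult:
    mean: float
    sd: float
    percent_sd: float
    max: float
    min: float
    flagged: bool = False  # non-positive mean: %SD not meaningful


def non_uniformity(img: np.ndarray, voi_mask: np.ndarray) -> NUResult:
    """Percent SD (100 x SD/mean) over the VOI, population SD."""
    vals = np.asarray(img)[voi_mask]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    flagged = mean <= 0
    pct = 100.0 * sd / mean if not flagged else float("nan")
    return NUResult(mean, sd, pct, float(vals.max()), float(vals.min()), flagged)


def recovery_coefficients(
    img: np.ndarray,
    grid: GridSpec,
    rod_centers_mm: dict[float, tuple[float, float]],
    rod_z_mm: tuple[float, float],
    true_conc: float,
    min_rod_mm: float = 2.0,
    axial_extent_mm: float = 10.0,
) -> dict[float, float]:
    """RC per rod: ROI max of the axially averaged image / true value.

    Rods thinner than ``min_rod_mm`` are excluded (not discernible).
    The axial average covers the central ``axial_extent_mm`` of the
    rod section.
    """
    if true_conc <= 0:
        raise ValueError("true concentration must be positive")
    z = grid.axis_coords("z")
    z_mid = 0.5 * (rod_z_mm[0] + rod_z_mm[1])
    in_z = np.abs(z - z_mid) <= axial_extent_mm / 2.0
    if not in_z.any():
        raise ValueError("axial averaging window contains no slices")
    slab = np.asarray(img)[:, :, in_z].mean(axis=2)
    x = grid.axis_coords("x")[:, None]
    y = grid.axis_coords("y")[None, :]
    rc: dict[float, float] = {}
    for d, (cx, cy) in rod_centers_mm.items():
        if d < min_rod_mm:
            continue
        roi = (x - cx) ** 2 + (y - cy) ** 2 <= d**2  # ROI diameter = 2d
        if not roi.any():
            raise ValueError(f"empty ROI for {d} mm rod")
        rc[d] = float(slab[roi].max() / true_conc)
    return rc


def spill_over_ratio(
    img: np.ndarray,
    cold_voi_masks: dict[str, np.ndarray],
    uniform_voi_mask: np.ndarray,
) -> dict[str, float]:
    """SOR per chamber: cold-VOI mean / uniform-VOI mean, unclamped."""
    img = np.asarray(img)
    denom = float(img[uniform_voi_mask].mean())
    if denom <= 0:
        raise ValueError("uniform-region mean is not positive; SOR undefined")
    return {name: float(img[m].mean() / denom) for name, m in cold_voi_masks.items()}


@dataclass
class IQReport:
    """All image-quality metrics for one reconstruction configuration."""

    config_id: str
    correction_level: str  # partial | AC | AC_SC
    nu: NUResult
    rc: dict[float, float]
    sor: dict[str, float]

    def to_dict(self) -> dict:
        d = {
            "config_id": self.config_id,
            "correction_level": self.correction_level,
            "nu_percent_sd": self.nu.percent_sd,
            "nu_mean": self.nu.mean,
            "nu_max": self.nu.max,
            "nu_min": self.nu.min,
        }
        d.update({f"rc_{d_mm:g}mm": v for d_mm, v in self.rc.items()})
        d.update({f"sor_{k}": v for k, v in self.sor.items()})
        return d


def standard_vois(
    grid: GridSpec,
    geometry: NU4Geometry,
    uniform_diameter_mm: float = 22.5,
    uniform_length_mm: float = 10.0,
    sor_diameter_mm: float = 4.0,
    sor_length_mm: float = 7.5,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Uniform-region and cold-chamber VOI masks at NU4 placements.

    The uniform VOI is centered in the portion of the uniform
    section below the cold chambers; the SOR VOIs are centered in
    each chamber.
    """
    z_lo = geometry.uniform_z_mm[0]
    z_hi = geometry.chamber_z_mm[0]
    uniform_voi = CylinderVOI(
        center_mm=(0.0, 0.0, 0.5 * (z_lo + z_hi)),
        diameter_mm=uniform_diameter_mm,
        length_mm=uniform_length_mm,
    )
    z_cham = 0.5 * (geometry.chamber_z_mm[0] + geometry.chamber_z_mm[1])
    cold = {
        name: cylinder_voi_mask(
            grid,
            CylinderVOI(
                center_mm=(cx, cy, z_cham),
                diameter_mm=sor_diameter_mm,
                length_mm=sor_length_mm,
            ),
        )
        for name, (cx, cy) in geometry.chamber_centers_mm.items()
    }
    return cylinder_voi_mask(grid, uniform_voi), cold


def compute_iq_report(
    img: np.ndarray,
    grid: GridSpec,
    geometry: NU4Geometry,
    true_conc: float,
    config_id: str,
    correction_level: str = "partial",
) -> IQReport:
    """Full NU / RC / SOR evaluation with the standard VOI layout."""
    uniform_mask, cold_masks = standard_vois(grid, geometry)
    return IQReport(
        config_id=config_id,
        correction_level=correction_level,
        nu=non_uniformity(img, uniform_mask),
        rc=recovery_coefficients(
            img, grid, geometry.rod_centers_mm, geometry.rod_z_mm, true_conc
        ),
        sor=spill_over_ratio(img, cold_masks, uniform_mask),
    )
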