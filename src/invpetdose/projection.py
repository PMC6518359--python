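"""2D parallel-beam projection model.

A pixel-driven projector with linear bin interpolation; the
backprojector is its exact matrix adjoint, which keeps iterative
reconstruction (EM-type updates) consistent. Line integrals are in
mm x (image units): a ray through a uniform disc of radius R filled
at concentration c integrates to ~2Rc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter1d

from .phantom import ActivityMap, GridSpec, MuMap
from . import constants


@dataclass(frozen=True)
class ScanGeometry:
    """Parallel-beam sampling: angles over [0, 180) deg, bins across the FOV."""

    n_angles: int = 192
    n_bins: int = 128
    bin_width_mm: float = 0.776

    def __post_init__(self) -> None:
        if self.n_angles < 1 or self.n_bins < 1:
            raise ValueError("n_angles and n_bins must be >= 1")
        if self.bin_width_mm <= 0:
            raise ValueError("bin_width must be > 0")

    @property
    def angles_rad(self) -> np.ndarray:
        return np.arange(self.n_angles) * np.pi / self.n_angles

    @property
    def bin_centers_mm(self) -> np.ndarray:
        n = self.n_bins
        return (np.arange(n) - (n - 1) / 2.0) * self.bin_width_mm

    @classmethod
    def for_grid(cls, grid: GridSpec, n_angles: int = 192) -> "ScanGeometry":
        """Geometry matched to a grid: bin width = in-plane voxel size."""
        return cls(n_angles=n_angles, n_bins=grid.nx, bin_width_mm=grid.dx)


@dataclass
class Sinogram:
    """Projection data, last two axes (angle, bin).

    A leading axis, when present, indexes image slices. ``meta``
    carries provenance such as the counts-per-line-integral scale
    set by :func:`sample_counts`.
    """

    data: np.ndarray
    geometry: ScanGeometry
    slice_index: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[-2:] != (self.geometry.n_angles, self.geometry.n_bins):
            raise ValueError("sinogram shape does not match geometry")

    def copy_with(self, data: np.ndarray) -> "Sinogram":
        return Sinogram(data, self.geometry, self.slice_index, dict(self.meta))


class ParallelProjector:
    """Sparse system matrix for one in-plane grid + scan geometry.

    ``forward`` maps images (ny*nx flattened, or (..., nx, ny)) to
    sinograms; ``back`` applies the exact transpose.
    """

    def __init__(self, grid: GridSpec, geom: ScanGeometry):
        self.grid = grid
        self.geom = geom
        self.matrix = self._build_matrix()

    def _build_matrix(self) -> sparse.csr_matrix:
        g, geom = self.grid, self.geom
        x = g.axis_coords("x")[:, None]
        y = g.axis_coords("y")[None, :]
        n_pix = g.nx * g.ny
        db = geom.bin_width_mm
        t0 = geom.bin_centers_mm[0]
        rows, cols, vals = [], [], []
        pix_idx = np.arange(n_pix)
        for a, ang in enumerate(geom.angles_rad):
            t = (x * np.cos(ang) + y * np.sin(ang)).ravel()
            s = (t - t0) / db
            i0 = np.floor(s).astype(int)
            w1 = s - i0
            for ib, w in ((i0, 1.0 - w1), (i0 + 1, w1)):
                ok = (ib >= 0) & (ib < geom.n_bins) & (w > 0)
                rows.append(a * geom.n_bins + ib[ok])
                cols.append(pix_idx[ok])
                # dx is the integration step along the ray
                vals.append(w[ok] * g.dx)
        mat = sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(geom.n_angles * geom.n_bins, n_pix),
        )
        return mat

    def forward(self, images: np.ndarray) -> np.ndarray:
        """(..., nx, ny) images -> (..., n_angles, n_bins) sinograms."""
        imgs = np.asarray(images, dtype=float)
        lead = imgs.shape[:-2]
        flat = imgs.reshape(-1, self.grid.nx * self.grid.ny).T
        sino = (self.matrix @ flat).T
        return sino.reshape(*lead, self.geom.n_angles, self.geom.n_bins)

    def back(self, sinos: np.ndarray) -> np.ndarray:
        """Exact adjoint of :meth:`forward`."""
        s = np.asarray(sinos, dtype=float)
        lead = s.shape[:-2]
        flat = s.reshape(-1, self.geom.n_angles * self.geom.n_bins).T
        imgs = (self.matrix.T @ flat).T
        return imgs.reshape(*lead, self.grid.nx, self.grid.ny)


_projector_cache: dict[tuple, ParallelProjector] = {}


def get_projector(grid: GridSpec, geom: ScanGeometry) -> ParallelProjector:
    """Build (or reuse) the projector for a grid/geometry pair."""
    key = (grid.nx, grid.ny, grid.dx, grid.dy, geom)
    if key not in _projector_cache:
        _projector_cache[key] = ParallelProjector(grid, geom)
    return _projector_cache[key]


def forward_project(
    amap: ActivityMap, geom: ScanGeometry, slices: slice | list | None = None
) -> Sinogram:
    """Line-integral projection of an activity volume, slice by slice."""
    proj = get_projector(amap.grid, geom)
    vol = amap.values
    if slices is not None:
        vol = vol[:, :, slices]
    # (nz, nx, ny) stacks for the projector
    imgs = np.moveaxis(vol, 2, 0)
    return Sinogram(proj.forward(imgs), geom)


def attenuation_factors(mu: MuMap, geom: ScanGeometry, slices=None) -> Sinogram:
    """Per-bin survival factors exp(-integral mu dl), in (0, 1]."""
    line_int = forward_project(ActivityMap(mu.values, mu.grid), geom, slices)
    return line_int.copy_with(np.exp(-line_int.data))


def apply_attenuation(sino: Sinogram, mu: MuMap, slices=None) -> Sinogram:
    """Attenuate expected counts by exp(-integral mu dl) per ray."""
    if np.any(mu.values < 0):
        raise ValueError("mu must be non-negative")
    fac = attenuation_factors(mu, sino.geometry, slices)
    if fac.data.shape != sino.data.shape:
        raise ValueError("mu-map slices do not match sinogram stack")
    return sino.copy_with(sino.data * fac.data)


def add_scatter(
    sino: Sinogram, scatter_fraction: float, kernel_fwhm_mm: float = 20.0
) -> tuple[Sinogram, Sinogram]:
    """Add a smooth scatter background along the radial bins.

    The scatter estimate is the true sinogram convolved with a broad
    Gaussian, scaled so that scatter/(trues+scatter) equals
    ``scatter_fraction`` exactly in total counts. Both the
    contaminated sinogram and the scatter term are returned so a
    correction step can be exercised against the known truth.
    """
    if not 0 <= scatter_fraction < 1:
        raise ValueError("scatter_fraction must be in [0, 1)")
    if scatter_fraction == 0:
        return sino, sino.copy_with(np.zeros_like(sino.data))
    sigma_bins = kernel_fwhm_mm / constants.FWHM_TO_SIGMA / sino.geometry.bin_width_mm
    smooth = gaussian_filter1d(sino.data, sigma_bins, axis=-1, mode="constant")
    total = sino.data.sum()
    target = scatter_fraction / (1.0 - scatter_fraction) * total
    scatter = smooth * (target / smooth.sum()) if smooth.sum() > 0 else smooth
    return sino.copy_with(sino.data + scatter), sino.copy_with(scatter)


def sample_counts(
    sino: Sinogram, target_total_counts: float, seed: int | np.random.Generator
) -> Sinogram:
    """Poisson-sample a noisy sinogram at a prescribed total count level.

    The expectation is scaled so its total equals
    ``target_total_counts``; the applied counts-per-line-integral
    scale is recorded in ``meta['counts_scale']`` so reconstructions
    can be calibrated back to Bq/mL.
    """
    if np.any(sino.data < 0):
        raise ValueError("expected sinogram must be non-negative")
    total = sino.data.sum()
    if target_total_counts <= 0 or total <= 0:
        raise ValueError("target and expected totals must be positive")
    rng = np.random.default_rng(seed)
    scale = target_total_counts / total
    out = sino.copy_with(rng.poisson(sino.data * scale).astype(float))
    out.meta["counts_scale"] = scale * sino.meta.get("counts_scale", 1.0)
    return out
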