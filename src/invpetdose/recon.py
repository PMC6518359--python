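"""2D reconstruction: FBP with apodized ramp filters, OSEM, MAP-EM.

FBP filters each projection in the frequency domain with the ramp
|f| tapered by a named apodization window, then backprojects; the
output may legitimately contain negative values in cold regions.
OSEM/MAP-EM use multiplicative EM updates with attenuation in the
system model and the scatter estimate as an additive background, so
their output is non-negative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from . import constants
from .phantom import GridSpec
from .projection import ScanGeometry, Sinogram, get_projector

FBP_WINDOWS = ("ramp", "butterworth", "hamming", "hanning", "parzen", "shepp_logan")


@dataclass(frozen=True)
class ReconConfig:
    """One reconstruction configuration (algorithm + parameters)."""

    algorithm: str = "OSEM"  # FBP | OSEM | MAPEM
    filter_name: str = "ramp"  # FBP only
    cutoff: float = 0.5  # fraction of Nyquist
    butterworth_order: int = 4
    n_subsets: int = 16
    n_iterations: int = 1
    beta: float = 0.0  # MAPEM smoothing strength
    post_filter_fwhm_mm: float = 0.0
    corrections: frozenset = frozenset()  # subset of {"AC", "SC"}

    def __post_init__(self) -> None:
        if self.algorithm not in ("FBP", "OSEM", "MAPEM"):
            raise ValueError(f"unknown algorithm: {self.algorithm}")
        if self.algorithm == "FBP" and self.filter_name not in FBP_WINDOWS:
            raise ValueError(f"unknown FBP window: {self.filter_name}")
        if not 0 < self.cutoff <= 1:
            raise ValueError("cutoff must be in (0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not self.corrections <= {"AC", "SC"}:
            raise ValueError("corrections must be a subset of {AC, SC}")

    @property
    def config_id(self) -> str:
        if self.algorithm == "FBP":
            base = f"fbp_{self.filter_name}"
        elif self.algorithm == "OSEM":
            base = f"osem2d_iter{self.n_iterations}"
        else:
            base = f"mapem_beta{self.beta:g}"
        if self.post_filter_fwhm_mm:
            base += f"_g{self.post_filter_fwhm_mm:g}mm"
        return base


def apodization_window(
    name: str,
    cutoff: float,
    freqs: int | np.ndarray,
    butterworth_order: int = 4,
) -> np.ndarray:
    """Ramp filter |f| tapered by a named window.

    ``freqs`` is either an array of frequencies in cycles/sample
    (0..0.5) or a count n, in which case n evenly spaced frequencies
    over [0, 0.5] are used. The cutoff f_c = cutoff x Nyquist; all
    windows (including Butterworth) are truncated to zero above f_c.

    Window shapes for u = f/f_c in [0, 1]:
      ramp         1
      hanning      0.5 (1 + cos(pi u))
      hamming      0.54 + 0.46 cos(pi u)
      parzen       cubic B-spline: 1 - 6u^2(1-u) for u <= 1/2, 2(1-u)^3 above
      shepp_logan  sinc(u/2)
      butterworth  1/sqrt(1 + u^(2n)), order n
    """
    if name not in FBP_WINDOWS:
        raise ValueError(f"unknown window: {name}")
    if np.isscalar(freqs):
        f = np.linspace(0.0, 0.5, int(freqs))
    else:
        f = np.asarray(freqs, dtype=float)
    fc = cutoff * 0.5
    u = np.minimum(np.abs(f) / fc, 1.0)
    if name == "ramp":
        w = np.ones_like(u)
    elif name == "hanning":
        w = 0.5 * (1.0 + np.cos(np.pi * u))
    elif name == "hamming":
        w = 0.54 + 0.46 * np.cos(np.pi * u)
    elif name == "parzen":
        w = np.where(u <= 0.5, 1.0 - 6.0 * u**2 * (1.0 - u), 2.0 * (1.0 - u) ** 3)
    elif name == "shepp_logan":
        w = np.sinc(u / 2.0)
    else:  # butterworth
        w = 1.0 / np.sqrt(1.0 + u ** (2 * butterworth_order))
    weights = np.abs(f) * w
    weights[np.abs(f) > fc] = 0.0
    return weights


def fbp2d(
    sino: Sinogram,
    grid: GridSpec,
    filter_name: str = "ramp",
    cutoff: float = 0.5,
    butterworth_order: int = 4,
) -> np.ndarray:
    """Filtered backprojection of (stacks of) 2D sinograms.

    Returns images shaped like the sinogram's leading axes plus
    (nx, ny). Projections are zero-padded to >= 4x the bin count
    (next power of two) before frequency filtering: the padding
    suppresses circular-convolution wraparound and shrinks the DC
    bias of the discretized ramp.
    """
    geom = sino.geometry
    proj = get_projector(grid, geom)
    n = geom.n_bins
    n_pad = int(2 ** np.ceil(np.log2(4 * n)))
    f = np.fft.rfftfreq(n_pad)  # cycles per sample
    weights = apodization_window(filter_name, cutoff, f, butterworth_order)
    spec = np.fft.rfft(sino.data, n=n_pad, axis=-1)
    filtered = np.fft.irfft(spec * weights, n=n_pad, axis=-1)[..., :n]
    # discretization: |nu| = f/dt, integration measures d nu and d theta
    dt = geom.bin_width_mm
    img = proj.back(filtered) * np.pi / geom.n_angles / dt**2
    return img


def _subset_rows(geom: ScanGeometry, n_subsets: int) -> list[np.ndarray]:
    """Round-robin angle subsets (angle i -> subset i mod n_subsets)."""
    if geom.n_angles % n_subsets != 0:
        raise ValueError("n_subsets must divide n_angles")
    rows = []
    for s in range(n_subsets):
        angles = np.arange(s, geom.n_angles, n_subsets)
        rows.append(
            (angles[:, None] * geom.n_bins + np.arange(geom.n_bins)[None, :]).ravel()
        )
    return rows


def _em_iterations(
    sino: Sinogram,
    grid: GridSpec,
    n_subsets: int,
    n_iterations: int,
    acf: np.ndarray | None,
    scatter_estimate: np.ndarray | None,
    beta: float,
    return_iterates: bool = False,
) -> np.ndarray | list[np.ndarray]:
    """Shared OSEM / one-step-late MAP-EM engine.

    Forward model per subset: ybar = atten * (A x) + scatter, with
    atten = 1/ACF. The one-step-late quadratic prior adds
    beta * dU(x) (8-neighborhood) to the sensitivity denominator.
    """
    geom = sino.geometry
    proj = get_projector(grid, geom)
    A = proj.matrix
    counts = sino.data
    if np.any(counts < 0):
        raise ValueError("EM reconstruction requires non-negative counts")
    lead = counts.shape[:-2]
    y = counts.reshape(-1, geom.n_angles * geom.n_bins).T  # (rays, nslices)
    nslc = y.shape[1]
    atten = None
    if acf is not None:
        acf_flat = np.asarray(acf, dtype=float).reshape(-1, y.shape[0]).T
        if acf_flat.shape != y.shape and acf_flat.shape[1] == 1:
            acf_flat = np.broadcast_to(acf_flat, y.shape)
        atten = 1.0 / acf_flat
    bg = None
    if scatter_estimate is not None:
        bg = np.asarray(scatter_estimate, dtype=float).reshape(-1, y.shape[0]).T
    subsets = _subset_rows(geom, n_subsets)
    x = np.ones((grid.nx * grid.ny, nslc))
    eps = 1e-12
    iterates: list[np.ndarray] = []
    for _ in range(n_iterations):
        for rows in subsets:
            A_s = A[rows]
            a_s = atten[rows] if atten is not None else 1.0
            ybar = a_s * (A_s @ x)
            if bg is not None:
                ybar = ybar + bg[rows]
            ratio = np.where(ybar > eps, y[rows] / np.maximum(ybar, eps), 0.0)
            back = A_s.T @ (a_s * ratio if atten is not None else ratio)
            if atten is not None:
                sens = A_s.T @ a_s
            else:
                sens = np.broadcast_to(
                    np.asarray(A_s.sum(axis=0)).ravel()[:, None], back.shape
                )
            denom = np.array(sens, dtype=float, copy=True)
            if beta > 0:
                penalty = _quadratic_prior_gradient(
                    x.reshape(grid.nx, grid.ny, nslc)
                ).reshape(-1, nslc)
                denom = denom + beta * penalty
            upd = np.where(denom > eps, back / np.maximum(denom, eps), 0.0)
            x = x * upd
            if not np.all(np.isfinite(x)):
                raise FloatingPointError("EM update diverged (non-finite voxels)")
        if return_iterates:
            iterates.append(x.T.reshape(*lead, grid.nx, grid.ny))
    if return_iterates:
        return iterates
    return x.T.reshape(*lead, grid.nx, grid.ny)


_NEIGHBOR_OFFSETS = [
    (di, dj, 1.0 if di == 0 or dj == 0 else 1.0 / np.sqrt(2.0))
    for di in (-1, 0, 1)
    for dj in (-1, 0, 1)
    if (di, dj) != (0, 0)
]


def _quadratic_prior_gradient(x: np.ndarray) -> np.ndarray:
    """dU/dx for U = 1/2 sum_j w_jk (x_j - x_k)^2 over the 8-neighborhood."""
    grad = np.zeros_like(x)
    for di, dj, w in _NEIGHBOR_OFFSETS:
        shifted = np.roll(np.roll(x, di, axis=0), dj, axis=1)
        grad += w * (x - shifted)
    return grad


def osem2d(
    sino: Sinogram,
    grid: GridSpec,
    n_subsets: int = 16,
    n_iterations: int = 1,
    acf: np.ndarray | Sinogram | None = None,
    scatter_estimate: np.ndarray | Sinogram | None = None,
    return_iterates: bool = False,
) -> np.ndarray | list[np.ndarray]:
    """Ordered-subset EM; with one subset this is plain MLEM.

    With ``return_iterates`` the image after every full iteration is
    returned (one OSEM run scores all iteration numbers at once).
    """
    acf_arr = acf.data if isinstance(acf, Sinogram) else acf
    sc_arr = (
        scatter_estimate.data
        if isinstance(scatter_estimate, Sinogram)
        else scatter_estimate
    )
    return _em_iterations(
        sino, grid, n_subsets, n_iterations, acf_arr, sc_arr, 0.0, return_iterates
    )


def mapem2d(
    sino: Sinogram,
    grid: GridSpec,
    beta: float,
    n_iterations: int = 18,
    acf: np.ndarray | Sinogram | None = None,
    scatter_estimate: np.ndarray | Sinogram | None = None,
) -> np.ndarray:
    """One-step-late MAP-EM with a quadratic 8-neighborhood prior.

    beta = 0 reduces exactly to MLEM; larger beta smooths more and
    lowers small-structure peak values.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    acf_arr = acf.data if isinstance(acf, Sinogram) else acf
    sc_arr = (
        scatter_estimate.data
        if isinstance(scatter_estimate, Sinogram)
        else scatter_estimate
    )
    return _em_iterations(sino, grid, 1, n_iterations, acf_arr, sc_arr, beta)


def gaussian_postfilter(
    img: np.ndarray, fwhm_mm: float, voxel_mm: tuple[float, ...] | float
) -> np.ndarray:
    """Separable Gaussian smoothing with the stated FWHM in mm.

    Reflective boundaries preserve the image total for the symmetric
    kernel. ``voxel_mm`` gives the spacing along each smoothed axis
    (last axes of ``img``); leading axes are left untouched.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return np.asarray(img, dtype=float).copy()
    img = np.asarray(img, dtype=float)
    if np.isscalar(voxel_mm):
        voxel_mm = (voxel_mm, voxel_mm)
    sigmas = [0.0] * (img.ndim - len(voxel_mm)) + [
        fwhm_mm / constants.FWHM_TO_SIGMA / v for v in voxel_mm
    ]
    return gaussian_filter(img, sigma=sigmas, mode="reflect")


def attenuation_correction_factors(mu, geom: ScanGeometry, slices=None) -> Sinogram:
    """ACF = exp(+integral mu dl) per ray; >= 1 everywhere."""
    from .projection import attenuation_factors

    fac = attenuation_factors(mu, geom, slices)
    return fac.copy_with(1.0 / fac.data)


def scatter_correct(
    sino: Sinogram, scatter_estimate: Sinogram | np.ndarray, clamp: bool = False
) -> Sinogram:
    """Subtract a scatter estimate; optionally clamp at zero.

    FBP input tolerates (and needs) negatives, EM input should be
    clamped.
    """
    est = scatter_estimate.data if isinstance(scatter_estimate, Sinogram) else np.asarray(scatter_estimate)
    if est.shape != sino.data.shape:
        raise ValueError("scatter estimate shape mismatch")
    out = sino.data - est
    if clamp:
        out = np.maximum(out, 0.0)
    return sino.copy_with(out)


def calibrate_to_concentration(
    img: np.ndarray, calibration_factor: float
) -> np.ndarray:
    """Scale reconstructed counts to Bq/mL (factor from the count model)."""
    if calibration_factor <= 0:
        raise ValueError("calibration factor must be positive")
    return np.asarray(img, dtype=float) * calibration_factor


def reconstruct(
    sino: Sinogram,
    grid: GridSpec,
    config: ReconConfig,
    acf: Sinogram | None = None,
    scatter_estimate: Sinogram | None = None,
    calibration_factor: float = 1.0,
) -> np.ndarray:
    """Run one full configuration: algorithm, corrections, post-filter.

    For FBP the corrections are applied to the sinogram (ACF
    multiplication, scatter subtraction without clamping); for
    EM algorithms they enter the forward model.
    """
    use_ac = "AC" in config.corrections and acf is not None
    use_sc = "SC" in config.corrections and scatter_estimate is not None
    if config.algorithm == "FBP":
        data = sino
        if use_sc:
            data = scatter_correct(data, scatter_estimate, clamp=False)
        if use_ac:
            data = data.copy_with(data.data * acf.data)
        img = fbp2d(
            data, grid, config.filter_name, config.cutoff, config.butterworth_order
        )
    elif config.algorithm == "OSEM":
        img = osem2d(
            sino,
            grid,
            config.n_subsets,
            config.n_iterations,
            acf=acf if use_ac else None,
            scatter_estimate=scatter_estimate if use_sc else None,
        )
    else:
        img = mapem2d(
            sino,
            grid,
            config.beta,
            config.n_iterations,
            acf=acf if use_ac else None,
            scatter_estimate=scatter_estimate if use_sc else None,
        )
    img = calibrate_to_concentration(img, calibration_factor)
    if config.post_filter_fwhm_mm:
        img = gaussian_postfilter(img, config.post_filter_fwhm_mm, (grid.dx, grid.dy))
    return img
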