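"""MIRD-style internal dosimetry chain.

From a region time-activity curve (TAC) the chain runs:
decay-uncorrected TAC -> cumulated activity (trapezoidal AUC with a
physical-decay tail) -> residence time tau = A_cum / A0 -> absorbed
dose via sphere-model S-values (tumor) or an organ S-factor matrix
(effective dose). Sphere S-values are interpolated in mass with a
power-law fit S(m) = a m^b rather than linearly, because linear
interpolation overestimates S between the tabulated masses of a
convex decreasing table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants


@dataclass
class TimeActivityCurve:
    """Region activity vs time.

    ``values`` are %ID/g by convention (``units`` records it);
    ``decay_corrected`` must be False before integration to
    cumulated activity.
    """

    region: str
    times_h: np.ndarray
    values: np.ndarray
    decay_corrected: bool
    injected_activity_MBq: float
    units: str = "%ID/g"

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_h.ndim != 1 or self.times_h.shape != self.values.shape:
            raise ValueError("times and values must be matching 1D arrays")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TAC values must be finite")
        if self.injected_activity_MBq <= 0:
            raise ValueError("injected activity must be positive")


@dataclass(frozen=True)
class ROISpec:
    """Named planar ROI, either an explicit mask or a circle of given area."""

    region: str
    mask: np.ndarray | None = None
    area_cm2: float | None = None

    def __post_init__(self) -> None:
        if self.mask is None and self.area_cm2 is None:
            raise ValueError("ROISpec needs a mask or an area")
        if self.area_cm2 is not None and not 0 < self.area_cm2 < 1.0:
            raise ValueError("ROI area out of plausible bounds")


def roi_max_concentration(img: np.ndarray, roi: ROISpec) -> tuple[float, tuple]:
    """Maximum voxel value in the ROI and its position."""
    img = np.asarray(img)
    if roi.mask is None:
        raise ValueError("roi_max_concentration requires an explicit mask")
    if roi.mask.shape != img.shape:
        raise ValueError("ROI mask shape does not match image")
    if not roi.mask.any():
        raise ValueError("ROI is empty")
    vals = np.where(roi.mask, img, -np.inf)
    pos = np.unravel_index(int(np.argmax(vals)), img.shape)
    return float(img[pos]), pos


def percent_id_per_gram(
    conc_Bq_per_mL: float, injected_Bq: float, density_g_per_mL: float = 1.0
) -> float:
    """%ID/g from a concentration, assuming unit tissue density by default."""
    if injected_Bq <= 0:
        raise ValueError("injected activity must be positive")
    return 100.0 * conc_Bq_per_mL / (injected_Bq * density_g_per_mL)


def decay_uncorrect(
    tac: TimeActivityCurve, lambda_phys: float = constants.CU64_LAMBDA_PER_H
) -> TimeActivityCurve:
    """Re-impose physical decay on a decay-corrected TAC."""
    if not tac.decay_corrected:
        raise ValueError("TAC is already decay-uncorrected")
    return TimeActivityCurve(
        tac.region,
        tac.times_h,
        tac.values * np.exp(-lambda_phys * tac.times_h),
        decay_corrected=False,
        injected_activity_MBq=tac.injected_activity_MBq,
        units=tac.units,
    )


def decay_correct(
    tac: TimeActivityCurve, lambda_phys: float = constants.CU64_LAMBDA_PER_H
) -> TimeActivityCurve:
    """Remove physical decay (inverse of :func:`decay_uncorrect`)."""
    if tac.decay_corrected:
        raise ValueError("TAC is already decay-corrected")
    return TimeActivityCurve(
        tac.region,
        tac.times_h,
        tac.values * np.exp(lambda_phys * tac.times_h),
        decay_corrected=True,
        injected_activity_MBq=tac.injected_activity_MBq,
        units=tac.units,
    )


def cumulated_activity(
    tac: TimeActivityCurve, lambda_phys: float = constants.CU64_LAMBDA_PER_H
) -> float:
    """Area under a decay-uncorrected TAC, in (value units) x h.

    Conventions: the value is held constant from t = 0 back to the
    first sample; trapezoidal integration across the samples; after
    the last sample a pure physical-decay tail A(t_last)/lambda (no
    further biological clearance, a conservative default).
    """
    if tac.decay_corrected:
        raise ValueError("cumulated activity requires a decay-uncorrected TAC")
    if tac.times_h.size < 2:
        raise ValueError("need at least two time points")
    if np.any(tac.values < 0):
        raise ValueError("negative activity values")
    head = tac.values[0] * tac.times_h[0]
    body = float(np.trapezoid(tac.values, tac.times_h))
    tail = tac.values[-1] / lambda_phys
    return float(head + body + tail)


def residence_time(cumulated_MBq_h: float, injected_MBq: float) -> float:
    """tau = A_cum / A0, in hours."""
    if injected_MBq <= 0:
        raise ValueError("injected activity must be positive")
    return cumulated_MBq_h / injected_MBq


def residence_time_from_tac(
    tac: TimeActivityCurve,
    region_mass_g: float,
    lambda_phys: float = constants.CU64_LAMBDA_PER_H,
) -> float:
    """Residence time from a %ID/g TAC and the region mass.

    %ID/g x mass / 100 is the fraction of the injected activity in
    the region, so the AUC of that fraction is tau directly.
    """
    if tac.units != "%ID/g":
        raise ValueError("expected a %ID/g TAC")
    auc = cumulated_activity(tac, lambda_phys)  # (%ID/g) x h
    return auc * region_mass_g / 100.0


@dataclass
class ResidenceTimeSet:
    """Residence times (h) per source region."""

    taus_h: dict[str, float]
    injected_MBq: float

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.taus_h.values()):
            raise ValueError("residence times must be non-negative")
        bound = 1.0 / constants.CU64_LAMBDA_PER_H
        if sum(self.taus_h.values()) > bound * (1 + 1e-9):
            raise ValueError(
                "summed residence times exceed the physical bound 1/lambda"
            )


@dataclass
class SphereSValueTable:
    """Tabulated sphere self-dose S-values, mGy/(MBq h), vs mass (g)."""

    masses_g: np.ndarray
    s_values: np.ndarray
    nuclide: str = "Cu-64"

    def __post_init__(self) -> None:
        self.masses_g = np.asarray(self.masses_g, dtype=float)
        self.s_values = np.asarray(self.s_values, dtype=float)
        if self.masses_g.ndim != 1 or self.masses_g.shape != self.s_values.shape:
            raise ValueError("masses and S-values must be matching 1D arrays")
        if np.any(np.diff(self.masses_g) <= 0):
            raise ValueError("masses must be strictly increasing")
        if np.any(np.diff(self.s_values) >= 0):
            raise ValueError("S-values must be strictly decreasing in mass")

    @classmethod
    def from_csv(cls, path) -> "SphereSValueTable":
        df = pd.read_csv(path)
        return cls(df["mass_g"].to_numpy(), df["s_mGy_per_MBq_h"].to_numpy())


@dataclass(frozen=True)
class PowerLawS:
    """S(m) = a m^b with fit diagnostics."""

    a: float
    b: float
    r_squared: float
    mass_range_g: tuple[float, float]

    def __call__(self, mass_g: float) -> float:
        return self.a * mass_g**self.b


def fit_sphere_svalue(table: SphereSValueTable) -> PowerLawS:
    """Least-squares power-law fit of log S on log m."""
    if table.masses_g.size < 3:
        raise ValueError("need at least three table points for a fit")
    logm = np.log(table.masses_g)
    logs = np.log(table.s_values)
    (b, loga), res = np.polyfit(logm, logs, 1, full=True)[:2]
    ss_tot = float(np.sum((logs - logs.mean()) ** 2))
    ss_res = float(res[0]) if res.size else 0.0
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawS(
        a=float(np.exp(loga)),
        b=float(b),
        r_squared=r2,
        mass_range_g=(float(table.masses_g[0]), float(table.masses_g[-1])),
    )


def tumor_absorbed_dose(
    tau_h: float, mass_g: float, table: SphereSValueTable
) -> tuple[float, bool]:
    """Tumor dose per injected MBq: tau x S(mass), mGy/MBq.

    Returns ``(dose, extrapolated)``; ``extrapolated`` flags a mass
    outside the tabulated hull.
    """
    if mass_g <= 0:
        raise ValueError("mass must be positive")
    fit = fit_sphere_svalue(table)
    lo, hi = fit.mass_range_g
    return tau_h * fit(mass_g), not (lo <= mass_g <= hi)


@dataclass
class OrganSMatrix:
    """Target x source S-factors (mGy/(MBq h)) with tissue weights."""

    s: pd.DataFrame  # index: target organs, columns: source organs
    organ_masses_g: dict[str, float]
    tissue_weights: dict[str, float]

    def __post_init__(self) -> None:
        w = sum(self.tissue_weights.values())
        if abs(w - 1.0) > 1e-6:
            raise ValueError(f"tissue weighting factors sum to {w}, expected 1")
        diag_ok = all(
            self.s.loc[t, t] >= self.s.loc[t].drop(t).max()
            for t in self.s.index
            if t in self.s.columns
        )
        if not diag_ok:
            raise ValueError("self-dose must dominate each target row")

    @classmethod
    def from_csv(cls, s_path, weights_path=None) -> "OrganSMatrix":
        df = pd.read_csv(s_path, index_col=0)
        masses = df.pop("mass_g").to_dict() if "mass_g" in df.columns else {}
        weights = df.pop("tissue_weight").to_dict() if "tissue_weight" in df.columns else {}
        return cls(df, masses, weights)


@dataclass
class DoseReport:
    """Per-target doses (mSv/MBq), effective dose, and provenance."""

    organ_doses: dict[str, float]
    effective_dose_mSv_per_MBq: float
    tumor_dose_mGy_per_MBq: float | None = None
    provenance: dict = field(default_factory=dict)


def organ_dose(res: ResidenceTimeSet, smat: OrganSMatrix) -> DoseReport:
    """Dose per target = sum over sources of tau_s x S(target<-source)."""
    missing = [s for s in res.taus_h if s not in smat.s.columns]
    if missing:
        raise KeyError(f"source regions missing from S matrix: {missing}")
    doses: dict[str, float] = {}
    for target in smat.s.index:
        doses[target] = float(
            sum(tau * smat.s.loc[target, src] for src, tau in res.taus_h.items())
        )
    eff = float(
        sum(smat.tissue_weights.get(t, 0.0) * d for t, d in doses.items())
    )
    return DoseReport(
        organ_doses=doses,
        effective_dose_mSv_per_MBq=eff,
        provenance={"n_sources": len(res.taus_h)},
    )


def scale_mouse_to_human(
    res_mouse: ResidenceTimeSet,
    mouse_masses_g: dict[str, float],
    human_masses_g: dict[str, float],
    mouse_body_g: float = 25.0,
    human_body_g: float = 73000.0,
    strategy: str = "relative-organ-mass",
) -> ResidenceTimeSet:
    """Scale mouse residence times to a human phantom.

    Default strategy multiplies each tau by the ratio of relative
    organ masses, tau_h = tau_m x (m_organ_h/M_h)/(m_organ_m/M_m);
    the whole-body region is left unchanged under this rule.
    """
    if strategy != "relative-organ-mass":
        raise ValueError(f"unknown scaling strategy: {strategy}")
    missing = [
        r
        for r in res_mouse.taus_h
        if r not in mouse_masses_g or r not in human_masses_g
    ]
    if missing:
        raise KeyError(f"missing mass entries for regions: {missing}")
    scaled = {
        r: tau
        * (human_masses_g[r] / human_body_g)
        / (mouse_masses_g[r] / mouse_body_g)
        for r, tau in res_mouse.taus_h.items()
    }
    return ResidenceTimeSet(scaled, res_mouse.injected_MBq)
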