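"""Dose-table comparison engine.

Dose estimates obtained under different reconstruction
configurations are compared against a gold-standard column with the
symmetric percent difference

    pd(x, ref) = 200 (x - ref) / (x + ref)

which is antisymmetric, bounded in (-200, 200) for positive inputs,
and strictly increasing in x. Published comparison tables render it
rounded half-away-from-zero to one decimal; internal values keep
full precision.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

#: reconstruction-configuration column order of the packaged dose table
DOSE_TABLE_COLUMNS = [
    "fbp_ramp",
    "fbp_butterworth",
    "fbp_hamming",
    "fbp_hanning",
    "fbp_parzen",
    "fbp_3drp",
    "osem2d_iter1",
    "osem2d_iter2",
    "osem2d_iter3",
    "osem2d_iter4",
    "osem2d_iter5",
    "osem2d_iter6",
    "osem2d_iter7",
    "osem2d_iter8",
    "osem2d_iter9",
    "osem2d_iter10",
    "mapem_beta0.1",
    "mapem_beta1.0",
    "mapem_beta1.5",
]

GOLD_STANDARD_COLUMN = "osem2d_iter1"


def percent_difference(x, ref):
    """Symmetric percent difference 200 (x - ref)/(x + ref)."""
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    denom = x + ref
    if np.any(denom == 0):
        raise ZeroDivisionError("percent difference undefined when x + ref = 0")
    out = 200.0 * (x - ref) / denom
    return float(out) if out.ndim == 0 else out


def round_half_away(values, decimals: int = 1):
    """Round half away from zero (matches printed table style)."""
    v = np.asarray(values, dtype=float)
    scale = 10.0**decimals
    out = np.sign(v) * np.floor(np.abs(v) * scale + 0.5) / scale
    return float(out) if out.ndim == 0 else out


def compare_to_reference(
    table: pd.DataFrame, ref_column: str = GOLD_STANDARD_COLUMN
) -> pd.DataFrame:
    """Elementwise percent difference of every column vs the reference.

    The reference column is kept (identically zero) so the result is
    shaped like the input; rounding is left to the caller/renderer.
    """
    if ref_column not in table.columns:
        raise KeyError(f"reference column {ref_column!r} not in table")
    ref = table[ref_column]
    out = 200.0 * table.sub(ref, axis=0).div(table.add(ref, axis=0))
    return out


def range_spread(series) -> dict[str, float]:
    """min, max, and relative spread 100 (max - min)/min of a series."""
    v = np.asarray(series, dtype=float)
    if v.size == 0:
        raise ValueError("empty series")
    if np.any(v <= 0):
        raise ValueError("range_spread requires positive values")
    lo, hi = float(v.min()), float(v.max())
    return {"min": lo, "max": hi, "rel_spread_percent": 100.0 * (hi - lo) / lo}


def normalize_by_max(series):
    """Divide by the maximum; the largest element maps to 1."""
    v = np.asarray(series, dtype=float)
    m = v.max()
    if m <= 0:
        raise ValueError("normalization requires a positive maximum")
    return v / m


def coefficient_of_determination(x, y) -> float:
    """Squared Pearson correlation of two paired series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.shape != y.shape:
        raise ValueError("need at least three paired points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def read_dose_table(path) -> pd.DataFrame:
    """Dose table CSV -> DataFrame (index: region, columns: configs).

    The file must have a ``region`` column; all remaining columns
    are configuration doses and must parse as positive numbers.
    Malformed cells are reported with their CSV line number.
    """
    df = pd.read_csv(path)
    if "region" not in df.columns:
        raise ValueError("dose table must have a 'region' column")
    df = df.set_index("region")
    units = df.pop("units") if "units" in df.columns else None
    bad = []
    for i, (region, row) in enumerate(df.iterrows()):
        vals = pd.to_numeric(row, errors="coerce")
        if vals.isna().any() or (vals <= 0).any():
            bad.append(f"line {i + 2} ({region})")
    if bad:
        raise ValueError("non-positive or non-numeric dose values at: " + ", ".join(bad))
    out = df.astype(float)
    if units is not None:
        out.attrs["units"] = units.to_dict()
    return out


def write_comparison(table: pd.DataFrame, path, decimals: int = 1) -> None:
    """Render a comparison table to CSV, reference column as '-'."""
    rendered = table.apply(lambda c: round_half_away(c, decimals))
    rendered = rendered.astype(object)
    zero_cols = [c for c in table.columns if (table[c] == 0).all()]
    for c in zero_cols:
        rendered[c] = "-"
    rendered.index.name = "region"
    rendered.to_csv(path)


def _data_path(name: str):
    return resources.files("invpetdose.data").joinpath(name)


def load_published_dose_table() -> pd.DataFrame:
    """Packaged dose-estimate table (tumor mGy/MBq, organs mSv/MBq)."""
    return read_dose_table(_data_path("table1_doses.csv"))


def load_published_comparison() -> pd.DataFrame:
    """Packaged percent-difference table (reference column as NaN)."""
    df = pd.read_csv(_data_path("table2_percent_diff.csv"), na_values=["-"])
    return df.set_index("region").astype(float)


def load_sphere_svalue_table():
    """Packaged synthetic Cu-64 sphere S-value table."""
    from .dosimetry import SphereSValueTable

    return SphereSValueTable.from_csv(_data_path("svalue_sphere_cu64_synthetic.csv"))


def load_organ_smatrix():
    """Packaged synthetic organ S-factor matrix with tissue weights."""
    from .dosimetry import OrganSMatrix

    return OrganSMatrix.from_csv(_data_path("smatrix_synthetic.csv"))
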