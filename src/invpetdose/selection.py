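"""RC-NU trade-off selection of a reconstruction configuration.

A configuration is acceptable when the 3 mm rod recovery
coefficient and the uniform-region non-uniformity satisfy, with
strict inequalities,

    rc_low < RC < rc_high   and   NU < nu_max_percent

(defaults 0.9 < RC < 1.0 and NU < 10%). Survivors are reported in
ascending NU order; no further tie-breaking is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import pandas as pd


@dataclass(frozen=True)
class CriterionConfig:
    rc_low: float = 0.9
    rc_high: float = 1.0
    nu_max_percent: float = 10.0
    rc_rod_mm: float = 3.0

    def __post_init__(self) -> None:
        if not self.rc_low < self.rc_high:
            raise ValueError("rc_low must be < rc_high")
        if self.nu_max_percent <= 0:
            raise ValueError("nu_max must be positive")


@dataclass(frozen=True)
class TradeoffEntry:
    """One (configuration, correction level) point on the RC-NU plane."""

    config_id: str
    rc: float | None
    nu_percent: float | None
    correction_level: str = "partial"


@dataclass
class SelectionResult:
    entries: list[dict]
    selected: list[str]  # config ids passing, ascending NU

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)


def _passes(rc, nu, cfg: CriterionConfig) -> bool | None:
    """Strict-inequality check; None when a metric is missing."""
    if rc is None or nu is None or not (math.isfinite(rc) and math.isfinite(nu)):
        return None
    return cfg.rc_low < rc < cfg.rc_high and nu < cfg.nu_max_percent


def apply_rc_nu_criterion(
    entries: list[TradeoffEntry], cfg: CriterionConfig | None = None
) -> SelectionResult:
    """Filter trade-off entries by the RC-NU box.

    Entries with a missing metric are flagged unevaluable
    (``passes = None``) rather than dropped.
    """
    cfg = cfg or CriterionConfig()
    rows = []
    for e in entries:
        rows.append(
            {
                "config_id": e.config_id,
                "correction_level": e.correction_level,
                f"rc_{cfg.rc_rod_mm:g}mm": e.rc,
                "nu_percent": e.nu_percent,
                "passes": _passes(e.rc, e.nu_percent, cfg),
            }
        )
    survivors = [r for r in rows if r["passes"]]
    survivors.sort(key=lambda r: r["nu_percent"])
    return SelectionResult(rows, [r["config_id"] for r in survivors])


def tradeoff_table(
    entries: list[TradeoffEntry], cfg: CriterionConfig | None = None
) -> pd.DataFrame:
    """One row per (config, correction level), CSV-serializable."""
    return apply_rc_nu_criterion(entries, cfg).to_frame()
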