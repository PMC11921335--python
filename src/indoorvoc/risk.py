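"""Lifetime cancer risk (LCR) and hazard quotient (HQ) benchmarks.

Indoor concentrations are compared against toxicity values of the
IRIS-database kind: an inhalation unit risk (IUR, (µg m-3)-1) — the
upper-bound excess lifetime cancer risk from continuous lifetime exposure
at 1 µg m-3 — and a non-cancer reference concentration (RfC, µg m-3).

Following the standard US EPA / ATSDR inhalation formulation, the measured
concentration is first converted to an exposure concentration

    EC = C * (ET/24) * (EF/365) * (ED/AT)

with exposure time ET (h day-1), frequency EF (days yr-1), duration ED (yr)
and averaging time AT (yr; lifetime for cancer, equal to ED for
non-cancer).  Then

    LCR = IUR * EC          (flagged above 1e-6, the 1-in-a-million level)
    HQ  = EC_ED / RfC       (flagged above 1)

Exposure factors and the per-VOC toxicity table are configuration, never
constants in the logic; the bundled defaults (ET=16 h at home, EF=365,
ED=AT=70 yr) are a documented stand-in for population-specific values.
These benchmarks are indicative screening values, not individual health
predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Optional

import math

import numpy as np
import pandas as pd

__all__ = [
    "LCR_THRESHOLD",
    "HQ_THRESHOLD",
    "ExposureFactors",
    "RiskTable",
    "RiskResult",
    "exposure_concentration",
    "lifetime_cancer_risk",
    "hazard_quotient",
    "assess_home",
    "risk_table_for_cohort",
    "exceedance_summary",
]

LCR_THRESHOLD = 1e-6
HQ_THRESHOLD = 1.0


@dataclass(frozen=True)
class ExposureFactors:
    """Inhalation exposure-factor set (EPA-style symbols in comments)."""

    hours_at_home_per_day: float = 16.0  # ET
    days_per_year: float = 365.0  # EF
    exposure_duration_years: float = 70.0  # ED
    averaging_time_years: float = 70.0  # AT (lifetime; cancer assessments)

    def __post_init__(self) -> None:
        if not 0 < self.hours_at_home_per_day <= 24:
            raise ValueError("hours_at_home_per_day must lie in (0, 24]")
        if not 0 < self.days_per_year <= 365:
            raise ValueError("days_per_year must lie in (0, 365]")
        if self.exposure_duration_years <= 0 or self.averaging_time_years <= 0:
            raise ValueError("durations must be positive")
        if self.exposure_duration_years > self.averaging_time_years:
            raise ValueError(
                "exposure_duration_years must not exceed averaging_time_years"
            )


class RiskTable:
    """Per-VOC inhalation unit risks and reference concentrations.

    Backed by a DataFrame with columns ``voc``, ``iur`` ((µg m-3)-1, may be
    missing), ``rfc`` (µg m-3, may be missing) and ``provenance``.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"voc", "iur", "rfc"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"risk table missing columns: {sorted(missing)}")
        t = table.copy()
        if "provenance" not in t.columns:
            t["provenance"] = ""
        bad_iur = t["iur"].dropna() < 0
        if bad_iur.any():
            raise ValueError("IUR values must be non-negative")
        bad_rfc = t["rfc"].dropna() <= 0
        if bad_rfc.any():
            raise ValueError("RfC values must be positive where present")
        if t["voc"].duplicated().any():
            raise ValueError("duplicate VOC entries in risk table")
        self._table = t.reset_index(drop=True)
        self._iur: Dict[str, float] = {
            r.voc: float(r.iur) for r in t.itertuples() if not pd.isna(r.iur)
        }
        self._rfc: Dict[str, float] = {
            r.voc: float(r.rfc) for r in t.itertuples() if not pd.isna(r.rfc)
        }

    @property
    def table(self) -> pd.DataFrame:
        return self._table.copy()

    def iur(self, voc: str) -> Optional[float]:
        return self._iur.get(voc)

    def rfc(self, voc: str) -> Optional[float]:
        return self._rfc.get(voc)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RiskTable":
        return cls(pd.read_csv(path))

    @classmethod
    def default(cls) -> "RiskTable":
        """The bundled table of IRIS-style values (editable CSV)."""
        with resources.files("indoorvoc.data").joinpath("risk_table.csv").open() as f:
            return cls(pd.read_csv(f))


@dataclass(frozen=True)
class RiskResult:
    """LCR/HQ outcome for one home x VOC; None marks not-assessable."""

    home_id: str
    voc: str
    concentration: float
    exposure_concentration: float
    lcr: Optional[float]
    hq: Optional[float]
    exceeds_lcr_1e6: Optional[bool]
    exceeds_hq_1: Optional[bool]


def exposure_concentration(c: float, ef: ExposureFactors) -> float:
    """EC = C * (ET/24) * (EF/365) * (ED/AT)."""
    if c < 0:
        raise ValueError("concentration must be non-negative")
    return (
        c
        * (ef.hours_at_home_per_day / 24.0)
        * (ef.days_per_year / 365.0)
        * (ef.exposure_duration_years / ef.averaging_time_years)
    )


def lifetime_cancer_risk(
    c: float, voc: str, table: RiskTable, ef: ExposureFactors
) -> Optional[float]:
    """LCR = IUR * EC, or None when the VOC has no IUR (never a silent 0)."""
    iur = table.iur(voc)
    if iur is None:
        return None
    return iur * exposure_concentration(c, ef)


def hazard_quotient(
    c: float, voc: str, table: RiskTable, ef: ExposureFactors
) -> Optional[float]:
    """HQ = EC / RfC with AT set to ED (chronic non-cancer convention)."""
    rfc = table.rfc(voc)
    if rfc is None:
        return None
    ef_hq = ExposureFactors(
        hours_at_home_per_day=ef.hours_at_home_per_day,
        days_per_year=ef.days_per_year,
        exposure_duration_years=ef.exposure_duration_years,
        averaging_time_years=ef.exposure_duration_years,
    )
    return exposure_concentration(c, ef_hq) / rfc


def assess_home(
    home_id: str,
    concentrations: Dict[str, float],
    table: RiskTable,
    ef: ExposureFactors = ExposureFactors(),
) -> list[RiskResult]:
    """LCR and HQ for every VOC of one home that has a toxicity value.

    VOCs with neither an IUR nor an RfC are omitted entirely (explicit
    absence, not zero risk).  "Exceeds" means strictly greater than the
    threshold.
    """
    results = []
    for voc, c in concentrations.items():
        lcr = lifetime_cancer_risk(c, voc, table, ef)
        hq = hazard_quotient(c, voc, table, ef)
        if lcr is None and hq is None:
            continue
        results.append(
            RiskResult(
                home_id=home_id,
                voc=voc,
                concentration=c,
                exposure_concentration=exposure_concentration(c, ef),
                lcr=lcr,
                hq=hq,
                exceeds_lcr_1e6=None if lcr is None else lcr > LCR_THRESHOLD,
                exceeds_hq_1=None if hq is None else hq > HQ_THRESHOLD,
            )
        )
    return results


def risk_table_for_cohort(
    conc: pd.DataFrame,
    table: RiskTable,
    ef: ExposureFactors = ExposureFactors(),
    value_col: str = "indoor_conc",
) -> pd.DataFrame:
    """Tidy LCR/HQ table over a long home x VOC concentration table.

    Vectorized equivalent of mapping :func:`assess_home` over every home;
    VOCs with neither an IUR nor an RfC are omitted, and within an
    assessable VOC the missing metric is NaN with a <NA> exceedance flag.
    """
    if (conc[value_col] < 0).any():
        raise ValueError("concentrations must be non-negative")
    iur = conc["voc"].map(table._iur)
    rfc = conc["voc"].map(table._rfc)
    assessable = iur.notna() | rfc.notna()
    out = conc.loc[assessable, ["home_id", "voc", value_col]].rename(
        columns={value_col: "concentration"}
    )
    ec_factor = (
        (ef.hours_at_home_per_day / 24.0)
        * (ef.days_per_year / 365.0)
        * (ef.exposure_duration_years / ef.averaging_time_years)
    )
    ec_hq_factor = (ef.hours_at_home_per_day / 24.0) * (ef.days_per_year / 365.0)
    out["exposure_concentration"] = out["concentration"] * ec_factor
    out["lcr"] = out["exposure_concentration"] * iur[assessable]
    out["hq"] = out["concentration"] * ec_hq_factor / rfc[assessable]
    out["exceeds_lcr_1e6"] = (out["lcr"] > LCR_THRESHOLD).mask(out["lcr"].isna())
    out["exceeds_hq_1"] = (out["hq"] > HQ_THRESHOLD).mask(out["hq"].isna())
    cols = ["home_id", "voc", "concentration", "exposure_concentration",
            "lcr", "hq", "exceeds_lcr_1e6", "exceeds_hq_1"]
    return out[cols].reset_index(drop=True)


def exceedance_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Per-VOC fraction of homes above the LCR and HQ thresholds.

    Fractions are over homes for which the metric is assessable; VOCs with
    no assessable homes for a metric get NaN there, never an implicit 0.
    """
    if results.empty:
        raise ValueError("no risk results to summarise")
    rows = []
    for voc, grp in results.groupby("voc", sort=False):
        lcr_known = grp["lcr"].notna()
        hq_known = grp["hq"].notna()
        rows.append(
            {
                "voc": voc,
                "n_homes": len(grp),
                "frac_exceed_lcr_1e6": (
                    float(grp.loc[lcr_known, "exceeds_lcr_1e6"].astype(bool).mean())
                    if lcr_known.any()
                    else math.nan
                ),
                "frac_exceed_hq_1": (
                    float(grp.loc[hq_known, "exceeds_hq_1"].astype(bool).mean())
                    if hq_known.any()
                    else math.nan
                ),
            }
        )
    return pd.DataFrame(rows)
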