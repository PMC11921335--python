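"""Air change rate (ACR) inference from occupant-generated CO2.

A single-zone steady-state mass balance relates the indoor excess CO2
mixing ratio to the occupants' metabolic CO2 source and the ventilation
rate.  At steady state the CO2 source is balanced by ventilation removal:

    ACR = G_total / (V_adj * (C_in - C_ex) * 1e-6)

where ``G_total`` is the occupancy-adjusted CO2 generation rate (m3 h-1),
``V_adj`` the furnishing-adjusted room volume (m3) and ``C_in - C_ex`` the
indoor-outdoor CO2 difference (ppm; the 1e-6 converts ppm to a volume
fraction).  Generation rates are specified per occupant in L min-1 and
converted to m3 h-1 (x 60 / 1000 = x 0.06); dimensional analysis forces
both conversions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple, TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import HomeSample

__all__ = [
    "AcrParams",
    "AcrResult",
    "adjusted_volume",
    "generation_rate",
    "infer_acr",
    "acr_table",
    "co2_from_acr",
    "summarise_acr_by_season",
]

#: L min-1 -> m3 h-1
_L_PER_MIN_TO_M3_PER_H = 60.0 / 1000.0
#: ppm -> volume fraction
_PPM = 1e-6


@dataclass(frozen=True)
class AcrParams:
    """Constants of the CO2 mass balance.

    Parameters
    ----------
    g_adult, g_child
        Metabolic CO2 generation rates, L min-1 per person.  Defaults are
        the standard adult (0.312) and child (0.174) values used for
        residential occupancy.
    co2_outdoor
        Assumed outdoor CO2 mixing ratio C_ex in ppm (default 450).
    furnishing_fraction
        Fraction of the measured room volume occupied by furnishings
        (default 0.07); the mass balance uses the remaining diluent volume.
    """

    g_adult: float = 0.312
    g_child: float = 0.174
    co2_outdoor: float = 450.0
    furnishing_fraction: float = 0.07

    def __post_init__(self) -> None:
        if self.g_adult <= 0 or self.g_child <= 0:
            raise ValueError("CO2 generation rates must be positive")
        if self.co2_outdoor <= 0:
            raise ValueError("co2_outdoor must be positive")
        if not 0.0 <= self.furnishing_fraction < 1.0:
            raise ValueError("furnishing_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class AcrResult:
    """Inferred ACR with the audit quantities that produced it."""

    acr: float  # h-1
    volume_adjusted: float  # m3
    co2_excess: float  # ppm
    generation_total: float  # m3 h-1


def adjusted_volume(volume_raw: float, params: AcrParams = AcrParams()) -> float:
    """Diluent volume after removing the furnishing fraction."""
    if volume_raw <= 0:
        raise ValueError(f"volume_raw must be positive, got {volume_raw}")
    return volume_raw * (1.0 - params.furnishing_fraction)


def generation_rate(
    n_adults: int,
    n_children: int,
    occupancy_fraction: float,
    params: AcrParams = AcrParams(),
) -> float:
    """Occupancy-adjusted total CO2 generation rate in m3 h-1.

    The per-person L min-1 rates are summed over occupants, scaled by the
    fraction of the sampling period spent in the room, and converted to
    m3 h-1.  A single shared occupancy fraction is applied to adults and
    children alike.
    """
    if n_adults < 0 or n_children < 0:
        raise ValueError("occupant counts must be non-negative")
    if n_adults + n_children < 1:
        raise ValueError("ACR inference requires at least one occupant")
    if not 0.0 < occupancy_fraction <= 1.0:
        raise ValueError(
            f"occupancy_fraction must lie in (0, 1], got {occupancy_fraction}"
        )
    g_l_per_min = n_adults * params.g_adult + n_children * params.g_child
    return g_l_per_min * occupancy_fraction * _L_PER_MIN_TO_M3_PER_H


def infer_acr(sample: "HomeSample", params: AcrParams = AcrParams()) -> AcrResult:
    """Infer the air change rate of one home from its CO2 excess.

    Raises
    ------
    ValueError
        If the indoor CO2 does not exceed the assumed outdoor level (the
        steady-state balance is then meaningless and the sample should be
        inspected rather than silently clamped), or if the home has no
        occupants.
    """
    v_adj = adjusted_volume(sample.volume_raw, params)
    excess = sample.co2_indoor - params.co2_outdoor
    if excess <= 0:
        raise ValueError(
            f"home {sample.home_id!r}: indoor CO2 ({sample.co2_indoor} ppm) does "
            f"not exceed the assumed outdoor level ({params.co2_outdoor} ppm); "
            "the occupant-CO2 steady-state balance cannot be applied"
        )
    g_total = generation_rate(
        sample.n_adults, sample.n_children, sample.occupancy_fraction, params
    )
    acr = g_total / (v_adj * excess * _PPM)
    return AcrResult(
        acr=acr, volume_adjusted=v_adj, co2_excess=excess, generation_total=g_total
    )


def co2_from_acr(
    true_acr: float,
    volume_raw: float,
    n_adults: int,
    n_children: int,
    occupancy_fraction: float,
    params: AcrParams = AcrParams(),
) -> float:
    """Indoor CO2 mixing ratio (ppm) implied by a known ACR.

    Algebraic inverse of :func:`infer_acr`; the synthetic cohort generator
    uses it so that ACR recovery is an exact round trip.
    """
    if true_acr <= 0:
        raise ValueError("true_acr must be positive")
    v_adj = adjusted_volume(volume_raw, params)
    g_total = generation_rate(n_adults, n_children, occupancy_fraction, params)
    excess_ppm = g_total / (true_acr * v_adj) / _PPM
    return params.co2_outdoor + excess_ppm


def acr_table(
    samples: Iterable["HomeSample"], params: AcrParams = AcrParams()
) -> pd.DataFrame:
    """Per-home ACR table with audit columns.

    Columns: home_id, season, urban, acr, volume_adjusted, co2_excess,
    generation_total.
    """
    rows = []
    for s in samples:
        res = infer_acr(s, params)
        rows.append(
            {
                "home_id": s.home_id,
                "season": s.season,
                "urban": s.urban,
                "acr": res.acr,
                "volume_adjusted": res.volume_adjusted,
                "co2_excess": res.co2_excess,
                "generation_total": res.generation_total,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "home_id",
            "season",
            "urban",
            "acr",
            "volume_adjusted",
            "co2_excess",
            "generation_total",
        ],
    )


def summarise_acr_by_season(
    results: Sequence[Tuple[str, AcrResult]] | pd.DataFrame,
    n_resamples: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Seasonal ACR summary: median, mean, percentile spread, bootstrap CI.

    Accepts either ``(season, AcrResult)`` pairs or a DataFrame with
    ``season`` and ``acr`` columns.  The 95% CI of the seasonal mean uses
    the percentile bootstrap with ``n_resamples`` seeded resamples.
    """
    from .nonparametric import bootstrap_ci, boxplot_summary

    if isinstance(results, pd.DataFrame):
        df = results[["season", "acr"]]
    else:
        df = pd.DataFrame(
            [{"season": season, "acr": res.acr} for season, res in results]
        )
    if df.empty:
        raise ValueError("no ACR results to summarise")

    rows = []
    for season, grp in df.groupby("season", sort=False):
        vals = grp["acr"].to_numpy()
        box = boxplot_summary(vals)
        ci = bootstrap_ci(vals, np.mean, n_resamples=n_resamples, seed=seed)
        rows.append(
            {
                "season": season,
                "n": len(vals),
                "median": box.percentiles[50],
                "mean": float(np.mean(vals)),
                "p5": box.percentiles[5],
                "p25": box.percentiles[25],
                "p75": box.percentiles[75],
                "p95": box.percentiles[95],
                "mean_ci_lower": ci.lower,
                "mean_ci_upper": ci.upper,
            }
        )
    return pd.DataFrame(rows)
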