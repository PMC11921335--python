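"""Time-averaged VOC emission rates from a single-zone steady-state balance.

If a VOC's indoor concentration is at steady state and ventilation is the
only removal process, the whole-room source strength over the sampling
period is

    q = ACR * V_adj * (C_in - C_out)        [µg h-1]

with ACR in h-1, the furnishing-adjusted volume V_adj in m3 and the
indoor/outdoor concentrations in µg m-3.  q is time-averaged: episodic
emission events are captured but smoothed over the integration period.
Negative q (outdoor exceeding indoor) is physically meaningful — net
ingress with indoor sinks — and is retained but flagged.

Per-VOC min-max normalization rescales each VOC's emission rates across
homes onto [0, 1], so that summed normalized totals are not dominated by
the few high-mass species (ethanol, butane, propane).
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "emission_rate",
    "emission_table",
    "tvoc",
    "tvoc_table",
    "class_total",
    "normalize_emissions",
    "sensitivity_analysis",
]


def emission_rate(c_in, c_out, acr, volume_adjusted):
    """q = acr * volume_adjusted * (c_in - c_out), in µg h-1.

    Accepts scalars or broadcastable arrays.  Negative differences give
    negative rates (net ingress); they are not clamped here.
    """
    acr_arr = np.asarray(acr, dtype=float)
    vol = np.asarray(volume_adjusted, dtype=float)
    if np.any(acr_arr <= 0):
        raise ValueError("acr must be positive")
    if np.any(vol <= 0):
        raise ValueError("volume_adjusted must be positive")
    c_in = np.asarray(c_in, dtype=float)
    c_out = np.asarray(c_out, dtype=float)
    if np.any(c_in < 0) or np.any(c_out < 0):
        raise ValueError("concentrations must be non-negative")
    q = acr_arr * vol * (c_in - c_out)
    return float(q) if np.ndim(q) == 0 else q


def emission_table(conc: pd.DataFrame, acr: pd.DataFrame) -> pd.DataFrame:
    """Per-home, per-VOC emission records from tidy tables.

    Parameters
    ----------
    conc
        Columns ``home_id``, ``voc``, ``indoor_conc``, ``outdoor_conc``.
    acr
        Columns ``home_id``, ``acr``, ``volume_adjusted`` (plus optional
        metadata such as ``season``/``urban``, carried through).

    Rows with a missing outdoor concentration are skipped (assuming
    C_out = 0 would overstate the source); a ``negative`` flag column marks
    net-ingress records.
    """
    meta_cols = [c for c in ("season", "urban") if c in acr.columns]
    merged = conc.merge(
        acr[["home_id", "acr", "volume_adjusted", *meta_cols]],
        on="home_id",
        how="inner",
    )
    usable = merged["outdoor_conc"].notna()
    merged = merged[usable].copy()
    merged["q"] = emission_rate(
        merged["indoor_conc"].to_numpy(),
        merged["outdoor_conc"].to_numpy(),
        merged["acr"].to_numpy(),
        merged["volume_adjusted"].to_numpy(),
    )
    merged["negative"] = merged["q"] < 0
    cols = ["home_id", "voc", "q", "indoor_conc", "outdoor_conc", "acr",
            "volume_adjusted", "negative", *meta_cols]
    return merged[cols].reset_index(drop=True)


def tvoc(sample_concentrations: Mapping[str, float]) -> float:
    """Total VOC concentration: the sum over all quantified VOCs.

    An operational metric — it sums whatever species were quantified in the
    sample, so an absent VOC and one present at zero contribute identically.
    """
    if not sample_concentrations:
        raise ValueError("cannot compute TVOC of an empty concentration map")
    vals = np.fromiter(sample_concentrations.values(), dtype=float)
    if np.any(vals < 0):
        raise ValueError("concentrations must be non-negative")
    return float(vals.sum())


def tvoc_table(conc: pd.DataFrame, value_col: str = "indoor_conc") -> pd.DataFrame:
    """Per-home TVOC from the tidy concentration table."""
    if conc.empty:
        raise ValueError("empty concentration table")
    out = (
        conc.groupby("home_id", sort=False)[value_col]
        .sum()
        .rename("tvoc")
        .reset_index()
    )
    return out


def class_total(
    records: pd.DataFrame,
    members: Iterable[str],
    value_col: str = "q",
) -> pd.Series:
    """Per-home sum of ``value_col`` over a VOC class.

    Homes with no member VOC present get 0.  Works on emission records
    (default) or any long home x VOC table.
    """
    members = set(members)
    if not members:
        raise ValueError("members must be non-empty")
    mask = records["voc"].isin(members)
    totals = records[mask].groupby("home_id", sort=False)[value_col].sum()
    all_homes = records["home_id"].drop_duplicates()
    return totals.reindex(all_homes, fill_value=0.0).rename(f"{value_col}_class_total")


def normalize_emissions(records: pd.DataFrame, value_col: str = "q") -> pd.DataFrame:
    """Min-max normalize emission rates per VOC across homes.

    x_hat = (x - min) / (max - min), so each VOC's largest rate maps to 1
    and its smallest to 0.  A VOC whose rates are constant across homes has
    no defined normalization and raises, naming the VOC.
    """
    rows = []
    for voc_name, grp in records.groupby("voc", sort=False):
        x = grp[value_col].to_numpy(dtype=float)
        if len(x) < 2:
            raise ValueError(f"VOC {voc_name!r}: need >= 2 records to normalize")
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise ValueError(
                f"VOC {voc_name!r}: constant emission series (max == min), "
                "min-max normalization undefined"
            )
        rows.append(
            pd.DataFrame(
                {
                    "home_id": grp["home_id"].to_numpy(),
                    "voc": voc_name,
                    "x_hat": (x - lo) / (hi - lo),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def sensitivity_analysis(
    q: float,
    acr_perturbations: Sequence[float],
    volume_perturbations: Sequence[float],
) -> pd.DataFrame:
    """Recompute an emission rate over a fractional-perturbation grid.

    Because q is multiplicative in ACR and volume, perturbing them by
    fractions (da, dv) rescales q exactly: q_grid = q * (1+da) * (1+dv).
    Returns a long DataFrame with columns ``acr_delta``, ``volume_delta``,
    ``q``.
    """
    da = np.asarray(acr_perturbations, dtype=float)
    dv = np.asarray(volume_perturbations, dtype=float)
    if np.any(da <= -1) or np.any(dv <= -1):
        raise ValueError("perturbation fractions must exceed -1")
    grid = q * np.outer(1.0 + da, 1.0 + dv)
    out = pd.DataFrame(
        {
            "acr_delta": np.repeat(da, len(dv)),
            "volume_delta": np.tile(dv, len(da)),
            "q": grid.ravel(),
        }
    )
    return out
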