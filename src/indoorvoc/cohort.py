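"""Synthetic home-cohort generator.

Emulates the statistical structure of a residential indoor-air campaign:
log-normally distributed indoor and outdoor VOC concentrations, seasonal
structure in the true air change rate, elevated aromatic (BTEX and
trimethylbenzene) levels in urban homes, rare multiplicative painting-style
spikes on indoor aromatics, and an indoor CO2 mixing ratio derived by
inverting the occupant-CO2 mass balance from each home's true ACR — so the
ACR inference is testable as an exact round trip.

Every draw comes from a single :class:`numpy.random.Generator` seeded from
``CohortSpec.seed``; the same spec reproduces the same cohort bit for bit.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import acr as _acr
from .acr import AcrParams

__all__ = [
    "VocParams",
    "CohortSpec",
    "HomeSample",
    "SEASONS",
    "assign_season",
    "generate_cohort",
    "cohort_to_tables",
    "tables_to_cohort",
    "default_spec",
]

SEASONS = ("winter", "spring", "summer", "autumn")

_MONTH_TO_SEASON = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}


def assign_season(date: _dt.date) -> str:
    """Meteorological season of a calendar date.

    Winter is December-February, spring March-May, summer June-August,
    autumn September-November.
    """
    return _MONTH_TO_SEASON[date.month]


@dataclass(frozen=True)
class VocParams:
    """Log-normal concentration parameters for one VOC (µg m-3).

    ``*_median`` is the distribution median (= geometric mean), ``*_gsd``
    the geometric standard deviation (> 1 for any spread).
    """

    indoor_median: float
    indoor_gsd: float
    outdoor_median: float
    outdoor_gsd: float


# Aromatics subject to the urban elevation and painting spikes.
AROMATIC_VOCS = (
    "benzene",
    "toluene",
    "ethylbenzene",
    "xylene",
    "1,2,4-trimethylbenzene",
    "1,2,3-trimethylbenzene",
)


def _default_panel() -> Dict[str, VocParams]:
    # Medians anchored to reported UK residential values where available;
    # geometric SDs by compound class (solvents/propellants ~3, aromatics
    # ~2, halocarbons tighter).
    return {
        "ethanol": VocParams(320.0, 3.0, 5.0, 2.0),
        "methanol": VocParams(30.0, 2.5, 3.0, 1.8),
        "isopropanol": VocParams(20.0, 3.0, 1.0, 2.0),
        "butane": VocParams(50.0, 3.0, 2.0, 2.0),
        "propane": VocParams(30.0, 3.0, 1.5, 2.0),
        "benzene": VocParams(0.70, 1.8, 0.35, 1.8),
        "toluene": VocParams(2.0, 2.2, 0.80, 2.0),
        "ethylbenzene": VocParams(0.45, 2.0, 0.15, 2.0),
        "xylene": VocParams(1.22, 2.2, 0.50, 2.0),
        "1,2,4-trimethylbenzene": VocParams(0.35, 2.2, 0.12, 2.0),
        "1,2,3-trimethylbenzene": VocParams(0.15, 2.2, 0.05, 2.0),
        "alpha-pinene": VocParams(3.0, 2.5, 0.10, 2.0),
        "limonene": VocParams(12.0, 2.8, 0.10, 2.0),
        "acetaldehyde": VocParams(15.0, 2.0, 1.5, 1.8),
        "1,3-butadiene": VocParams(2.5, 2.2, 0.30, 2.0),
        "carbon tetrachloride": VocParams(15.5, 1.5, 0.60, 1.3),
        "chloroform": VocParams(1.0, 2.0, 0.10, 1.8),
    }


def _default_seasonal_acr() -> Dict[str, Tuple[float, float]]:
    # (median h-1, geometric SD): high in summer, low in winter, with the
    # spring rise preceding the autumn decline.
    return {
        "winter": (0.70, 1.35),
        "spring": (1.00, 1.40),
        "summer": (1.20, 1.50),
        "autumn": (0.80, 1.35),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterisation of a synthetic cohort."""

    n_homes: int = 124
    seed: int = 0
    voc_panel: Dict[str, VocParams] = field(default_factory=_default_panel)
    seasonal_acr: Dict[str, Tuple[float, float]] = field(
        default_factory=_default_seasonal_acr
    )
    urban_fraction: float = 0.7
    urban_aromatic_multiplier: float = 2.0
    spike_prob: float = 0.05
    spike_multiplier: float = 50.0
    volume_range: Tuple[float, float] = (20.0, 120.0)
    adult_choices: Tuple[int, ...] = (1, 2)
    child_choices: Tuple[int, ...] = (0, 1, 2, 3)
    occupancy_fraction_range: Tuple[float, float] = (0.3, 0.8)
    start_date: _dt.date = _dt.date(2023, 3, 1)
    n_days: int = 366
    co2_noise_gsd: float = 1.0  # 1.0 = exact inversion (no noise)
    acr_params: AcrParams = field(default_factory=AcrParams)

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first offending field."""
        if self.n_homes < 0:
            raise ValueError("n_homes: must be non-negative")
        if not self.voc_panel:
            raise ValueError("voc_panel: must be non-empty")
        for voc, p in self.voc_panel.items():
            if p.indoor_median <= 0 or p.outdoor_median <= 0:
                raise ValueError(f"voc_panel[{voc!r}]: medians must be positive")
            if p.indoor_gsd < 1 or p.outdoor_gsd < 1:
                raise ValueError(f"voc_panel[{voc!r}]: geometric SDs must be >= 1")
        missing = set(SEASONS) - set(self.seasonal_acr)
        if missing:
            raise ValueError(f"seasonal_acr: missing seasons {sorted(missing)}")
        for season, (med, gsd) in self.seasonal_acr.items():
            if med <= 0 or gsd < 1:
                raise ValueError(
                    f"seasonal_acr[{season!r}]: median must be > 0 and GSD >= 1"
                )
        for name, prob in (
            ("urban_fraction", self.urban_fraction),
            ("spike_prob", self.spike_prob),
        ):
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"{name}: must lie in [0, 1]")
        for name, mult in (
            ("urban_aromatic_multiplier", self.urban_aromatic_multiplier),
            ("spike_multiplier", self.spike_multiplier),
        ):
            if mult < 1.0:
                raise ValueError(f"{name}: must be >= 1")
        lo, hi = self.volume_range
        if not 0 < lo <= hi:
            raise ValueError("volume_range: require 0 < min <= max")
        flo, fhi = self.occupancy_fraction_range
        if not 0 < flo <= fhi <= 1:
            raise ValueError("occupancy_fraction_range: require 0 < min <= max <= 1")
        if not self.adult_choices and not any(self.child_choices):
            raise ValueError("adult_choices: at least one occupant must be possible")
        if min(self.adult_choices) + min(self.child_choices, default=0) < 1:
            raise ValueError(
                "adult_choices/child_choices: every home needs >= 1 occupant"
            )
        if self.co2_noise_gsd < 1.0:
            raise ValueError("co2_noise_gsd: must be >= 1")

    def with_(self, **kwargs) -> "CohortSpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def default_spec(**overrides) -> CohortSpec:
    """The bundled default cohort specification, optionally overridden."""
    return CohortSpec(**overrides)


@dataclass
class HomeSample:
    """One canister deployment: home metadata plus measured quantities.

    ``true_acr`` is generator-only ground truth and is ``None`` when the
    sample comes from real data.
    """

    home_id: str
    sample_date: _dt.date
    season: str
    urban: bool
    volume_raw: float  # m3, before furnishing adjustment
    n_adults: int
    n_children: int
    occupancy_fraction: float
    co2_indoor: float  # ppm
    indoor_conc: Dict[str, float]  # VOC -> µg m-3
    outdoor_conc: Dict[str, float]  # VOC -> µg m-3
    true_acr: Optional[float] = None
    spiked: bool = False

    def __post_init__(self) -> None:
        if self.volume_raw <= 0:
            raise ValueError(f"home {self.home_id!r}: volume_raw must be positive")
        if self.n_adults + self.n_children < 1:
            raise ValueError(f"home {self.home_id!r}: needs at least one occupant")
        if self.season != assign_season(self.sample_date):
            raise ValueError(
                f"home {self.home_id!r}: season {self.season!r} inconsistent with "
                f"sample date {self.sample_date}"
            )
        for name, conc in (("indoor", self.indoor_conc), ("outdoor", self.outdoor_conc)):
            for voc, v in conc.items():
                if v < 0:
                    raise ValueError(
                        f"home {self.home_id!r}: negative {name} {voc} concentration"
                    )


def _lognormal(rng: np.random.Generator, median: float, gsd: float, size=None):
    """Log-normal draw parameterised by median and geometric SD."""
    return rng.lognormal(mean=np.log(median), sigma=np.log(gsd), size=size)


def generate_cohort(spec: CohortSpec) -> List[HomeSample]:
    """Draw a reproducible synthetic cohort from ``spec``.

    Each home gets a sampling date (uniform over the campaign window), an
    urban/rural label, room volume, occupants, a season-specific true ACR,
    per-VOC indoor and outdoor concentrations, and an indoor CO2 mixing
    ratio computed by inverting the occupant-CO2 mass balance from its true
    ACR (optionally degraded by multiplicative noise on the CO2 excess).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    samples: List[HomeSample] = []
    width = max(3, len(str(max(spec.n_homes, 1))))

    for i in range(spec.n_homes):
        date = spec.start_date + _dt.timedelta(days=int(rng.integers(0, spec.n_days)))
        season = assign_season(date)
        urban = bool(rng.random() < spec.urban_fraction)
        volume = float(rng.uniform(*spec.volume_range))
        n_adults = int(rng.choice(spec.adult_choices))
        n_children = int(rng.choice(spec.child_choices))
        if n_adults + n_children < 1:  # pragma: no cover - guarded by validate
            n_adults = 1
        occ_frac = float(rng.uniform(*spec.occupancy_fraction_range))
        med, gsd = spec.seasonal_acr[season]
        true_acr = float(_lognormal(rng, med, gsd))
        spiked = bool(rng.random() < spec.spike_prob)

        indoor: Dict[str, float] = {}
        outdoor: Dict[str, float] = {}
        for voc, p in spec.voc_panel.items():
            aromatic = voc in AROMATIC_VOCS
            in_med = p.indoor_median
            out_med = p.outdoor_median
            if urban and aromatic:
                # Elevated traffic aromatics outdoors, carried indoors by
                # ingress: same multiplicative shift on both medians.
                in_med *= spec.urban_aromatic_multiplier
                out_med *= spec.urban_aromatic_multiplier
            c_in = float(_lognormal(rng, in_med, p.indoor_gsd))
            if spiked and aromatic:
                c_in *= spec.spike_multiplier
            indoor[voc] = c_in
            outdoor[voc] = float(_lognormal(rng, out_med, p.outdoor_gsd))

        co2 = _acr.co2_from_acr(
            true_acr, volume, n_adults, n_children, occ_frac, spec.acr_params
        )
        if spec.co2_noise_gsd > 1.0:
            excess = co2 - spec.acr_params.co2_outdoor
            excess *= float(_lognormal(rng, 1.0, spec.co2_noise_gsd))
            co2 = spec.acr_params.co2_outdoor + excess

        samples.append(
            HomeSample(
                home_id=f"H{i + 1:0{width}d}",
                sample_date=date,
                season=season,
                urban=urban,
                volume_raw=volume,
                n_adults=n_adults,
                n_children=n_children,
                occupancy_fraction=occ_frac,
                co2_indoor=co2,
                indoor_conc=indoor,
                outdoor_conc=outdoor,
                true_acr=true_acr,
                spiked=spiked,
            )
        )
    return samples


# ---------------------------------------------------------------------------
# Tidy-table round trip

HOME_COLUMNS = [
    "home_id", "sample_date", "season", "urban", "volume_raw", "n_adults",
    "n_children", "occupancy_fraction", "co2_indoor", "true_acr", "spiked",
]
CONC_COLUMNS = ["home_id", "voc", "indoor_conc", "outdoor_conc"]


def cohort_to_tables(samples: Sequence[HomeSample]) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Split a cohort into a per-home metadata table and a long
    home x VOC concentration table (columns documented in
    :data:`HOME_COLUMNS` / :data:`CONC_COLUMNS`)."""
    home_rows = []
    conc_rows = []
    for s in samples:
        home_rows.append(
            {
                "home_id": s.home_id,
                "sample_date": s.sample_date.isoformat(),
                "season": s.season,
                "urban": s.urban,
                "volume_raw": s.volume_raw,
                "n_adults": s.n_adults,
                "n_children": s.n_children,
                "occupancy_fraction": s.occupancy_fraction,
                "co2_indoor": s.co2_indoor,
                "true_acr": s.true_acr,
                "spiked": s.spiked,
            }
        )
        for voc in s.indoor_conc:
            conc_rows.append(
                {
                    "home_id": s.home_id,
                    "voc": voc,
                    "indoor_conc": s.indoor_conc[voc],
                    "outdoor_conc": s.outdoor_conc.get(voc, np.nan),
                }
            )
    homes = pd.DataFrame(home_rows, columns=HOME_COLUMNS)
    conc = pd.DataFrame(conc_rows, columns=CONC_COLUMNS)
    return homes, conc


def tables_to_cohort(
    homes: pd.DataFrame, conc: pd.DataFrame
) -> List[HomeSample]:
    """Rebuild :class:`HomeSample` objects from the tidy tables.

    Missing optional columns (``true_acr``, ``spiked``, ``season``) are
    tolerated; season is derived from the sample date when absent.
    """
    required = {"home_id", "sample_date", "urban", "volume_raw", "n_adults",
                "n_children", "occupancy_fraction", "co2_indoor"}
    missing = required - set(homes.columns)
    if missing:
        raise ValueError(f"home table missing required columns: {sorted(missing)}")
    missing_c = set(CONC_COLUMNS) - set(conc.columns)
    if missing_c:
        raise ValueError(
            f"concentration table missing required columns: {sorted(missing_c)}"
        )

    by_home = {hid: grp for hid, grp in conc.groupby("home_id", sort=False)}
    samples = []
    for _, row in homes.iterrows():
        date = row["sample_date"]
        if isinstance(date, str):
            date = _dt.date.fromisoformat(date)
        elif isinstance(date, pd.Timestamp):
            date = date.date()
        grp = by_home.get(row["home_id"])
        if grp is None:
            raise ValueError(f"home {row['home_id']!r} has no concentration rows")
        indoor = dict(zip(grp["voc"], grp["indoor_conc"].astype(float)))
        outdoor = dict(zip(grp["voc"], grp["outdoor_conc"].astype(float)))
        true_acr = row.get("true_acr")
        samples.append(
            HomeSample(
                home_id=str(row["home_id"]),
                sample_date=date,
                season=row.get("season") or assign_season(date),
                urban=bool(row["urban"]),
                volume_raw=float(row["volume_raw"]),
                n_adults=int(row["n_adults"]),
                n_children=int(row["n_children"]),
                occupancy_fraction=float(row["occupancy_fraction"]),
                co2_indoor=float(row["co2_indoor"]),
                indoor_conc=indoor,
                outdoor_conc=outdoor,
                true_acr=None if true_acr is None or pd.isna(true_acr) else float(true_acr),
                spiked=bool(row.get("spiked", False)),
            )
        )
    return samples
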