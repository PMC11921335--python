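"""End-to-end exposure analysis as a model/results pair.

:class:`ExposureModel` is built from the two tidy cohort tables (per-home
metadata and long home x VOC concentrations) or directly from a synthetic
cohort spec.  ``fit()`` runs the full analysis — below-LOD policy, ACR
inference, aromatic outlier treatment, TVOC, time-averaged emission rates,
min-max normalization, LCR/HQ benchmarks, and the seasonal / urban-rural
rank tests — and returns an :class:`ExposureResults` carrying every
intermediate table, the test results and an exclusion log, with a
``summary()`` text report and a ``save()`` that writes the stable file
contract.

The whole fit is deterministic given the input tables and the config seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import config as _config
from .acr import AcrParams, acr_table, summarise_acr_by_season
from .cohort import CohortSpec, HomeSample, cohort_to_tables, generate_cohort, tables_to_cohort
from .emissions import class_total, emission_table, normalize_emissions, tvoc_table
from .nonparametric import boxplot_summary, bootstrap_ci, compare_groups, holm_adjust
from .outliers import DEFAULT_THRESHOLD, treat_table
from .risk import ExposureFactors, RiskTable, exceedance_summary, risk_table_for_cohort

logger = logging.getLogger("indoorvoc")

__all__ = ["PipelineConfig", "ExposureModel", "ExposureResults", "handle_below_lod"]

LOD_POLICIES = ("keep", "drop", "half-lod")


@dataclass
class PipelineConfig:
    """Everything the pipeline can be steered by.

    Defaults reproduce the standard analysis: outlier treatment restricted
    to the aromatic panel (BTEX + TMB) at threshold 3.5 one-sided, bundled
    toxicity table and exposure factors, alpha 0.05, 1000 bootstrap
    resamples, below-LOD values kept as reported.
    """

    acr_params: AcrParams = field(default_factory=AcrParams)
    outlier_vocs: Optional[List[str]] = None  # None -> BTEX + TMB classes
    outlier_threshold: float = DEFAULT_THRESHOLD
    outlier_two_sided: bool = False
    voc_classes: Optional[Dict[str, List[str]]] = None  # None -> bundled
    risk_table: Optional[RiskTable] = None  # None -> bundled
    exposure_factors: ExposureFactors = field(default_factory=ExposureFactors)
    alpha: float = 0.05
    n_resamples: int = 1000
    seed: int = 0
    lod: Optional[Union[float, Mapping[str, float]]] = None
    lod_policy: str = "keep"
    min_group_n: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if self.lod_policy not in LOD_POLICIES:
            raise ValueError(
                f"unknown lod_policy {self.lod_policy!r}; choose from {LOD_POLICIES}"
            )
        if self.voc_classes is None:
            self.voc_classes = _config.load_voc_classes()
        if self.outlier_vocs is None:
            self.outlier_vocs = list(self.voc_classes.get("btex", [])) + list(
                self.voc_classes.get("tmb", [])
            )
        if self.risk_table is None:
            self.risk_table = RiskTable.default()


def handle_below_lod(
    conc: pd.DataFrame,
    lod: Union[float, Mapping[str, float], None],
    policy: str,
    value_col: str = "indoor_conc",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply a below-LOD policy to a tidy concentration table.

    ``policy`` is one of ``keep`` (return unchanged), ``drop`` (remove rows
    whose value is below the VOC's LOD) or ``half-lod`` (replace them with
    LOD/2).  ``lod`` may be a scalar applied to every VOC or a per-VOC
    mapping (VOCs absent from the mapping are untouched).  Returns the
    treated table plus an exclusion log (home_id, voc, value, reason).
    """
    if policy not in LOD_POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {LOD_POLICIES}")
    log_cols = ["home_id", "voc", "value", "reason"]
    if policy == "keep" or lod is None:
        return conc, pd.DataFrame(columns=log_cols)

    if isinstance(lod, Mapping):
        lod_series = conc["voc"].map(lod)
    else:
        if float(lod) < 0:
            raise ValueError("lod must be non-negative")
        lod_series = pd.Series(float(lod), index=conc.index)
    below = conc[value_col].lt(lod_series).fillna(False)

    log = pd.DataFrame(
        {
            "home_id": conc.loc[below, "home_id"],
            "voc": conc.loc[below, "voc"],
            "value": conc.loc[below, value_col],
            "reason": f"below_lod_{policy}",
        },
        columns=log_cols,
    )
    if policy == "drop":
        return conc[~below].reset_index(drop=True), log.reset_index(drop=True)
    out = conc.copy()
    out.loc[below, value_col] = lod_series[below] / 2.0
    return out, log.reset_index(drop=True)


def _seasonal_summary(values: pd.Series, seasons: pd.Series,
                      n_resamples: int, seed: int) -> pd.DataFrame:
    """Per-season percentile summary plus bootstrap CI of the mean."""
    rows = []
    df = pd.DataFrame({"season": seasons.to_numpy(), "value": values.to_numpy()})
    for season, grp in df.groupby("season", sort=False):
        v = grp["value"].to_numpy()
        box = boxplot_summary(v)
        ci = bootstrap_ci(v, np.mean, n_resamples=n_resamples, seed=seed)
        rows.append(
            {
                "season": season,
                "n": len(v),
                "median": box.percentiles[50],
                "mean": float(np.mean(v)),
                "p5": box.percentiles[5],
                "p25": box.percentiles[25],
                "p75": box.percentiles[75],
                "p95": box.percentiles[95],
                "mean_ci_lower": ci.lower,
                "mean_ci_upper": ci.upper,
            }
        )
    return pd.DataFrame(rows)


class ExposureModel:
    """Indoor VOC exposure analysis over one home cohort.

    Parameters
    ----------
    homes
        Per-home metadata table (see ``cohort.HOME_COLUMNS``).
    conc
        Long home x VOC concentration table (``cohort.CONC_COLUMNS``).
    config
        :class:`PipelineConfig`; defaults reproduce the standard analysis.
    """

    def __init__(
        self,
        homes: pd.DataFrame,
        conc: pd.DataFrame,
        config: Optional[PipelineConfig] = None,
    ):
        required = {"home_id", "sample_date", "urban", "volume_raw", "n_adults",
                    "n_children", "occupancy_fraction", "co2_indoor"}
        missing = sorted(required - set(homes.columns))
        if missing:
            raise ValueError(f"home table missing required columns: {missing}")
        missing_c = sorted({"home_id", "voc", "indoor_conc"} - set(conc.columns))
        if missing_c:
            raise ValueError(f"concentration table missing required columns: {missing_c}")
        self.homes = homes.reset_index(drop=True)
        self.conc = conc.reset_index(drop=True)
        self.config = config or PipelineConfig()

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_cohort(
        cls, samples: Sequence[HomeSample], config: Optional[PipelineConfig] = None
    ) -> "ExposureModel":
        homes, conc = cohort_to_tables(samples)
        return cls(homes, conc, config)

    @classmethod
    def from_spec(
        cls, spec: CohortSpec, config: Optional[PipelineConfig] = None
    ) -> "ExposureModel":
        """Simulate a cohort from ``spec`` and wrap it in a model."""
        return cls.from_cohort(generate_cohort(spec), config)

    @classmethod
    def from_files(
        cls,
        homes_path: str | Path,
        conc_path: str | Path,
        config: Optional[PipelineConfig] = None,
        sep: str = ",",
    ) -> "ExposureModel":
        homes = pd.read_csv(homes_path, sep=sep)
        conc = pd.read_csv(conc_path, sep=sep)
        return cls(homes, conc, config)

    # -- fitting ----------------------------------------------------------
    def fit(self) -> "ExposureResults":
        cfg = self.config
        warnings: List[str] = []
        exclusions: List[pd.DataFrame] = []

        # 1. below-LOD policy (must precede the log-domain outlier step)
        conc, lod_log = handle_below_lod(self.conc, cfg.lod, cfg.lod_policy)
        if not lod_log.empty:
            exclusions.append(lod_log)
            logger.info("below-LOD policy %r affected %d rows", cfg.lod_policy, len(lod_log))

        # 2. ACR inference (homes violating the steady-state balance are
        #    excluded from ACR- and emission-based analyses, never silently)
        samples = tables_to_cohort(self.homes, conc)
        good, acr_excluded = [], []
        for s in samples:
            if s.co2_indoor <= cfg.acr_params.co2_outdoor:
                acr_excluded.append(
                    {"home_id": s.home_id, "voc": "", "value": s.co2_indoor,
                     "reason": "co2_not_above_outdoor"})
            elif s.n_adults + s.n_children < 1:
                acr_excluded.append(
                    {"home_id": s.home_id, "voc": "", "value": 0,
                     "reason": "no_occupants"})
            else:
                good.append(s)
        if acr_excluded:
            exclusions.append(pd.DataFrame(acr_excluded))
            warnings.append(f"{len(acr_excluded)} home(s) excluded from ACR inference")
        acr = acr_table(good, cfg.acr_params)
        acr_seasonal = (
            summarise_acr_by_season(acr, n_resamples=cfg.n_resamples, seed=cfg.seed)
            if not acr.empty else pd.DataFrame()
        )

        # 3. aromatic outlier treatment (indoor concentrations)
        treatable = [v for v in cfg.outlier_vocs if v in set(conc["voc"])]
        skipped = sorted(set(cfg.outlier_vocs) - set(treatable))
        if skipped:
            warnings.append(f"outlier scope VOCs absent from data: {skipped}")
        treated_conc, outlier_report = treat_table(
            conc, treatable, threshold=cfg.outlier_threshold,
            two_sided=cfg.outlier_two_sided,
        )
        if not outlier_report.empty:
            exclusions.append(
                outlier_report[["home_id", "voc", "value"]].assign(
                    reason="modified_z_outlier"
                )
            )

        # 4. TVOC (raw quantified concentrations, by definition)
        tvoc = tvoc_table(conc)
        # season/urban metadata from the parsed samples (season is derived
        # from the sample date when the input table lacks the column)
        meta = pd.DataFrame(
            {"home_id": [s.home_id for s in samples],
             "season": [s.season for s in samples],
             "urban": [s.urban for s in samples]})
        tvoc = tvoc.merge(meta, on="home_id", how="left")
        tvoc_seasonal = _seasonal_summary(
            tvoc["tvoc"], tvoc["season"], cfg.n_resamples, cfg.seed
        )

        # 5. emission rates (raw concentrations; ACR-excluded homes drop out)
        emissions = emission_table(conc, acr)
        n_skipped = len(conc.merge(acr[["home_id"]], on="home_id")) - len(emissions)
        if n_skipped:
            warnings.append(
                f"{n_skipped} concentration row(s) without an outdoor value "
                "skipped in emission rates"
            )
        normalized = (
            normalize_emissions(emissions)
            if emissions["voc"].value_counts().ge(2).all() and not emissions.empty
            and emissions.groupby("voc")["q"].nunique().gt(1).all()
            else pd.DataFrame(columns=["home_id", "voc", "x_hat"])
        )
        if normalized.empty and not emissions.empty:
            warnings.append("normalization skipped (constant or singleton VOC series)")

        # per-home class totals
        def _totals(records: pd.DataFrame, value_col: str) -> pd.DataFrame:
            out = pd.DataFrame({"home_id": records["home_id"].drop_duplicates()})
            out["total"] = class_total(
                records, set(records["voc"]), value_col=value_col
            ).to_numpy()
            mono = cfg.voc_classes.get("monoterpenes", [])
            if mono:
                out["monoterpenes"] = class_total(
                    records, mono, value_col=value_col
                ).to_numpy()
            return out.merge(meta, on="home_id", how="left")

        emission_totals = _totals(emissions, "q") if not emissions.empty else pd.DataFrame()
        normalized_totals = _totals(normalized, "x_hat") if not normalized.empty else pd.DataFrame()

        seasonal_emissions = {}
        for name, tbl, col in (
            ("total_emission", emission_totals, "total"),
            ("monoterpene_emission", emission_totals, "monoterpenes"),
            ("normalized_total", normalized_totals, "total"),
            ("normalized_monoterpenes", normalized_totals, "monoterpenes"),
        ):
            if not tbl.empty and col in tbl:
                seasonal_emissions[name] = _seasonal_summary(
                    tbl[col], tbl["season"], cfg.n_resamples, cfg.seed
                )

        # 6. risk benchmarks on indoor concentrations
        risk_results = risk_table_for_cohort(
            conc, cfg.risk_table, cfg.exposure_factors
        )
        assessed_vocs = set(risk_results["voc"])
        unassessed = sorted(set(conc["voc"]) - assessed_vocs)
        if unassessed:
            warnings.append(
                f"no IUR/RfC available, excluded from risk benchmarks: {unassessed}"
            )
        exceedance = (
            exceedance_summary(risk_results) if not risk_results.empty else pd.DataFrame()
        )

        # 7. rank-based comparisons
        tests = self._run_tests(
            treated_conc, meta, acr, tvoc, emission_totals, normalized_totals, warnings
        )

        exclusion_log = (
            pd.concat(exclusions, ignore_index=True)
            if exclusions
            else pd.DataFrame(columns=["home_id", "voc", "value", "reason"])
        )
        return ExposureResults(
            model=self,
            config=cfg,
            acr=acr,
            acr_seasonal=acr_seasonal,
            treated_conc=treated_conc,
            outlier_report=outlier_report,
            tvoc=tvoc,
            tvoc_seasonal=tvoc_seasonal,
            emissions=emissions,
            normalized=normalized,
            emission_totals=emission_totals,
            normalized_totals=normalized_totals,
            seasonal_emissions=seasonal_emissions,
            risk_results=risk_results,
            exceedance=exceedance,
            tests=tests,
            exclusions=exclusion_log,
            warnings=warnings,
        )

    def _run_tests(
        self,
        treated_conc: pd.DataFrame,
        meta: pd.DataFrame,
        acr: pd.DataFrame,
        tvoc: pd.DataFrame,
        emission_totals: pd.DataFrame,
        normalized_totals: pd.DataFrame,
        warnings: List[str],
    ) -> pd.DataFrame:
        cfg = self.config
        rows: List[dict] = []

        def _enough(values: pd.Series, labels: pd.Series) -> bool:
            counts = pd.DataFrame({"v": values, "g": labels}).groupby("g")["v"].count()
            return len(counts) >= 2 and (counts >= cfg.min_group_n).sum() >= 2

        # urban vs rural on treated indoor aromatics: one BM test per VOC,
        # Holm-adjusted across the aromatic family
        aromatic = treated_conc[treated_conc["voc"].isin(cfg.outlier_vocs)].merge(
            meta[["home_id", "urban"]], on="home_id", how="left"
        )
        bm_rows = []
        for voc, grp in aromatic.groupby("voc", sort=False):
            labels = grp["urban"].map({True: "urban", False: "rural"})
            if not _enough(grp["indoor_conc"], labels):
                continue
            res = compare_groups(grp["indoor_conc"], labels, alpha=cfg.alpha)[0]
            bm_rows.append(
                {"metric": f"indoor_{voc}", "grouping": "urban_rural",
                 "test": res.test_name, "groups": "rural|urban",
                 "statistic": res.statistic, "p_raw": res.p_raw,
                 "effect": res.effect}
            )
        if bm_rows:
            adj = holm_adjust([r["p_raw"] for r in bm_rows])
            for r, a in zip(bm_rows, adj):
                r["p_adjusted"] = a
            rows.extend(bm_rows)
        elif len(aromatic):
            warnings.append("urban/rural comparison skipped (insufficient group sizes)")

        # seasonal comparisons: KW omnibus + Holm-adjusted Dunn pairs
        seasonal_metrics = [("acr", acr, "acr")]
        seasonal_metrics.append(("tvoc", tvoc, "tvoc"))
        for name, tbl, col in (
            ("total_emission", emission_totals, "total"),
            ("monoterpene_emission", emission_totals, "monoterpenes"),
            ("normalized_total", normalized_totals, "total"),
            ("normalized_monoterpenes", normalized_totals, "monoterpenes"),
        ):
            if not tbl.empty and col in tbl:
                seasonal_metrics.append((name, tbl, col))
        for name, tbl, col in seasonal_metrics:
            if tbl.empty or "season" not in tbl:
                continue
            if not _enough(tbl[col], tbl["season"]):
                warnings.append(f"seasonal tests for {name} skipped (insufficient n)")
                continue
            for res in compare_groups(tbl[col], tbl["season"], alpha=cfg.alpha):
                rows.append(
                    {"metric": name, "grouping": "season", "test": res.test_name,
                     "groups": "|".join(res.groups), "statistic": res.statistic,
                     "p_raw": res.p_raw, "p_adjusted": res.p_adjusted,
                     "effect": res.effect}
                )
        return pd.DataFrame(
            rows,
            columns=["metric", "grouping", "test", "groups", "statistic",
                     "p_raw", "p_adjusted", "effect"],
        )


@dataclass
class ExposureResults:
    """Fitted exposure analysis: tables, tests, diagnostics."""

    model: ExposureModel
    config: PipelineConfig
    acr: pd.DataFrame
    acr_seasonal: pd.DataFrame
    treated_conc: pd.DataFrame
    outlier_report: pd.DataFrame
    tvoc: pd.DataFrame
    tvoc_seasonal: pd.DataFrame
    emissions: pd.DataFrame
    normalized: pd.DataFrame
    emission_totals: pd.DataFrame
    normalized_totals: pd.DataFrame
    seasonal_emissions: Dict[str, pd.DataFrame]
    risk_results: pd.DataFrame
    exceedance: pd.DataFrame
    tests: pd.DataFrame
    exclusions: pd.DataFrame
    warnings: List[str]

    def summary(self) -> str:
        """Human-readable report of the fitted analysis."""
        lines = []
        n_homes = len(self.model.homes)
        lines.append("Indoor VOC exposure analysis")
        lines.append("=" * 60)
        lines.append(f"homes: {n_homes}   VOCs: {self.model.conc['voc'].nunique()}")
        if self.warnings:
            lines.append("warnings:")
            lines.extend(f"  - {w}" for w in self.warnings)
        if not self.acr_seasonal.empty:
            lines.append("")
            lines.append("Seasonal air change rate (h^-1)")
            lines.append(self.acr_seasonal.round(3).to_string(index=False))
        if not self.tvoc_seasonal.empty:
            lines.append("")
            lines.append("Seasonal TVOC concentration (ug m^-3)")
            lines.append(self.tvoc_seasonal.round(1).to_string(index=False))
        for name, tbl in self.seasonal_emissions.items():
            lines.append("")
            unit = "(0-1 scale)" if name.startswith("normalized") else "(ug h^-1)"
            lines.append(f"Seasonal {name.replace('_', ' ')} {unit}")
            lines.append(tbl.round(3).to_string(index=False))
        if not self.outlier_report.empty:
            lines.append("")
            lines.append(
                f"Outlier treatment removed {len(self.outlier_report)} "
                f"observation(s) (modified Z > "
                f"{self.config.outlier_threshold})"
            )
        if not self.exceedance.empty:
            lines.append("")
            lines.append("Risk benchmark exceedance fractions")
            lines.append(self.exceedance.round(3).to_string(index=False))
        if not self.tests.empty:
            lines.append("")
            lines.append("Hypothesis tests (two-sided, Holm-adjusted)")
            lines.append(self.tests.round(4).to_string(index=False))
        return "\n".join(lines)

    def save(self, outdir: str | Path, sep: str = ",") -> None:
        """Write the stable table contract under ``outdir``.

        One CSV per table plus ``summary.txt`` and ``report.json`` (the
        seasonal summaries and warnings in machine-readable form).
        """
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "acr.csv": self.acr,
            "acr_seasonal.csv": self.acr_seasonal,
            "concentrations_treated.csv": self.treated_conc,
            "outlier_report.csv": self.outlier_report,
            "tvoc.csv": self.tvoc,
            "tvoc_seasonal.csv": self.tvoc_seasonal,
            "emissions.csv": self.emissions,
            "emissions_normalized.csv": self.normalized,
            "emission_totals.csv": self.emission_totals,
            "normalized_totals.csv": self.normalized_totals,
            "risk_results.csv": self.risk_results,
            "risk_exceedance.csv": self.exceedance,
            "tests.csv": self.tests,
            "exclusions.csv": self.exclusions,
        }
        for fname, tbl in tables.items():
            tbl.to_csv(out / fname, sep=sep, index=False)
        for name, tbl in self.seasonal_emissions.items():
            tbl.to_csv(out / f"seasonal_{name}.csv", sep=sep, index=False)
        (out / "summary.txt").write_text(self.summary() + "\n")
        report = {
            "n_homes": int(len(self.model.homes)),
            "warnings": self.warnings,
            "seasonal": {
                name: tbl.to_dict(orient="records")
                for name, tbl in self.seasonal_emissions.items()
            },
            "config": {
                "alpha": self.config.alpha,
                "n_resamples": self.config.n_resamples,
                "seed": self.config.seed,
                "outlier_threshold": self.config.outlier_threshold,
                "lod_policy": self.config.lod_policy,
                "exposure_factors": dataclasses.asdict(self.config.exposure_factors),
            },
        }
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
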