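"""Config-file handling: cohort specs, VOC classes, risk tables.

All tunable inputs — the synthetic-cohort parameters, VOC class
memberships, toxicity values and exposure factors — live in editable
YAML/CSV files rather than code.  The bundled defaults under
``indoorvoc/data`` document the schema by example.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from .acr import AcrParams
from .cohort import CohortSpec, VocParams
from .risk import ExposureFactors, RiskTable

__all__ = [
    "cohort_spec_to_dict",
    "cohort_spec_from_dict",
    "save_cohort_spec",
    "load_cohort_spec",
    "load_voc_classes",
    "load_risk_table",
    "exposure_factors_from_dict",
]


def cohort_spec_to_dict(spec: CohortSpec) -> dict:
    """Plain-dict (YAML-ready) form of a cohort spec."""
    return {
        "n_homes": spec.n_homes,
        "seed": spec.seed,
        "urban_fraction": spec.urban_fraction,
        "urban_aromatic_multiplier": spec.urban_aromatic_multiplier,
        "spike_prob": spec.spike_prob,
        "spike_multiplier": spec.spike_multiplier,
        "volume_range": list(spec.volume_range),
        "adult_choices": list(spec.adult_choices),
        "child_choices": list(spec.child_choices),
        "occupancy_fraction_range": list(spec.occupancy_fraction_range),
        "start_date": spec.start_date.isoformat(),
        "n_days": spec.n_days,
        "co2_noise_gsd": spec.co2_noise_gsd,
        "acr_params": dataclasses.asdict(spec.acr_params),
        "seasonal_acr": {
            season: {"median": med, "gsd": gsd}
            for season, (med, gsd) in spec.seasonal_acr.items()
        },
        "voc_panel": {
            voc: dataclasses.asdict(p) for voc, p in spec.voc_panel.items()
        },
    }


def cohort_spec_from_dict(d: dict) -> CohortSpec:
    """Build (and validate) a cohort spec from its dict form.

    Omitted keys fall back to the package defaults, so a config file only
    needs the fields it overrides.
    """
    kwargs: dict = {}
    simple = (
        "n_homes", "seed", "urban_fraction", "urban_aromatic_multiplier",
        "spike_prob", "spike_multiplier", "n_days", "co2_noise_gsd",
    )
    for key in simple:
        if key in d:
            kwargs[key] = d[key]
    for key in ("volume_range", "adult_choices", "child_choices",
                "occupancy_fraction_range"):
        if key in d:
            kwargs[key] = tuple(d[key])
    if "start_date" in d:
        sd = d["start_date"]
        kwargs["start_date"] = (
            sd if isinstance(sd, _dt.date) else _dt.date.fromisoformat(str(sd))
        )
    if "acr_params" in d:
        kwargs["acr_params"] = AcrParams(**d["acr_params"])
    if "seasonal_acr" in d:
        kwargs["seasonal_acr"] = {
            season: (float(v["median"]), float(v["gsd"]))
            for season, v in d["seasonal_acr"].items()
        }
    if "voc_panel" in d:
        kwargs["voc_panel"] = {
            voc: VocParams(**params) for voc, params in d["voc_panel"].items()
        }
    spec = CohortSpec(**kwargs)
    spec.validate()
    return spec


def save_cohort_spec(spec: CohortSpec, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cohort_spec_to_dict(spec), f, sort_keys=False)


def load_cohort_spec(path: Optional[str | Path] = None) -> CohortSpec:
    """Load a cohort spec from YAML; the bundled default when no path."""
    if path is None:
        with resources.files("indoorvoc.data").joinpath("default_cohort.yaml").open() as f:
            return cohort_spec_from_dict(yaml.safe_load(f))
    with open(path) as f:
        return cohort_spec_from_dict(yaml.safe_load(f))


def load_voc_classes(path: Optional[str | Path] = None) -> Dict[str, List[str]]:
    """VOC class memberships (btex, tmb, monoterpenes, ...)."""
    if path is None:
        with resources.files("indoorvoc.data").joinpath("voc_classes.yaml").open() as f:
            classes = yaml.safe_load(f)
    else:
        with open(path) as f:
            classes = yaml.safe_load(f)
    if not isinstance(classes, dict) or not classes:
        raise ValueError("VOC class config must be a non-empty mapping")
    return {str(k): [str(v) for v in vals] for k, vals in classes.items()}


def load_risk_table(path: Optional[str | Path] = None) -> RiskTable:
    return RiskTable.default() if path is None else RiskTable.from_csv(path)


def exposure_factors_from_dict(d: dict) -> ExposureFactors:
    return ExposureFactors(**d)
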