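"""Robust outlier treatment for episodic concentration bursts.

Indoor aromatics (BTEX, trimethylbenzenes) show intense but episodic
spikes — most visibly after painting and decorating — that would distort
medians and rank statistics.  Each VOC's concentrations are therefore
log-transformed and scored with a modified Z-score built from the median
and the median absolute deviation (MAD):

    mz_i = 0.6745 * (log x_i - median(log x)) / MAD(log x)

The 0.6745 factor (the 0.75 normal quantile) scales MAD to the normal
standard deviation so mz is comparable with an ordinary Z-score.  Values
with mz above +3.5 are removed; by default the filter is one-sided because
episodic sources only inflate concentrations.  Retained values are the
original concentrations, untouched — the log transform and its inverse
cancel exactly.

The procedure is deliberately single-pass: scores are computed once on the
full group and the flagged values removed once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "MZ_SCALE",
    "DEFAULT_THRESHOLD",
    "OutlierReport",
    "modified_z_scores",
    "treat_outliers",
    "treat_table",
]

MZ_SCALE = 0.6745
DEFAULT_THRESHOLD = 3.5


@dataclass
class OutlierReport:
    """Outcome of outlier treatment for one VOC group."""

    voc: str
    values_in: np.ndarray  # µg m-3
    log_values: np.ndarray
    group_median: float  # median of log values
    mad: float  # MAD of log values
    scores: np.ndarray
    flagged: np.ndarray  # indices into values_in
    values_out: np.ndarray  # retained, original scale

    def __post_init__(self) -> None:
        assert len(self.scores) == len(self.values_in)
        assert len(self.flagged) + len(self.values_out) == len(self.values_in)


def _validate(values: np.ndarray) -> None:
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need a 1-D sequence of at least two values")
    if np.any(~np.isfinite(values)):
        raise ValueError("values must be finite")
    if np.any(values <= 0):
        bad = np.flatnonzero(values <= 0)[0]
        raise ValueError(
            f"value at index {bad} is {values[bad]}; the log transform requires "
            "strictly positive concentrations (handle below-LOD values upstream)"
        )


def modified_z_scores(values: Sequence[float]) -> np.ndarray:
    """MAD-based modified Z-scores of log-transformed concentrations.

    Input order is preserved.  Raises on non-positive values and on a
    degenerate group (MAD = 0, i.e. at least half the values identical):
    the score is then undefined and substituting a fallback scale would
    silently change what "outlier" means.
    """
    x = np.asarray(values, dtype=float)
    _validate(x)
    logs = np.log(x)
    med = float(np.median(logs))
    mad = float(np.median(np.abs(logs - med)))
    if mad == 0.0:
        raise ValueError(
            "MAD of the log-transformed group is zero (>= half the values are "
            "identical); modified Z-scores are undefined for this group"
        )
    return MZ_SCALE * (logs - med) / mad


def treat_outliers(
    values: Sequence[float],
    threshold: float = DEFAULT_THRESHOLD,
    voc: str = "",
    two_sided: bool = False,
) -> OutlierReport:
    """Score one VOC group and remove its high outliers.

    Only values with ``score > threshold`` are removed (``|score| >
    threshold`` when ``two_sided``); everything retained is returned at its
    original concentration, bit for bit.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    x = np.asarray(values, dtype=float)
    scores = modified_z_scores(x)
    if two_sided:
        mask = np.abs(scores) > threshold
    else:
        mask = scores > threshold
    flagged = np.flatnonzero(mask)
    logs = np.log(x)
    med = float(np.median(logs))
    mad = float(np.median(np.abs(logs - med)))
    return OutlierReport(
        voc=voc,
        values_in=x,
        log_values=logs,
        group_median=med,
        mad=mad,
        scores=scores,
        flagged=flagged,
        values_out=x[~mask],
    )


def treat_table(
    conc: pd.DataFrame,
    vocs: Sequence[str],
    value_col: str = "indoor_conc",
    threshold: float = DEFAULT_THRESHOLD,
    two_sided: bool = False,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Apply outlier treatment per VOC over a tidy concentration table.

    Parameters
    ----------
    conc
        Long table with ``home_id``, ``voc`` and ``value_col`` columns.
    vocs
        VOC names to treat (typically the aromatic panel); rows for other
        VOCs pass through untouched.

    Returns
    -------
    treated, report
        ``treated`` is ``conc`` minus the flagged rows; ``report`` has one
        row per flagged observation (home_id, voc, value, score).
    """
    treated_parts: List[pd.DataFrame] = []
    report_rows = []
    for voc_name, grp in conc.groupby("voc", sort=False):
        if voc_name not in vocs or len(grp) < 2:
            treated_parts.append(grp)
            continue
        rep = treat_outliers(
            grp[value_col].to_numpy(), threshold=threshold, voc=str(voc_name),
            two_sided=two_sided,
        )
        keep = np.ones(len(grp), dtype=bool)
        keep[rep.flagged] = False
        treated_parts.append(grp.iloc[keep])
        for idx in rep.flagged:
            report_rows.append(
                {
                    "home_id": grp.iloc[int(idx)]["home_id"],
                    "voc": voc_name,
                    "value": rep.values_in[idx],
                    "score": rep.scores[idx],
                    "threshold": threshold,
                }
            )
    treated = pd.concat(treated_parts, ignore_index=True) if treated_parts else conc
    report = pd.DataFrame(
        report_rows, columns=["home_id", "voc", "value", "score", "threshold"]
    )
    return treated, report
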