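"""Rank-based comparison stack for skewed, heteroscedastic exposure data.

Indoor concentration and emission data are non-normal and groupwise
heteroscedastic, so all group comparisons here are rank-based:

* :func:`brunner_munzel` — two-sample test of stochastic equality.  Its
  effect measure is the relative effect p = P(X < Y) + 0.5 P(X = Y); unlike
  the Mann-Whitney U test it assumes neither equal variances nor a location
  shift.  The studentized statistic is referred to a t distribution with
  Satterthwaite-type degrees of freedom; an exact permutation reference is
  available for small samples.
* :func:`kruskal_wallis` — k-group omnibus test (ties-corrected H, chi2
  reference).
* :func:`dunn_posthoc` — pairwise z tests on the pooled midranks after a
  significant omnibus test, Holm-adjusted by default.
* :func:`holm_adjust` — step-down familywise-error correction.
* :func:`bootstrap_ci` — seeded percentile bootstrap confidence interval of
  any statistic (default 1000 resamples).
* :func:`boxplot_summary` — the 5/25/50/75/95 percentile summary used for
  all distributional reporting, with values outside the 5-95 band listed as
  outliers.

Midranks are used for all ties.  All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as _sps
from scipy.stats import rankdata

__all__ = [
    "TestResult",
    "BootstrapCI",
    "BoxplotSummary",
    "brunner_munzel",
    "kruskal_wallis",
    "dunn_posthoc",
    "holm_adjust",
    "bootstrap_ci",
    "boxplot_summary",
    "compare_groups",
]


@dataclass(frozen=True)
class TestResult:
    """One hypothesis-test outcome."""

    test_name: str
    statistic: float
    p_raw: float
    groups: Tuple[str, ...]
    p_adjusted: Optional[float] = None
    effect: Optional[float] = None  # relative effect (BM) / mean-rank diff (Dunn)
    df: Optional[float] = None
    extra: Dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class BootstrapCI:
    point: float
    lower: float
    upper: float
    n_resamples: int
    seed: int


@dataclass(frozen=True)
class BoxplotSummary:
    percentiles: Dict[int, float]  # keys 5, 25, 50, 75, 95
    lower_outliers: np.ndarray
    upper_outliers: np.ndarray
    n: int


def _clean(sample, name: str, min_n: int = 1) -> np.ndarray:
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if np.any(~np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    if len(x) < min_n:
        raise ValueError(f"{name} needs at least {min_n} observations, got {len(x)}")
    return x


def _bm_statistic(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """(studentized statistic, Satterthwaite df, relative effect).

    Relative effect p_hat = P(X < Y) + 0.5 P(X = Y), estimated from the
    pooled midranks; variance estimated from the placements
    (pooled rank minus within-group rank).
    """
    nx, ny = len(x), len(y)
    ranks = rankdata(np.concatenate([x, y]))
    rx, ry = ranks[:nx], ranks[nx:]
    rx_mean, ry_mean = rx.mean(), ry.mean()
    p_hat = (ry_mean - (ny + 1) / 2.0) / nx

    wx = rankdata(x)
    wy = rankdata(y)
    sx2 = np.sum((rx - wx - rx_mean + (nx + 1) / 2.0) ** 2) / (nx - 1)
    sy2 = np.sum((ry - wy - ry_mean + (ny + 1) / 2.0) ** 2) / (ny - 1)
    pooled = nx * sx2 + ny * sy2
    if pooled == 0.0:
        # All observations tied across both groups: no rank information.
        raise ValueError(
            "degenerate samples: all values tied across both groups"
        )
    w = nx * ny * (ry_mean - rx_mean) / ((nx + ny) * np.sqrt(pooled))
    df = pooled**2 / ((nx * sx2) ** 2 / (nx - 1) + (ny * sy2) ** 2 / (ny - 1))
    return float(w), float(df), float(p_hat)


def brunner_munzel(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.05,
    method: str = "t",
    n_permutations: Optional[int] = None,
    seed: int = 0,
    labels: Tuple[str, str] = ("x", "y"),
) -> TestResult:
    """Two-sided Brunner-Munzel test of P(X < Y) + 0.5 P(X = Y) = 0.5.

    Parameters
    ----------
    method
        ``"t"`` (default): studentized statistic against a t distribution
        with Satterthwaite-type degrees of freedom.  ``"permutation"``:
        the same statistic referred to its group-label permutation
        distribution — exhaustive when the number of splits is modest
        (<= ~200k), otherwise ``n_permutations`` Monte-Carlo draws.
    """
    x = _clean(x, "x", min_n=2)
    y = _clean(y, "y", min_n=2)
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    w, df, p_hat = _bm_statistic(x, y)

    if method == "t":
        if np.isclose(w, 0.0):
            p = 1.0
        else:
            p = float(2.0 * _sps.t.sf(abs(w), df))
    elif method == "permutation":
        p = _bm_permutation_p(x, y, w, n_permutations, seed)
        df = float("nan")
    else:
        raise ValueError(f"unknown method {method!r}")

    return TestResult(
        test_name="brunner-munzel",
        statistic=w,
        p_raw=min(p, 1.0),
        groups=labels,
        effect=p_hat,
        df=df,
        extra={"alpha": alpha},
    )


def _bm_permutation_p(
    x: np.ndarray,
    y: np.ndarray,
    w_obs: float,
    n_permutations: Optional[int],
    seed: int,
    exhaustive_limit: int = 200_000,
) -> float:
    """Permutation p-value of the BM statistic under label exchange.

    Degenerate permutations (all within-group placements equal, variance
    zero) are counted as |W| = 0, i.e. never more extreme than a non-zero
    observed statistic.
    """
    from math import comb

    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    n_splits = comb(n, nx)

    def stat_for(idx: np.ndarray) -> float:
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        try:
            w, _, _ = _bm_statistic(pooled[mask], pooled[~mask])
        except ValueError:
            return 0.0
        return w

    tol = 1e-12
    if n_splits <= exhaustive_limit:
        count = 0
        for idx in combinations(range(n), nx):
            if abs(stat_for(np.asarray(idx))) >= abs(w_obs) - tol:
                count += 1
        return count / n_splits

    rng = np.random.default_rng(seed)
    n_permutations = n_permutations or 10_000
    count = 0
    for _ in range(n_permutations):
        idx = rng.choice(n, size=nx, replace=False)
        if abs(stat_for(idx)) >= abs(w_obs) - tol:
            count += 1
    # add-one smoothing keeps the Monte-Carlo p valid
    return (count + 1) / (n_permutations + 1)


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
) -> TestResult:
    """Ties-corrected Kruskal-Wallis H test against chi2(k-1).

    With every observation equal, the ties correction removes all rank
    variance; H is defined as 0 (no evidence of any difference).
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    arrs = [_clean(g, f"group {i}", min_n=1) for i, g in enumerate(groups)]
    labels = tuple(labels) if labels is not None else tuple(
        f"group{i}" for i in range(len(arrs))
    )
    pooled = np.concatenate(arrs)
    n = len(pooled)
    if n < 2:
        raise ValueError("need at least two observations in total")
    ranks = rankdata(pooled)

    h = 0.0
    start = 0
    for a in arrs:
        r = ranks[start : start + len(a)]
        h += len(a) * (r.mean() - (n + 1) / 2.0) ** 2
        start += len(a)
    h *= 12.0 / (n * (n + 1))

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (n**3 - n)
    if correction == 0.0:
        h_corr = 0.0
        p = 1.0
    else:
        h_corr = h / correction
        p = float(_sps.chi2.sf(h_corr, df=len(arrs) - 1))
    return TestResult(
        test_name="kruskal-wallis",
        statistic=h_corr,
        p_raw=p,
        groups=labels,
        df=float(len(arrs) - 1),
    )


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    adjust: str = "holm",
) -> List[TestResult]:
    """Pairwise Dunn z tests on the pooled midranks.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with
    ties term T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p-values,
    adjusted across the k(k-1)/2 pairs by Holm (or left raw with
    ``adjust="none"``).
    """
    if len(groups) < 2:
        raise ValueError("dunn_posthoc needs at least two groups")
    if adjust not in ("holm", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    arrs = [_clean(g, f"group {i}", min_n=1) for i, g in enumerate(groups)]
    labels = list(labels) if labels is not None else [
        f"group{i}" for i in range(len(arrs))
    ]
    pooled = np.concatenate(arrs)
    n = len(pooled)
    ranks = rankdata(pooled)
    mean_ranks = []
    start = 0
    for a in arrs:
        mean_ranks.append(ranks[start : start + len(a)].mean())
        start += len(a)

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term

    results = []
    raw_ps = []
    for i, j in combinations(range(len(arrs)), 2):
        diff = mean_ranks[i] - mean_ranks[j]
        se2 = var_base * (1.0 / len(arrs[i]) + 1.0 / len(arrs[j]))
        if se2 <= 0:
            z, p = 0.0, 1.0
        else:
            z = diff / np.sqrt(se2)
            p = float(2.0 * _sps.norm.sf(abs(z)))
        raw_ps.append(p)
        results.append(
            TestResult(
                test_name="dunn",
                statistic=float(z),
                p_raw=p,
                groups=(labels[i], labels[j]),
                effect=float(diff),
            )
        )
    if adjust == "holm":
        adj = holm_adjust(raw_ps)
        results = [
            TestResult(
                test_name=r.test_name,
                statistic=r.statistic,
                p_raw=r.p_raw,
                groups=r.groups,
                p_adjusted=a,
                effect=r.effect,
            )
            for r, a in zip(results, adj)
        ]
    return results


def holm_adjust(p_values: Sequence[float]) -> List[float]:
    """Holm step-down adjusted p-values, in the input order.

    Sorted ascending, p_(i) is multiplied by (m - i + 1); a running maximum
    enforces monotonicity and results are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 0.0
    for rank_idx, orig_idx in enumerate(order):
        running = max(running, (m - rank_idx) * p[orig_idx])
        adj_sorted[rank_idx] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out.tolist()


def bootstrap_ci(
    values: Sequence[float],
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_resamples: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> BootstrapCI:
    """Seeded percentile bootstrap CI of ``statistic``.

    Resamples with replacement ``n_resamples`` times and returns the
    (1-level)/2 and 1-(1-level)/2 percentiles of the resample statistics.
    Deterministic for a given seed.
    """
    x = _clean(values, "values", min_n=1)
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_resamples, len(x)))
    try:
        # vectorized path for axis-aware statistics (np.mean, np.median, ...)
        stats = np.asarray(statistic(x[idx], axis=1))
        if stats.shape != (n_resamples,):
            raise TypeError
    except TypeError:
        stats = np.apply_along_axis(statistic, 1, x[idx])
    lo, hi = np.percentile(stats, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    point = float(statistic(x))
    return BootstrapCI(
        point=point,
        lower=float(min(lo, point)),
        upper=float(max(hi, point)),
        n_resamples=n_resamples,
        seed=seed,
    )


def boxplot_summary(values: Sequence[float]) -> BoxplotSummary:
    """5/25/50/75/95 percentile summary with 5-95-band outliers.

    Percentiles use linear interpolation between order statistics
    (numpy's default rule).
    """
    x = _clean(values, "values", min_n=1)
    qs = np.percentile(x, [5, 25, 50, 75, 95])
    pct = {5: float(qs[0]), 25: float(qs[1]), 50: float(qs[2]),
           75: float(qs[3]), 95: float(qs[4])}
    return BoxplotSummary(
        percentiles=pct,
        lower_outliers=np.sort(x[x < pct[5]]),
        upper_outliers=np.sort(x[x > pct[95]]),
        n=len(x),
    )


def compare_groups(
    values: Sequence[float],
    group_labels: Sequence[str],
    alpha: float = 0.05,
) -> List[TestResult]:
    """Run the comparison appropriate to the number of groups.

    Two groups: Brunner-Munzel.  More: Kruskal-Wallis omnibus followed by
    Holm-adjusted Dunn pairwise tests.  Groups with fewer than two
    observations are excluded.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if len(values) != len(labels):
        raise ValueError("values and group_labels must have equal length")
    uniq = [g for g in dict.fromkeys(labels.tolist())]
    groups = {g: values[labels == g] for g in uniq}
    groups = {g: v for g, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need at least two groups with >= 2 observations each")
    names = list(groups)
    if len(names) == 2:
        return [
            brunner_munzel(
                groups[names[0]], groups[names[1]], alpha=alpha,
                labels=(names[0], names[1]),
            )
        ]
    omnibus = kruskal_wallis([groups[g] for g in names], labels=names)
    pairwise = dunn_posthoc([groups[g] for g in names], labels=names)
    return [omnibus, *pairwise]
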