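"""Opportunity-for-selection indices and bootstrap confidence intervals.

The opportunity for selection on a fitness component ``x`` is its squared
coefficient of variation, ``var(x) / mean(x)**2`` (sample variance, n−1
denominator).  Applied to male reproductive success ``T`` it gives ``I``,
to mating success ``M`` it gives ``I_S`` (the opportunity for
pre-copulatory sexual selection), and to paternity share ``P`` it gives
``I_P`` (post-copulatory).  Uncertainty is quantified with a percentile
bootstrap over males (optionally over groups); two treatment estimates are
called significantly different only when their intervals do not overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def opportunity_index(values, axis=None) -> float | np.ndarray:
    """Squared coefficient of variation: var(x, ddof=1) / mean(x)**2.

    Raises ``ValueError`` for fewer than two values or a zero mean (the
    index is undefined there).  ``axis`` allows vectorised evaluation over
    a matrix of bootstrap resamples.
    """
    values = np.asarray(values, dtype=float)
    if axis is None:
        if values.size < 2:
            raise ValueError("opportunity index needs at least 2 values")
        mean = values.mean()
        if mean == 0:
            raise ValueError("opportunity index undefined for zero mean")
        return float(values.var(ddof=1) / mean**2)
    mean = values.mean(axis=axis)
    var = values.var(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(mean == 0, np.nan, var / mean**2)


@dataclass(frozen=True)
class BootstrapCI:
    point: float
    lower: float
    upper: float
    n_boot: int
    n_dropped: int
    seed: int | None


def bootstrap_ci(
    values,
    statistic=opportunity_index,
    n_boot: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> BootstrapCI:
    """Percentile bootstrap interval for ``statistic`` over ``values``.

    Resamples rows with replacement.  ``statistic`` may either accept an
    ``axis`` keyword (vectorised over a resample matrix) or be a plain
    1-D callable.  Resamples where the statistic is undefined (NaN, e.g.
    zero-mean draws) are dropped and counted.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    n = values.size
    if n < 2:
        raise ValueError("bootstrap needs at least 2 values")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    point = float(statistic(values))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = values[idx]
    try:
        stats = np.asarray(statistic(boot, axis=-1), dtype=float)
    except TypeError:
        stats = np.array([_safe_stat(statistic, row) for row in boot])
    keep = ~np.isnan(stats)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("bootstrap: dropped %d degenerate resamples", n_dropped)
    stats = stats[keep]
    if stats.size == 0:
        raise ValueError("all bootstrap resamples were degenerate")
    lower, upper = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapCI(point, float(lower), float(upper), n_boot, n_dropped, seed)


def _safe_stat(statistic, row):
    try:
        return float(statistic(row))
    except ValueError:
        return np.nan


def intervals_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def compare_indices(a: BootstrapCI, b: BootstrapCI) -> bool:
    """True (significant) iff the two bootstrap intervals are disjoint."""
    return not intervals_overlap((a.lower, a.upper), (b.lower, b.upper))


def selection_indices(
    summaries: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int | None = None,
    unit: str = "male",
) -> pd.DataFrame:
    """I, I_S and I_P with bootstrap CIs for one treatment's summary table.

    Males with undefined ``P`` (no mates) are excluded from ``I_P``.  With
    ``unit="group"`` resampling is over whole groups rather than individual
    focal males (one focal per group makes these coincide in the standard
    design, but user data may differ).
    """
    if unit not in {"male", "group"}:
        raise ValueError("unit must be 'male' or 'group'")
    rows = []
    specs = [("I", "T"), ("I_S", "M"), ("I_P", "P")]
    for k, (index_name, col) in enumerate(specs):
        vals = summaries[col].to_numpy(dtype=float)
        if unit == "group":
            vals = summaries.groupby("group_id")[col].mean().to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        sub_seed = None if seed is None else seed + k
        ci = bootstrap_ci(vals, opportunity_index, n_boot=n_boot, seed=sub_seed)
        rows.append(
            {
                "index": index_name,
                "component": col,
                "point": ci.point,
                "lower": ci.lower,
                "upper": ci.upper,
                "n": vals.size,
                "n_boot": n_boot,
                "n_dropped": ci.n_dropped,
            }
        )
    return pd.DataFrame(rows)
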