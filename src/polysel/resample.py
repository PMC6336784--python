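"""Focal-male resampling estimator of the opportunity for post-copulatory
selection (I_P) from twice-mated-female ("trio") data.

Each trio is one female that mated exactly two males, with the paternity
proportion of each male recorded.  Because only one male per female can be
treated as "focal" (mirroring a one-focal-per-group design), the estimator
samples one of the two males uniformly per trio — each trio contributes
exactly one male per iteration — computes I_P = var/mean² over the sampled
shares within each treatment, and repeats.  The iteration distribution
gives a mean and a 95 percentile interval for I_P; across iterations the
draws are independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRIO_COLUMNS = ["female_id", "treatment", "first_share", "second_share", "interval"]


@dataclass(frozen=True)
class MatingTrio:
    female_id: str
    treatment: str
    first_male_share: float
    second_male_share: float
    remating_interval: str = ""

    def __post_init__(self) -> None:
        for s in (self.first_male_share, self.second_male_share):
            if not 0 <= s <= 1:
                raise ValueError(f"trio {self.female_id}: share {s} outside [0, 1]")
        if self.first_male_share + self.second_male_share > 1 + 1e-9:
            raise ValueError(f"trio {self.female_id}: shares sum to more than 1")


def read_trios(path: str | Path) -> list[MatingTrio]:
    sep = "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in TRIO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if df["female_id"].duplicated().any():
        dup = df.loc[df["female_id"].duplicated(), "female_id"].iloc[0]
        raise ValueError(f"{path}: more than one trio for female {dup!r}")
    return [
        MatingTrio(
            female_id=str(r.female_id),
            treatment=str(r.treatment),
            first_male_share=float(r.first_share),
            second_male_share=float(r.second_share),
            remating_interval=str(r.interval),
        )
        for r in df.itertuples()
    ]


@dataclass
class IPResampleResult:
    treatment: str
    values: np.ndarray
    mean: float
    lower: float
    upper: float
    n_trios: int
    n_iter: int
    n_dropped: int
    seed: int | None


def resample_focal_ip(
    trios: list[MatingTrio],
    n_iter: int = 1000,
    seed: int | None = None,
) -> dict[str, IPResampleResult]:
    """Distribution of I_P per treatment under random focal-male labelling.

    Iterations in which every sampled share is zero (I_P undefined) are
    dropped and counted.  Pooled across remating intervals.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    results: dict[str, IPResampleResult] = {}
    for treatment in sorted({t.treatment for t in trios}):
        sub = [t for t in trios if t.treatment == treatment]
        if len(sub) < 2:
            raise ValueError(f"treatment {treatment!r}: need at least 2 trios")
        shares = np.array(
            [[t.first_male_share, t.second_male_share] for t in sub]
        )  # (n_trios, 2)
        picks = rng.integers(0, 2, size=(n_iter, len(sub)))
        sampled = shares[np.arange(len(sub))[None, :], picks]  # (n_iter, n_trios)
        means = sampled.mean(axis=1)
        variances = sampled.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ip = np.where(means == 0, np.nan, variances / means**2)
        valid = ip[~np.isnan(ip)]
        n_dropped = n_iter - valid.size
        if n_dropped:
            logger.info(
                "resample_focal_ip[%s]: dropped %d all-zero iterations",
                treatment, n_dropped,
            )
        if valid.size == 0:
            raise ValueError(f"treatment {treatment!r}: every iteration degenerate")
        lower, upper = np.percentile(valid, [2.5, 97.5])
        results[treatment] = IPResampleResult(
            treatment=treatment,
            values=ip,
            mean=float(valid.mean()),
            lower=float(lower),
            upper=float(upper),
            n_trios=len(sub),
            n_iter=n_iter,
            n_dropped=n_dropped,
            seed=seed,
        )
    return results
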