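"""Delta-method decomposition of variance in male reproductive success.

Relative reproductive success factorises exactly as t = m · p · n (each
variable divided by its treatment mean, with the pooled definition of
paternity share).  To first order, the variance of the product splits into
the component variances plus pairwise covariance terms; the ledger used
here enters each covariance once,

    var(t) = var(m) + var(p) + var(n)
             + cov(m,p) + cov(m,n) + cov(n,p) + D,

with D defined as the residual that closes the identity exactly (it
absorbs both the conventional factor-of-2 ambiguity on the covariances and
all higher-order terms, so the ledger always balances regardless of
convention).  Percent contributions are descriptive and reported relative
to var(t) by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMPONENT_ORDER = ["var_M", "var_P", "var_N", "cov_MP", "cov_MN", "cov_NP"]


@dataclass
class DecompositionResult:
    var_T: float
    var_M: float
    var_P: float
    var_N: float
    cov_MP: float
    cov_MN: float
    cov_NP: float
    D: float
    n_males: int
    n_excluded: int
    percent_denominator: str = "var_T"

    def components(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in COMPONENT_ORDER}

    def percents(self) -> dict[str, float]:
        denom = self.var_T if self.percent_denominator == "var_T" else (
            sum(self.components().values()) + self.D
        )
        return {k: 100.0 * v / denom for k, v in self.components().items()}

    def as_frame(self) -> pd.DataFrame:
        pct = self.percents()
        rows = [{"component": "var_T", "value": self.var_T, "percent": 100.0}]
        rows += [
            {"component": k, "value": v, "percent": pct[k]}
            for k, v in self.components().items()
        ]
        rows.append({"component": "D", "value": self.D, "percent": np.nan})
        return pd.DataFrame(rows)


def residual_from_components(
    var_T: float,
    var_M: float,
    var_P: float,
    var_N: float,
    cov_MP: float,
    cov_MN: float,
    cov_NP: float,
) -> float:
    """Residual D closing the single-counted-covariance ledger.

    Useful for auditing a published component table: D is whatever is left
    of var(t) after the six tabulated terms.
    """
    return var_T - (var_M + var_P + var_N + cov_MP + cov_MN + cov_NP)


def decompose_variance(
    summaries: pd.DataFrame, percent_denominator: str = "var_T"
) -> DecompositionResult:
    """Decompose var(relative T) into M, P, N terms for one treatment.

    Males with undefined P or N (no mates, or mates with no scored
    daughters) are excluded with a logged count.  Sample (n−1) moments
    throughout.
    """
    if percent_denominator not in {"var_T", "component_sum"}:
        raise ValueError("percent_denominator must be 'var_T' or 'component_sum'")
    df = summaries.dropna(subset=["T", "M", "P", "N"])
    n_excluded = len(summaries) - len(df)
    if n_excluded:
        logger.info("decomposition: excluded %d males with undefined P/N", n_excluded)
    if len(df) < 3:
        raise ValueError("need at least 3 males with defined components")

    rel = {}
    for col in ("T", "M", "P", "N"):
        x = df[col].to_numpy(dtype=float)
        if x.mean() == 0:
            raise ValueError(f"mean of {col} is zero: cannot standardise")
        rel[col] = x / x.mean()

    def cov(a, b):
        return float(np.cov(rel[a], rel[b], ddof=1)[0, 1])

    var_T = float(np.var(rel["T"], ddof=1))
    var_M = float(np.var(rel["M"], ddof=1))
    var_P = float(np.var(rel["P"], ddof=1))
    var_N = float(np.var(rel["N"], ddof=1))
    cov_MP = cov("M", "P")
    cov_MN = cov("M", "N")
    cov_NP = cov("N", "P")
    D = residual_from_components(var_T, var_M, var_P, var_N, cov_MP, cov_MN, cov_NP)
    return DecompositionResult(
        var_T=var_T,
        var_M=var_M,
        var_P=var_P,
        var_N=var_N,
        cov_MP=cov_MP,
        cov_MN=cov_MN,
        cov_NP=cov_NP,
        D=D,
        n_males=len(df),
        n_excluded=n_excluded,
        percent_denominator=percent_denominator,
    )
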