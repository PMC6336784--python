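"""Bateman gradients, s'max / Jones' indices and adjusted paternity share.

The Bateman gradient is the least-squares slope of relative reproductive
success (T scaled to mean 1) on mating success.  Two standardisations are
supported:

* mean-standardised — predictor divided by its mean; the slope is the
  proportional change in relative fitness per proportional change in the
  predictor;
* variance-standardised — predictor z-scored; the slope is the change in
  relative fitness per SD of the predictor, i.e. the maximum standardised
  selection differential s'max (Jones' index in the univariate case).

The two are linked by the identity  β_σ = β_μ · CV(x), and since
CV(x) = sqrt(opportunity index of x), the univariate Jones' index equals
β_μ · sqrt(I_S) (pre-copulatory) or β_μ · sqrt(I_P) (post-copulatory).
Both code paths are computed here so the identity is checkable.

Multivariate gradients regress relative T jointly on M, P and N
(standardised), separating direct selection on each component from
covariance-driven selection.  Covariates default to vial fecundity
(continuous) and experimental replicate (categorical); significance can
additionally be assessed on square-root (Box–Cox λ=1/2) transformed T,
which tames the right skew of count fitness data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import GroupRoster, MatingEvent, PaternityRecord

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("group_fecundity", "replicate_id")


# ---------------------------------------------------------------------------
# design helpers


def _covariate_design(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Continuous covariates as-is; string-valued ones dummy-coded."""
    parts = []
    for cov in covariates:
        col = df[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(col.astype(float).to_frame(cov))
    if not parts:
        return pd.DataFrame(index=df.index)
    return pd.concat(parts, axis=1)


def _build_design(
    df: pd.DataFrame,
    predictors: Mapping[str, np.ndarray],
    covariates: Sequence[str],
) -> pd.DataFrame:
    X = pd.DataFrame({name: np.asarray(v, float) for name, v in predictors.items()},
                     index=df.index)
    X = pd.concat([X, _covariate_design(df, covariates)], axis=1)
    X.insert(0, "const", 1.0)
    if len(X) <= X.shape[1]:
        raise ValueError(
            f"saturated design: {len(X)} males for {X.shape[1]} parameters; "
            "reduce covariates or add males"
        )
    _check_rank(X)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, r = np.linalg.qr(arr)
        bad = [X.columns[i] for i in range(arr.shape[1])
               if abs(r[i, i]) < 1e-10 * max(1.0, abs(r[0, 0]))]
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")


def _ols_table(y: np.ndarray, X: pd.DataFrame) -> pd.DataFrame:
    fit = sm.OLS(y, X).fit()
    return pd.DataFrame(
        {
            "term": X.columns,
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )


def _clean(df: pd.DataFrame, cols: Iterable[str]) -> pd.DataFrame:
    cols = list(cols)
    out = df.dropna(subset=cols)
    dropped = len(df) - len(out)
    if dropped:
        logger.info("dropped %d males with undefined %s", dropped, cols)
    if len(out) < 3:
        raise ValueError("need at least 3 males with defined components")
    return out


# ---------------------------------------------------------------------------
# univariate gradients


@dataclass(frozen=True)
class UnivariateGradient:
    """Mean- and variance-standardised slope of relative T on one predictor."""

    predictor: str
    beta_mean: float
    se_mean: float
    t: float
    p: float
    p_sqrt_t: float
    beta_var: float           # slope on the z-scored predictor (direct fit)
    se_var: float
    jones: float              # beta_mean * CV(predictor): the identity route
    cv: float
    n: int

    @property
    def opportunity(self) -> float:
        return self.cv**2


def bateman_univariate(
    summaries: pd.DataFrame,
    predictor: str = "M",
    response: str = "T",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> UnivariateGradient:
    """Univariate Bateman gradient of relative ``response`` on ``predictor``.

    ``beta_var`` comes from a direct fit on the z-scored predictor, while
    ``jones`` is ``beta_mean * CV``; the two agree to numerical precision,
    providing an internal cross-check of the standardisation identity.
    """
    df = _clean(summaries, [predictor, response])
    x = df[predictor].to_numpy(dtype=float)
    y = df[response].to_numpy(dtype=float)
    if x.std(ddof=1) == 0:
        raise ValueError(f"zero variance in {predictor}: gradient undefined")
    if y.mean() == 0:
        raise ValueError(f"mean {response} is zero: relative fitness undefined")
    y_rel = y / y.mean()
    x_mean = x / x.mean()
    x_var = (x - x.mean()) / x.std(ddof=1)
    cv = x.std(ddof=1) / x.mean()

    Xm = _build_design(df, {predictor: x_mean}, covariates)
    tab_m = _ols_table(y_rel, Xm)
    row_m = tab_m.loc[tab_m.term == predictor].iloc[0]
    Xv = _build_design(df, {predictor: x_var}, covariates)
    tab_v = _ols_table(y_rel, Xv)
    row_v = tab_v.loc[tab_v.term == predictor].iloc[0]
    # significance on sqrt-transformed raw response (Box-Cox, lambda = 1/2)
    tab_s = _ols_table(np.sqrt(y), Xm)
    p_sqrt = float(tab_s.loc[tab_s.term == predictor, "p"].iloc[0])

    return UnivariateGradient(
        predictor=predictor,
        beta_mean=float(row_m.estimate),
        se_mean=float(row_m.se),
        t=float(row_m.t),
        p=float(row_m.p),
        p_sqrt_t=p_sqrt,
        beta_var=float(row_v.estimate),
        se_var=float(row_v.se),
        jones=float(row_m.estimate * cv),
        cv=float(cv),
        n=len(df),
    )


# ---------------------------------------------------------------------------
# multivariate gradients


@dataclass
class GradientSet:
    """Full set of gradients for one treatment's male summaries."""

    uni_pre: UnivariateGradient | None
    uni_post: UnivariateGradient | None
    multi_mean: pd.DataFrame      # T_rel ~ M/μ + P/μ + N/μ + covariates
    multi_var: pd.DataFrame       # T_rel ~ z(M) + z(P) + z(N) + covariates
    multi_p_sqrt_t: pd.DataFrame  # p-values from sqrt(T) refit
    n: int = 0
    dropped: tuple[str, ...] = ()  # zero-variance components left out

    def _coef(self, table: pd.DataFrame, term: str) -> float:
        rows = table.loc[table.term == term, "estimate"]
        return float(rows.iloc[0]) if len(rows) else float("nan")

    @property
    def beta_M_multi(self) -> float:
        return self._coef(self.multi_mean, "M")

    @property
    def beta_P_multi(self) -> float:
        return self._coef(self.multi_mean, "P")

    @property
    def beta_N_multi(self) -> float:
        return self._coef(self.multi_mean, "N")

    @property
    def smax_pre_multi(self) -> float:
        return self._coef(self.multi_var, "M")

    @property
    def smax_post_multi(self) -> float:
        return self._coef(self.multi_var, "P")

    @property
    def jones_pre(self) -> float:
        return self.uni_pre.jones if self.uni_pre else float("nan")

    @property
    def jones_post(self) -> float:
        return self.uni_post.jones if self.uni_post else float("nan")


def bateman_multivariate(
    summaries: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> GradientSet:
    """Univariate and multivariate gradient set for one treatment.

    Components with zero variance carry no selection information and are
    dropped from the fits (recorded in ``dropped``); genuinely collinear
    non-constant predictors raise ``ValueError`` naming the offending
    columns.
    """
    df = _clean(summaries, ["T", "M", "P", "N"])
    y = df["T"].to_numpy(dtype=float)
    y_rel = y / y.mean()
    mean_std, var_std, dropped = {}, {}, []
    for col in ("M", "P", "N"):
        x = df[col].to_numpy(dtype=float)
        if x.std(ddof=1) == 0:
            dropped.append(col)
            logger.warning("%s constant across males: dropped from gradients", col)
            continue
        if x.mean() == 0:
            raise ValueError(f"mean of {col} is zero: cannot mean-standardise")
        mean_std[col] = x / x.mean()
        var_std[col] = (x - x.mean()) / x.std(ddof=1)
    if "M" in dropped:
        raise ValueError("zero variance in M: Bateman gradient undefined")

    Xm = _build_design(df, mean_std, covariates)
    Xv = _build_design(df, var_std, covariates)
    tab_mean = _ols_table(y_rel, Xm)
    tab_var = _ols_table(y_rel, Xv)
    tab_sqrt = _ols_table(np.sqrt(y), Xm)[["term", "p"]].rename(
        columns={"p": "p_sqrt_t"}
    )
    return GradientSet(
        uni_pre=bateman_univariate(df, "M", covariates=covariates),
        uni_post=(
            None if "P" in dropped
            else bateman_univariate(df, "P", covariates=covariates)
        ),
        multi_mean=tab_mean,
        multi_var=tab_var,
        multi_p_sqrt_t=tab_sqrt,
        n=len(df),
        dropped=tuple(dropped),
    )


# ---------------------------------------------------------------------------
# repetitive-mating gradient


def repetitive_gradient(
    summaries: pd.DataFrame,
    response: str = "P",
    covariates: Sequence[str] = ("replicate_id",),
) -> pd.DataFrame:
    """Slope of mean-standardised ``response`` on the re-mating rate.

    The re-mating rate is copulations per unique mate; vial fecundity is
    deliberately not a covariate here (only replicate).
    """
    df = _clean(summaries, [response, "repetitive_rate"])
    y = df[response].to_numpy(dtype=float)
    if y.mean() == 0:
        raise ValueError(f"mean {response} is zero")
    X = _build_design(
        df, {"repetitive_rate": df["repetitive_rate"].to_numpy(float)}, covariates
    )
    return _ols_table(y / y.mean(), X)


def gradient_treatment_difference(
    summaries: pd.DataFrame,
    predictor: str,
    response: str = "T",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    standardise_predictor: str = "mean",
) -> pd.Series:
    """Test whether a gradient differs between two treatments.

    Response and (optionally) predictor are standardised *within*
    treatment, then a pooled model with a treatment × predictor interaction
    is fitted; returns the interaction row (estimate, se, t, p, df_resid).
    """
    df = _clean(summaries, [predictor, response, "treatment"])
    treatments = sorted(df["treatment"].unique())
    if len(treatments) != 2:
        raise ValueError(f"need exactly 2 treatments, got {treatments}")
    y = np.empty(len(df))
    x = np.empty(len(df))
    for t in treatments:
        mask = (df["treatment"] == t).to_numpy()
        yt = df.loc[mask, response].to_numpy(float)
        xt = df.loc[mask, predictor].to_numpy(float)
        y[mask] = yt / yt.mean()
        if standardise_predictor == "mean":
            x[mask] = xt / xt.mean()
        elif standardise_predictor == "var":
            x[mask] = (xt - xt.mean()) / xt.std(ddof=1)
        elif standardise_predictor == "none":
            x[mask] = xt
        else:
            raise ValueError("standardise_predictor must be mean|var|none")
    is_b = (df["treatment"] == treatments[1]).to_numpy(dtype=float)
    X = _build_design(
        df,
        {predictor: x, "treatment_b": is_b, "interaction": x * is_b},
        covariates,
    )
    fit = sm.OLS(y, X).fit()
    return pd.Series(
        {
            "treatments": f"{treatments[1]} - {treatments[0]}",
            "estimate": float(fit.params["interaction"]),
            "se": float(fit.bse["interaction"]),
            "t": float(fit.tvalues["interaction"]),
            "p": float(fit.pvalues["interaction"]),
            "df_resid": float(fit.df_resid),
        }
    )


# ---------------------------------------------------------------------------
# adjusted paternity share


def adjusted_pcs(pcs_obs, n):
    """Paternity share adjusted to the two-male standard.

    ``adjusted = pcs_obs * (n - 1) / (pcs_obs * (n - 2) + 1)``, where ``n``
    is the number of males that mated the female.  A fair-raffle share of
    1/n maps to 1/2 for every n, n = 2 is the identity, and shares of 0 or
    1 are fixed points.
    """
    pcs = np.asarray(pcs_obs, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if np.any((pcs < 0) | (pcs > 1)):
        raise ValueError("pcs_obs must lie in [0, 1]")
    if np.any(n_arr < 2):
        raise ValueError("n must be >= 2 (competing females only)")
    out = pcs * (n_arr - 1) / (pcs * (n_arr - 2) + 1)
    return float(out) if np.isscalar(pcs_obs) and np.isscalar(n) else out


@dataclass
class AdjustedPCS:
    male_id: str
    group_id: str
    treatment: str
    replicate_id: str
    adjusted_share: float
    n_females_used: int
    n_excluded: int
    per_female: dict[str, float] = field(default_factory=dict)


def adjusted_shares(
    events: Iterable[MatingEvent],
    paternity: Iterable[PaternityRecord],
    rosters: Mapping[str, GroupRoster],
) -> list[AdjustedPCS]:
    """Per-focal-male mean adjusted paternity share.

    For each female a focal male mated, his observed share of her daughters
    is adjusted by the number of males (n) that mated her.  Females mated
    by only one male, never mated by the focal, or with no scored
    daughters, are excluded (and counted).
    """
    events = list(events)
    maters: dict[tuple[str, str], set[str]] = {}
    for e in events:
        maters.setdefault((e.group_id, e.female_id), set()).add(e.male_id)
    recs = {(r.group_id, r.female_id): r for r in paternity}

    out = []
    for gid in sorted(rosters):
        roster = rosters[gid]
        focal = roster.focal_male
        shares: dict[str, float] = {}
        excluded = 0
        for fid in roster.females:
            males_of_f = maters.get((gid, fid), set())
            if focal not in males_of_f or len(males_of_f) < 2:
                excluded += 1
                continue
            rec = recs.get((gid, fid))
            if rec is None or rec.total == 0:
                excluded += 1
                continue
            pcs = rec.daughters_focal / rec.total
            shares[fid] = adjusted_pcs(pcs, len(males_of_f))
        replicate = roster.replicate_id
        out.append(
            AdjustedPCS(
                male_id=focal,
                group_id=gid,
                treatment=roster.treatment,
                replicate_id=replicate,
                adjusted_share=(
                    float(np.mean(list(shares.values()))) if shares else float("nan")
                ),
                n_females_used=len(shares),
                n_excluded=excluded,
                per_female=shares,
            )
        )
    return out


def adjusted_shares_frame(adjusted: Iterable[AdjustedPCS]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "male_id": a.male_id,
                "group_id": a.group_id,
                "treatment": a.treatment,
                "replicate_id": a.replicate_id,
                "adjusted_share": a.adjusted_share,
                "n_females_used": a.n_females_used,
                "n_excluded": a.n_excluded,
            }
            for a in adjusted
        ]
    )
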