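"""Sperm competition intensity and the mating-matrix randomization test.

Within each group the unique mating pairs form a binary male × female
incidence matrix (the mating matrix).  A male's sperm competition
intensity (SCI) is the harmonic mean of his mates' polyandry counts
(column sums): SCI_i = M_i / Σ_j 1/k_j.  The SCI correlation (SCIC) is
the least-squares slope of mean-standardised SCI on mean-standardised M
pooled over *all* males (focal and rival) in a treatment — negative when
highly polygynous males tend to share the least polyandrous females.

The null model for SCIC preserves, per group, the exact row and column
sums of the binary matrix (every male's and female's number of unique
partners) while shuffling who mates whom.  Sampling is uniform over the
fixed-margin family: by exhaustive enumeration whenever the family is
small (it always is for 4 × 4 groups), otherwise by a checkerboard-swap
Markov chain (symmetric proposal; stationary distribution uniform).
Groups whose margins admit a single matrix are passed through unchanged
and flagged.
"""

from __future__ import annotations

import logging
import random as _pyrandom
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as scipy_stats

from .core import GroupRoster, MatingEvent
from .gradients import _build_design

logger = logging.getLogger(__name__)

ENUMERATION_LIMIT = 10_000


@dataclass
class MatingMatrix:
    """Unique-pair incidence (and copulation counts) for one group."""

    group_id: str
    treatment: str
    males: tuple[str, ...]
    females: tuple[str, ...]
    binary: np.ndarray
    counts: np.ndarray
    focal_index: int = 0

    def __post_init__(self) -> None:
        self.binary = np.asarray(self.binary, dtype=int)
        if not np.isin(self.binary, (0, 1)).all():
            raise ValueError("mating matrix must be binary")

    @property
    def male_mating_success(self) -> np.ndarray:
        return self.binary.sum(axis=1)

    @property
    def female_polyandry(self) -> np.ndarray:
        return self.binary.sum(axis=0)


def build_mating_matrices(
    events: Iterable[MatingEvent], rosters: Mapping[str, GroupRoster]
) -> list[MatingMatrix]:
    by_group: dict[str, list[MatingEvent]] = {g: [] for g in rosters}
    for e in events:
        if e.group_id not in by_group:
            raise ValueError(f"event {e}: unknown group {e.group_id!r}")
        by_group[e.group_id].append(e)
    matrices = []
    for gid in sorted(rosters):
        roster = rosters[gid]
        males = roster.male_ids
        females = roster.females
        m_idx = {m: i for i, m in enumerate(males)}
        f_idx = {f: j for j, f in enumerate(females)}
        counts = np.zeros((len(males), len(females)), dtype=int)
        for e in by_group[gid]:
            counts[m_idx[e.male_id], f_idx[e.female_id]] += 1
        matrices.append(
            MatingMatrix(
                group_id=gid,
                treatment=roster.treatment,
                males=males,
                females=females,
                binary=(counts > 0).astype(int),
                counts=counts,
                focal_index=males.index(roster.focal_male),
            )
        )
    return matrices


def sperm_competition_intensity(matrix: MatingMatrix) -> np.ndarray:
    """Per-male SCI: harmonic mean of his mates' polyandry (NaN if M=0)."""
    binary = matrix.binary
    k = matrix.female_polyandry.astype(float)
    sci = np.full(binary.shape[0], np.nan)
    for i in range(binary.shape[0]):
        mates = np.flatnonzero(binary[i])
        if mates.size:
            sci[i] = mates.size / np.sum(1.0 / k[mates])
    return sci


@dataclass(frozen=True)
class SCICSlope:
    slope: float
    n_males: int
    degenerate: bool


def _pooled_m_sci(matrices: Sequence[MatingMatrix]) -> tuple[np.ndarray, np.ndarray]:
    ms, scis = [], []
    for mat in matrices:
        sci = sperm_competition_intensity(mat)
        m = mat.male_mating_success.astype(float)
        keep = m > 0
        ms.append(m[keep])
        scis.append(sci[keep])
    return np.concatenate(ms), np.concatenate(scis)


def standardised_slope(m: np.ndarray, sci: np.ndarray) -> float:
    """Least-squares slope of SCI on M after dividing each by its mean.

    NaN when the predictor M is constant (undefined slope; e.g. a fully
    saturated mating matrix, where every male also has the same SCI).
    Constant SCI with varying M gives an exact zero slope.
    """
    m = np.asarray(m, dtype=float)
    sci = np.asarray(sci, dtype=float)
    if m.size < 2 or m.mean() == 0 or sci.mean() == 0:
        return float("nan")
    m_std = m / m.mean()
    sci_std = sci / sci.mean()
    if m_std.std() == 0:
        return float("nan")
    if sci_std.std() == 0:
        return 0.0
    return float(np.polyfit(m_std, sci_std, 1)[0])


def scic(matrices: Sequence[MatingMatrix]) -> SCICSlope:
    """Slope of mean-standardised SCI on mean-standardised M, all males pooled."""
    m, sci = _pooled_m_sci(matrices)
    if m.size < 2:
        return SCICSlope(float("nan"), int(m.size), True)
    slope = standardised_slope(m, sci)
    return SCICSlope(slope, int(m.size), bool(np.isnan(slope)))


# ---------------------------------------------------------------------------
# fixed-margin sampling


def enumerate_fixed_margins(
    row_sums: Sequence[int],
    col_sums: Sequence[int],
    limit: int = ENUMERATION_LIMIT,
) -> list[np.ndarray] | None:
    """All binary matrices with the given margins, or None if > ``limit``.

    Row-by-row backtracking over column subsets; intended for the small
    matrices of group-structured mating data (a 4 × 4 family never
    approaches the default limit).
    """
    row_sums = list(int(r) for r in row_sums)
    col_sums = np.asarray(col_sums, dtype=int)
    if sum(row_sums) != col_sums.sum():
        raise ValueError("row and column sums disagree")
    n_rows, n_cols = len(row_sums), len(col_sums)
    out: list[np.ndarray] = []
    mat = np.zeros((n_rows, n_cols), dtype=int)

    def recurse(i: int, remaining: np.ndarray) -> bool:
        if i == n_rows:
            if (remaining == 0).all():
                out.append(mat.copy())
                if len(out) > limit:
                    return False
            return True
        # prune: remaining capacity must be able to absorb later rows
        if remaining.sum() != sum(row_sums[i:]):
            return True  # unreachable by construction, kept as a guard
        rows_left = n_rows - i
        if (remaining > rows_left).any():
            return True
        candidates = [j for j in range(n_cols) if remaining[j] > 0]
        if len(candidates) < row_sums[i]:
            return True
        for cols in combinations(candidates, row_sums[i]):
            mat[i] = 0
            mat[i, list(cols)] = 1
            remaining[list(cols)] -= 1
            ok = recurse(i + 1, remaining)
            remaining[list(cols)] += 1
            if not ok:
                return False
        return True

    if not recurse(0, col_sums.copy()):
        return None
    return out


def sample_fixed_margins_mcmc(
    binary: np.ndarray,
    n_samples: int,
    rng: _pyrandom.Random,
    thin: int | None = None,
    burn_in: int | None = None,
) -> list[np.ndarray]:
    """Uniform samples from the fixed-margin family by checkerboard swaps.

    A swap picks two 1-entries (r1,c1), (r2,c2) with r1≠r2, c1≠c2 and
    (r1,c2) = (r2,c1) = 0, and replaces the 2×2 checkerboard with its
    complement; margins are preserved exactly.  Defaults: thinning of
    100 × (number of 1-entries) swap attempts between samples and a
    burn-in of 10 thinning intervals.
    """
    binary = np.asarray(binary, dtype=int)
    edges = [tuple(e) for e in np.argwhere(binary == 1)]
    n_edges = len(edges)
    if n_edges < 2:
        return [binary.copy() for _ in range(n_samples)]
    if thin is None:
        thin = 100 * n_edges
    if burn_in is None:
        burn_in = 10 * thin
    edgeset = set(edges)
    randrange = rng.randrange

    def attempt() -> None:
        i = randrange(n_edges)
        j = randrange(n_edges)
        r1, c1 = edges[i]
        r2, c2 = edges[j]
        if r1 == r2 or c1 == c2:
            return
        if (r1, c2) in edgeset or (r2, c1) in edgeset:
            return
        edgeset.discard((r1, c1))
        edgeset.discard((r2, c2))
        edgeset.add((r1, c2))
        edgeset.add((r2, c1))
        edges[i] = (r1, c2)
        edges[j] = (r2, c1)

    for _ in range(burn_in):
        attempt()
    samples = []
    for _ in range(n_samples):
        for _ in range(thin):
            attempt()
        mat = np.zeros_like(binary)
        for r, c in edges:
            mat[r, c] = 1
        samples.append(mat)
    return samples


@dataclass
class SCICResult:
    observed: float
    null_values: np.ndarray
    p_lower: float
    p_upper: float
    p_two_sided: float
    n_randomisations: int
    seed: int | None
    unique_groups: list[str] = field(default_factory=list)
    degenerate: bool = False


def randomize_scic(
    matrices: Sequence[MatingMatrix],
    n_rand: int = 1000,
    seed: int | None = None,
    method: str = "auto",
) -> SCICResult:
    """Margin-preserving randomization null for the SCIC.

    Per randomisation, every group's binary matrix is replaced by a
    uniform draw from the family of binary matrices sharing its row and
    column sums; the SCIC is recomputed on the pooled draw.  ``p_lower``
    is the proportion of null values ≤ observed (the tail relevant to the
    directional negative-SCIC hypothesis), ``p_upper`` the ≥ tail and
    ``p_two_sided`` twice the smaller, capped at 1.
    """
    if method not in {"auto", "enumerate", "mcmc"}:
        raise ValueError("method must be auto|enumerate|mcmc")
    obs = scic(matrices)
    rng = np.random.default_rng(seed)
    pyrng = _pyrandom.Random(None if seed is None else seed + 7919)

    # Precompute, per group, the (M, SCI) vectors of each admissible matrix.
    per_group: list[tuple[str, list[tuple[np.ndarray, np.ndarray]]]] = []
    unique_groups: list[str] = []
    for mat in matrices:
        family: list[np.ndarray] | None = None
        if method in {"auto", "enumerate"}:
            family = enumerate_fixed_margins(
                mat.binary.sum(axis=1), mat.binary.sum(axis=0)
            )
            if family is None and method == "enumerate":
                raise ValueError(
                    f"group {mat.group_id}: fixed-margin family exceeds "
                    f"{ENUMERATION_LIMIT}; use method='mcmc'"
                )
        if method == "mcmc":
            family = None
        if family is not None:
            mode = "enum"
            if len(family) == 1:
                unique_groups.append(mat.group_id)
            members = family
        else:
            mode = "chain"
            members = sample_fixed_margins_mcmc(mat.binary, n_rand, pyrng)
            if all((m == members[0]).all() for m in members):
                unique_groups.append(mat.group_id)
        stats = []
        for member in members:
            proxy = MatingMatrix(
                group_id=mat.group_id,
                treatment=mat.treatment,
                males=mat.males,
                females=mat.females,
                binary=member,
                counts=member,
                focal_index=mat.focal_index,
            )
            assert (member.sum(axis=1) == mat.binary.sum(axis=1)).all()
            assert (member.sum(axis=0) == mat.binary.sum(axis=0)).all()
            m = proxy.male_mating_success.astype(float)
            sci = sperm_competition_intensity(proxy)
            keep = m > 0
            stats.append((m[keep], sci[keep]))
        per_group.append((mode, stats))

    null = np.empty(n_rand)
    for r in range(n_rand):
        ms, scis = [], []
        for mode, stats in per_group:
            if mode == "chain":
                # chain samples are already one draw per randomisation
                m, s = stats[r]
            else:
                m, s = stats[rng.integers(len(stats))]
            ms.append(m)
            scis.append(s)
        null[r] = standardised_slope(np.concatenate(ms), np.concatenate(scis))

    valid = null[~np.isnan(null)]
    if obs.degenerate or valid.size == 0:
        return SCICResult(
            observed=obs.slope, null_values=null, p_lower=float("nan"),
            p_upper=float("nan"), p_two_sided=float("nan"),
            n_randomisations=n_rand, seed=seed, unique_groups=unique_groups,
            degenerate=True,
        )
    tol = 1e-12
    p_lower = float(np.mean(valid <= obs.slope + tol))
    p_upper = float(np.mean(valid >= obs.slope - tol))
    return SCICResult(
        observed=obs.slope,
        null_values=null,
        p_lower=p_lower,
        p_upper=p_upper,
        p_two_sided=min(1.0, 2 * min(p_lower, p_upper)),
        n_randomisations=n_rand,
        seed=seed,
        unique_groups=unique_groups,
    )


# ---------------------------------------------------------------------------
# SCI regressions on focal-male fitness


def sci_regressions(
    summaries: pd.DataFrame,
    matrices: Sequence[MatingMatrix],
    covariates: Sequence[str] = ("group_fecundity", "replicate_id"),
) -> dict[str, pd.DataFrame]:
    """Quasi-likelihood regressions of focal T and P on SCI.

    ``T_model``: overdispersed Poisson (log link, Pearson-X2 scale) of T on
    mean-standardised M and SCI plus covariates.  ``P_model``:
    overdispersed binomial of (daughters sired, daughters not sired) on
    mean-standardised SCI plus covariates.  SCI here is the focal male's
    value from his group's mating matrix.
    """
    sci_by_group = {}
    for mat in matrices:
        sci_by_group[mat.group_id] = sperm_competition_intensity(mat)[mat.focal_index]
    df = summaries.copy()
    df["sci"] = df["group_id"].map(sci_by_group)
    df = df.dropna(subset=["sci", "M", "P", "N", "T"])
    if len(df) < 3:
        raise ValueError("need at least 3 focal males with defined SCI")
    for col in ("M", "sci"):
        if df[col].std(ddof=1) == 0:
            raise ValueError(f"{col} constant across males: coefficient inestimable")
    m_std = df["M"].to_numpy(float) / df["M"].mean()
    sci_std = df["sci"].to_numpy(float) / df["sci"].mean()

    X_t = _build_design(df, {"M": m_std, "sci": sci_std}, covariates)
    fit_t = sm.GLM(df["T"].to_numpy(float), X_t, family=sm.families.Poisson()).fit(
        scale="X2"
    )
    sired = df["T"].to_numpy(float)
    unsired = (df["M"] * df["N"]).to_numpy(float) - sired
    X_p = _build_design(df, {"sci": sci_std}, covariates)
    model_p = sm.GLM(
        np.column_stack([sired, unsired]), X_p, family=sm.families.Binomial()
    )
    fit_p0 = model_p.fit()
    # quasi-binomial dispersion: Pearson X2 on the proportion scale with
    # binomial variance mu(1-mu)/n, divided by residual df
    trials = sired + unsired
    prop = sired / trials
    mu = fit_p0.mu
    x2 = float(np.sum((prop - mu) ** 2 * trials / (mu * (1 - mu))))
    fit_p = model_p.fit(scale=x2 / fit_p0.df_resid)

    def table(fit, X):
        est = fit.params.to_numpy()
        se = fit.bse.to_numpy()
        tval = est / se
        p = 2 * scipy_stats.t.sf(np.abs(tval), fit.df_resid)
        return pd.DataFrame(
            {"term": X.columns, "estimate": est, "se": se, "t": tval, "p": p}
        )

    return {"T_model": table(fit_t, X_t), "P_model": table(fit_p, X_p)}
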