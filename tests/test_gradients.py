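import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polysel as ps
from tests.conftest import make_summaries_frame


def random_summaries(rng, n=30):
    M = rng.integers(1, 5, size=n).astype(float)
    P = rng.uniform(0.1, 1.0, size=n)
    N = rng.uniform(5, 15, size=n)
    T = M * N * P
    return make_summaries_frame(
        T=T, M=M, P=P, N=N,
        group_fecundity=rng.uniform(30, 70, size=n),
    )


class TestUnivariate:
    def test_proportional_fitness_gives_unit_gradient(self):
        """T exactly proportional to M: relative T = relative M, slope 1."""
        M = np.array([1.0, 2.0, 3.0, 4.0, 2.0, 3.0])
        df = make_summaries_frame(T=3 * M, M=M, P=[0.5] * 6, N=[6.0] * 6)
        g = ps.bateman_univariate(df, covariates=())
        assert g.beta_mean == pytest.approx(1.0, abs=1e-12)

    def test_independent_predictor_gives_null_gradient(self):
        """Permuting M against T kills the gradient on average."""
        rng = np.random.default_rng(11)
        base = random_summaries(rng, n=40)
        slopes = []
        for _ in range(200):
            df = base.copy()
            df["M"] = rng.permutation(df["M"].to_numpy())
            slopes.append(ps.bateman_univariate(df, covariates=()).beta_mean)
        assert np.mean(slopes) == pytest.approx(0.0, abs=0.05)

    def test_zero_variance_predictor_fails(self):
        df = make_summaries_frame(T=[1.0, 2, 3, 4], M=[2.0] * 4,
                                  P=[0.5] * 4, N=[5.0] * 4)
        with pytest.raises(ValueError, match="zero variance"):
            ps.bateman_univariate(df, covariates=())

    def test_standardisation_identity_two_code_paths(self):
        """Variance-standardised slope (direct z-score fit) equals
        mean-standardised slope x CV of the predictor, with and without
        covariates."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            df = random_summaries(rng)
            for covs in ((), ("group_fecundity", "replicate_id")):
                g = ps.bateman_univariate(df, covariates=covs)
                assert g.beta_var == pytest.approx(g.jones, abs=1e-10)
                g2 = ps.bateman_univariate(df, "P", covariates=covs)
                assert g2.beta_var == pytest.approx(g2.jones, abs=1e-10)

    def test_gradient_invariant_to_rescaling(self):
        rng = np.random.default_rng(6)
        df = random_summaries(rng)
        scaled = df.copy()
        scaled["T"] *= 7.0
        scaled["M"] *= 3.0
        a = ps.bateman_univariate(df, covariates=())
        b = ps.bateman_univariate(scaled, covariates=())
        assert b.beta_mean == pytest.approx(a.beta_mean, rel=1e-9)
        assert b.beta_var == pytest.approx(a.beta_var, rel=1e-9)


class TestMultivariate:
    def test_constant_p_n_reduces_to_univariate(self):
        """With P and N constant only M carries information: the
        multivariate M gradient equals the univariate Bateman gradient."""
        M = np.array([1.0, 2, 3, 4, 2, 3, 1, 4])
        df = make_summaries_frame(
            T=M * 6.0 * 0.5, M=M, P=[0.5] * 8, N=[6.0] * 8
        )
        gset = ps.bateman_multivariate(df, covariates=())
        assert gset.dropped == ("P", "N")
        uni = ps.bateman_univariate(df, covariates=())
        assert gset.beta_M_multi == pytest.approx(uni.beta_mean, abs=1e-10)
        assert np.isnan(gset.beta_P_multi)

    def test_matches_normal_equation_solve(self):
        """Coefficients agree with a direct least-squares solve of the
        normal equations on a random 20 x 4 design to 1e-8."""
        rng = np.random.default_rng(7)
        df = random_summaries(rng, n=20)
        df["T"] += rng.uniform(0, 5, size=20)  # break the exact product
        gset = ps.bateman_multivariate(df, covariates=())
        y = df["T"].to_numpy() / df["T"].mean()
        X = np.column_stack(
            [np.ones(20)]
            + [df[c].to_numpy() / df[c].mean() for c in ("M", "P", "N")]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert gset.multi_mean["estimate"].to_numpy() == pytest.approx(
            beta, abs=1e-8
        )

    def test_known_coefficient_recovery(self):
        """Orthogonalised predictors with true coefficients (1, 2, -1) and
        small noise are recovered within 3 SE."""
        rng = np.random.default_rng(8)
        n = 60
        Z = np.linalg.qr(rng.normal(size=(n, 3)))[0]  # orthonormal columns
        y = 1.0 + Z @ np.array([1.0, 2.0, -1.0]) + rng.normal(0, 0.05, n)
        import statsmodels.api as sm

        X = sm.add_constant(pd.DataFrame(Z, columns=["M", "P", "N"]))
        fit = sm.OLS(y, X).fit()
        for term, true in zip(("M", "P", "N"), (1.0, 2.0, -1.0)):
            assert abs(fit.params[term] - true) < 3 * fit.bse[term]

    def test_collinear_predictors_named(self):
        rng = np.random.default_rng(9)
        df = random_summaries(rng, n=20)
        df["dup"] = df["M"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            ps.bateman_multivariate(df, covariates=("dup",))

    def test_smax_from_variance_standardised_fit(self):
        rng = np.random.default_rng(10)
        df = random_summaries(rng)
        gset = ps.bateman_multivariate(df, covariates=())
        # variance-standardised slope = mean-standardised slope * CV
        for comp in ("M", "P", "N"):
            x = df[comp].to_numpy()
            cv = x.std(ddof=1) / x.mean()
            mean_coef = gset._coef(gset.multi_mean, comp)
            var_coef = gset._coef(gset.multi_var, comp)
            assert var_coef == pytest.approx(mean_coef * cv, abs=1e-10)


class TestRepetitiveGradient:
    def test_constant_share_gives_zero_slope(self):
        df = make_summaries_frame(
            T=[5.0] * 6, M=[2.0] * 6, P=[0.4] * 6, N=[6.0] * 6,
            repetitive_rate=[1.0, 1.5, 2.0, 1.2, 1.8, 1.1],
        )
        tab = ps.repetitive_gradient(df, covariates=())
        slope = tab.loc[tab.term == "repetitive_rate", "estimate"].iloc[0]
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_constructed_slope_recovered_exactly(self):
        """Mean-standardised P built as 1 + 0.5*(rate - mean rate) gives a
        slope of exactly 0.5."""
        rate = np.array([1.0, 1.2, 1.6, 2.0, 2.4, 1.8])
        P = 0.3 * (1 + 0.5 * (rate - rate.mean()))
        df = make_summaries_frame(
            T=[5.0] * 6, M=[2.0] * 6, P=P, N=[6.0] * 6, repetitive_rate=rate
        )
        tab = ps.repetitive_gradient(df, covariates=())
        slope = tab.loc[tab.term == "repetitive_rate", "estimate"].iloc[0]
        assert slope == pytest.approx(0.5, abs=1e-12)

    def test_last_male_weight_steepens_gradient_under_high_polyandry(self):
        """With sperm precedence for the last male, re-mating pays: the
        paternity-share gradient on re-mating rate is positive and steeper
        in the high-polyandry arm."""
        arms = ps.make_paired_treatments(
            ps.SimConfig(n_groups=80, last_male_weight=2.5, seed=77)
        )
        slopes = {}
        pooled = []
        for name, ds in arms.items():
            sdf = ps.summaries_to_frame(
                ps.compute_male_summaries(ds.events, ds.paternity, ds.rosters)
            )
            pooled.append(sdf)
            tab = ps.repetitive_gradient(sdf)
            slopes[name] = tab.loc[
                tab.term == "repetitive_rate", "estimate"
            ].iloc[0]
        assert slopes["SPR-"] > 0
        assert slopes["SPR-"] > slopes["control"]
        diff = ps.gradient_treatment_difference(
            pd.concat(pooled, ignore_index=True),
            predictor="repetitive_rate", response="P",
            covariates=("replicate_id",), standardise_predictor="none",
        )
        # interaction is control minus high-polyandry: steeper in SPR- arm
        assert diff["estimate"] < 0


class TestAdjustedShare:
    @pytest.mark.parametrize(
        "pcs, n, expected",
        [
            (0.37, 2, 0.37),        # two maters: identity
            (1.0, 2, 1.0),          # full paternity is a fixed point
            (1.0, 5, 1.0),
            (0.5, 3, 2 / 3),
            (0.0, 4, 0.0),
        ],
    )
    def test_worked_cases(self, pcs, n, expected):
        assert ps.adjusted_pcs(pcs, n) == pytest.approx(expected)

    def test_fair_share_maps_to_half(self):
        for n in range(2, 8):
            assert ps.adjusted_pcs(1 / n, n) == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=100)
    @given(pcs=st.floats(0, 1), n=st.integers(2, 12))
    def test_stays_in_unit_interval(self, pcs, n):
        assert 0.0 <= ps.adjusted_pcs(pcs, n) <= 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ps.adjusted_pcs(1.2, 3)
        with pytest.raises(ValueError):
            ps.adjusted_pcs(0.5, 1)

    def test_exclusions_in_per_male_average(self, tiny_dataset):
        """fB has two maters (focal + rival) -> kept with n=2; fA is
        monogamous to the focal and fC never mated the focal -> excluded."""
        ev, pat, rosters = tiny_dataset
        (adj,) = ps.adjusted_shares(ev, pat, rosters)
        assert adj.n_females_used == 1
        assert adj.n_excluded == 2
        assert adj.adjusted_share == pytest.approx(ps.adjusted_pcs(0.2, 2))
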