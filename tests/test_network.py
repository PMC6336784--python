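import itertools
import random

import numpy as np
import pytest
from scipy import stats

import polysel as ps
from polysel.network import (
    MatingMatrix,
    sample_fixed_margins_mcmc,
    standardised_slope,
)


def matrix_from(binary, group_id="g", treatment="t"):
    binary = np.asarray(binary)
    return MatingMatrix(
        group_id=group_id,
        treatment=treatment,
        males=tuple(f"m{i}" for i in range(binary.shape[0])),
        females=tuple(f"f{j}" for j in range(binary.shape[1])),
        binary=binary,
        counts=binary,
    )


class TestSCI:
    def test_equal_polyandry_mates(self):
        """All mates have two partners: SCI is their common value, 2."""
        mat = matrix_from([[1, 1, 0], [1, 1, 0], [0, 0, 1]])
        sci = ps.sperm_competition_intensity(mat)
        assert sci[0] == pytest.approx(2.0)

    def test_hand_computed_harmonic_mean(self):
        """Mates with polyandry 1 and 3: SCI = 2 / (1 + 1/3) = 1.5."""
        mat = matrix_from([[1, 1, 0], [0, 1, 0], [0, 1, 0]])
        sci = ps.sperm_competition_intensity(mat)
        assert sci[0] == pytest.approx(1.5)

    def test_single_mate(self):
        mat = matrix_from([[1, 0], [1, 0], [1, 0], [1, 1]])
        sci = ps.sperm_competition_intensity(mat)
        assert sci[0] == pytest.approx(4.0)

    def test_unmated_male_undefined(self):
        mat = matrix_from([[0, 0], [1, 1]])
        assert np.isnan(ps.sperm_competition_intensity(mat)[0])


class TestSCIC:
    def test_constant_sci_zero_slope(self):
        m = np.array([1.0, 2.0, 3.0, 2.0])
        sci = np.array([2.0, 2.0, 2.0, 2.0])
        assert standardised_slope(m, sci) == pytest.approx(0.0, abs=1e-12)

    def test_constructed_slope_exact(self):
        """SCI_std = 1 - 0.2 (M_std - 1) recovers slope -0.2 exactly."""
        m = np.array([1.0, 2.0, 3.0, 4.0, 2.0])
        m_std = m / m.mean()
        sci = 1 - 0.2 * (m_std - 1)  # already mean 1
        assert standardised_slope(m, sci * 3.7) == pytest.approx(-0.2, abs=1e-12)

    def test_saturated_matrix_degenerate(self):
        mats = [matrix_from(np.ones((4, 4), dtype=int))]
        res = ps.scic(mats)
        assert res.degenerate and np.isnan(res.slope)


class TestEnumeration:
    @pytest.mark.parametrize(
        "rows, cols",
        [((2, 1, 1), (2, 1, 1)), ((2, 2, 1), (2, 2, 1)), ((2, 2, 2, 2), (2, 2, 2, 2))],
    )
    def test_matches_brute_force(self, rows, cols):
        """Backtracking enumeration equals filtering all 2^(r*c) matrices."""
        fam = ps.enumerate_fixed_margins(rows, cols)
        keys = {m.tobytes() for m in fam}
        assert len(keys) == len(fam)
        n_r, n_c = len(rows), len(cols)
        brute = 0
        for bits in itertools.product((0, 1), repeat=n_r * n_c):
            m = np.array(bits, dtype=int).reshape(n_r, n_c)
            if tuple(m.sum(1)) == rows and tuple(m.sum(0)) == cols:
                brute += 1
                assert m.tobytes() in keys
        assert brute == len(fam)

    def test_margin_mismatch_rejected(self):
        with pytest.raises(ValueError, match="disagree"):
            ps.enumerate_fixed_margins((2, 1), (1, 1, 2))

    def test_limit_returns_none(self):
        assert ps.enumerate_fixed_margins((2, 2, 2), (2, 2, 2), limit=2) is None


class TestMCMCSampler:
    def test_margins_preserved_every_draw(self):
        rng = random.Random(0)
        binary = np.array([[1, 1, 0, 0], [1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 1]])
        for m in sample_fixed_margins_mcmc(binary, 50, rng):
            assert (m.sum(1) == binary.sum(1)).all()
            assert (m.sum(0) == binary.sum(0)).all()

    def test_uniform_over_enumerated_family(self):
        """Chain visits every fixed-margin configuration at its uniform
        frequency (chi-square on a 3x3 family, moderate sample)."""
        binary = np.array([[1, 1, 0], [1, 0, 0], [0, 0, 1]])  # margins (2,1,1)
        fam = ps.enumerate_fixed_margins(binary.sum(1), binary.sum(0))
        index = {m.tobytes(): i for i, m in enumerate(fam)}
        counts = np.zeros(len(fam))
        for m in sample_fixed_margins_mcmc(binary, 4000, random.Random(1)):
            counts[index[m.tobytes()]] += 1
        assert counts.min() > 0
        p = stats.chisquare(counts).pvalue
        assert p > 1e-3


class TestRandomizeSCIC:
    def test_margin_unique_groups_give_degenerate_null(self):
        """Nested (staircase) margins admit a single matrix: the null is a
        point mass at the observed SCIC and p_lower = 1."""
        nested = matrix_from([[1, 1, 1], [1, 1, 0], [1, 0, 0]])
        res = ps.randomize_scic([nested], n_rand=200, seed=0)
        assert res.unique_groups == ["g"]
        assert np.allclose(res.null_values, res.observed)
        assert res.p_lower == 1.0 and res.p_upper == 1.0

    def test_same_seed_identical_null(self, paired_small):
        ds = paired_small["control"]
        mats = ps.build_mating_matrices(ds.events, ds.rosters)[:10]
        a = ps.randomize_scic(mats, n_rand=100, seed=5)
        b = ps.randomize_scic(mats, n_rand=100, seed=5)
        assert np.array_equal(a.null_values, b.null_values)
        assert 0 <= a.p_lower <= 1 and 0 <= a.p_upper <= 1

    def test_mcmc_and_enumeration_nulls_agree(self):
        """The two sampling backends give the same null distribution of
        SCIC up to Monte-Carlo error on a 3x3 group."""
        mat = matrix_from([[1, 1, 0], [1, 0, 0], [0, 0, 1]])
        enum = ps.randomize_scic([mat], n_rand=3000, seed=1, method="enumerate")
        mcmc = ps.randomize_scic([mat], n_rand=3000, seed=2, method="mcmc")
        va = enum.null_values[~np.isnan(enum.null_values)]
        vb = mcmc.null_values[~np.isnan(mcmc.null_values)]
        assert np.mean(va) == pytest.approx(np.mean(vb), abs=0.05)
        assert stats.ks_2samp(va, vb).pvalue > 1e-3

    def test_null_range_shrinks_with_saturation(self):
        """Higher polyandry saturates the mating matrix and narrows the
        range of SCIC values the null can reach."""
        widths = []
        for refractory in (2.0, 8.0, 32.0):
            spans = []
            for seed in range(3):
                ds = ps.simulate_experiment(
                    ps.SimConfig(n_groups=15, refractory_mean=refractory, seed=seed)
                )
                mats = ps.build_mating_matrices(ds.events, ds.rosters)
                res = ps.randomize_scic(mats, n_rand=300, seed=seed)
                v = res.null_values[~np.isnan(res.null_values)]
                spans.append(v.max() - v.min())
            widths.append(np.mean(spans))
        assert widths[0] <= widths[1] <= widths[2]


class TestSCIRegressions:
    # Frozen from an R glm cross-fit (quasipoisson / quasibinomial with
    # Pearson dispersion) on the dataset regenerated below; estimates and
    # dispersion-scaled standard errors agree to 1e-6.
    R_T_MODEL = {
        "const": (2.06338114583220, 0.50674610461684),
        "M": (0.96231193207492, 0.07572586726270),
        "sci": (-0.83084313453681, 0.13810496356317),
        "group_fecundity": (0.00897345846908, 0.00242543167165),
        "replicate_id_R2": (0.14145024582628, 0.07212667437129),
    }
    R_P_MODEL = {
        "const": (3.57222471049335, 1.47301361825486),
        "sci": (-2.41263794072538, 0.40073279654322),
        "group_fecundity": (-0.00302919942918, 0.00693198204755),
        "replicate_id_R2": (-0.11514977767406, 0.18360732852698),
    }

    @staticmethod
    def _fixture_tables():
        ds = ps.simulate_experiment(ps.SimConfig(n_groups=20, seed=42))
        sdf = ps.summaries_to_frame(
            ps.compute_male_summaries(ds.events, ds.paternity, ds.rosters)
        )
        mats = ps.build_mating_matrices(ds.events, ds.rosters)
        return ps.sci_regressions(sdf, mats)

    def test_matches_reference_quasilikelihood_fit(self):
        tables = self._fixture_tables()
        for name, frozen in (("T_model", self.R_T_MODEL), ("P_model", self.R_P_MODEL)):
            tab = tables[name].set_index("term")
            for term, (est, se) in frozen.items():
                assert tab.loc[term, "estimate"] == pytest.approx(est, abs=1e-6)
                assert tab.loc[term, "se"] == pytest.approx(se, abs=1e-6)

    def test_share_declines_with_sperm_competition(self, paired_small):
        """Fair raffle: a male sharing his mates with more rivals sires a
        smaller share, so the SCI coefficient in the P model is negative."""
        ds = paired_small["SPR-"]
        sdf = ps.summaries_to_frame(
            ps.compute_male_summaries(ds.events, ds.paternity, ds.rosters)
        )
        mats = ps.build_mating_matrices(ds.events, ds.rosters)
        tab = ps.sci_regressions(sdf, mats)["P_model"].set_index("term")
        assert tab.loc["sci", "estimate"] < 0

    def test_constant_sci_inestimable(self):
        from tests.conftest import make_summaries_frame

        df = make_summaries_frame(
            T=[5.0, 6, 7, 8], M=[2.0, 2, 3, 2], P=[0.5] * 4, N=[6.0] * 4
        )
        mats = [
            matrix_from([[1, 1], [1, 1]], group_id=f"g{i}") for i in range(4)
        ]
        with pytest.raises(ValueError, match="constant"):
            ps.sci_regressions(df, mats)
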