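"""Statistical pipeline: oracles, identities, and calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from geomintruder.analysis import (
    SubjectShapeTable,
    confidence_regression,
    crossmodal_correlation,
    gg_epsilon,
    mixed_anova,
    model_comparison,
    subjectwise_slopes,
    tabulate,
)
from geomintruder.geometry import FAMILY_ORDER


def _table(data: np.ndarray, groups: list[str], measure="error") -> SubjectShapeTable:
    idx = [f"s{i:02d}" for i in range(data.shape[0])]
    return SubjectShapeTable(
        data=pd.DataFrame(data, index=idx, columns=list(FAMILY_ORDER)),
        group=pd.Series(groups, index=idx),
        measure=measure,
    )


class TestTabulate:
    def test_two_subject_toy_matches_hand_computation(self, sequence):
        rows = []
        for subj, wrong in (("a", {"square"}), ("b", {"square", "kite"})):
            for t, card in enumerate(sequence, start=1):
                rows.append(
                    {
                        "subject": subj,
                        "group": "blind",
                        "trial": t,
                        "card_id": card.card_id,
                        "family": card.family,
                        "complexity_rank": 1,
                        "chosen_position": 1,
                        "correct": card.family not in wrong,
                        "confidence": 10 if card.family not in wrong else 1,
                    }
                )
        t_err = tabulate(pd.DataFrame(rows), "error")
        assert t_err.data.loc["a", "square"] == 1.0
        assert t_err.data.loc["a"].drop("square").eq(0.0).all()
        assert t_err.data.loc["b", ["square", "kite"]].eq(1.0).all()
        t_conf = tabulate(pd.DataFrame(rows), "confidence")
        assert t_conf.data.loc["b", "kite"] == 1.0
        assert t_conf.data.loc["a", "rhombus"] == 10.0

    def test_all_correct_gives_zero_errors(self, sequence):
        rows = [
            {
                "subject": "a",
                "group": "blind",
                "trial": t,
                "card_id": c.card_id,
                "family": c.family,
                "complexity_rank": 1,
                "chosen_position": c.intruder_position,
                "correct": True,
                "confidence": 5,
            }
            for t, c in enumerate(sequence, 1)
        ] + [
            {
                "subject": "b",
                "group": "blind",
                "trial": t,
                "card_id": c.card_id,
                "family": c.family,
                "complexity_rank": 1,
                "chosen_position": c.intruder_position,
                "correct": True,
                "confidence": 5,
            }
            for t, c in enumerate(sequence, 1)
        ]
        t_err = tabulate(pd.DataFrame(rows), "error")
        assert (t_err.data.to_numpy() == 0).all()

    def test_missing_cells_reported(self, sequence):
        rows = [
            {
                "subject": "a",
                "group": "blind",
                "trial": 1,
                "card_id": "x",
                "family": "square",
                "complexity_rank": 1,
                "chosen_position": 1,
                "correct": True,
                "confidence": 5,
            }
        ]
        with pytest.raises(ValueError, match="missing"):
            tabulate(pd.DataFrame(rows), "error")


def _anova_oracle(y: np.ndarray, groups: np.ndarray):
    """Textbook balanced mixed-design sums of squares (equal group sizes)."""
    n, k = y.shape
    labels = np.unique(groups)
    M = y.mean()
    subj_means = y.mean(axis=1)
    ss_between_subj = k * ((subj_means - M) ** 2).sum()
    ss_group = sum(
        k * (groups == g).sum() * (y[groups == g].mean() - M) ** 2 for g in labels
    )
    ss_subj_within = ss_between_subj - ss_group
    col_means = y.mean(axis=0)
    ss_shape = n * ((col_means - M) ** 2).sum()
    ss_inter = sum(
        (groups == g).sum()
        * (
            (y[groups == g].mean(axis=0) - y[groups == g].mean() - col_means + M) ** 2
        ).sum()
        for g in labels
    )
    # within error: total within-subject SS minus shape and interaction
    ss_within_total = ((y - subj_means[:, None]) ** 2).sum()
    ss_err = ss_within_total - ss_shape - ss_inter
    g_, k_, n_ = len(labels), k, n
    f_group = (ss_group / (g_ - 1)) / (ss_subj_within / (n_ - g_))
    f_shape = (ss_shape / (k_ - 1)) / (ss_err / ((n_ - g_) * (k_ - 1)))
    f_inter = (ss_inter / ((g_ - 1) * (k_ - 1))) / (ss_err / ((n_ - g_) * (k_ - 1)))
    return f_group, f_shape, f_inter


class TestMixedAnova:
    def test_f_values_match_sums_of_squares_oracle(self, rng):
        y = rng.normal(size=(16, 11)) + np.linspace(0, 0.5, 11)
        groups = np.array(["blind"] * 8 + ["blindfolded"] * 8)
        y[8:] += 0.3
        rep = mixed_anova(_table(y, list(groups)))
        fg, fs, fi = _anova_oracle(y, groups)
        assert rep.effect("group")["F"] == pytest.approx(fg, rel=1e-6)
        assert rep.effect("shape")["F"] == pytest.approx(fs, rel=1e-6)
        assert rep.effect("interaction")["F"] == pytest.approx(fi, rel=1e-6)
        assert rep.effect("shape")["df1"] == 10
        assert rep.effect("shape")["df2"] == 140

    def test_identical_groups_give_null_group_effect(self, rng):
        half = rng.normal(size=(8, 11))
        y = np.vstack([half, half])
        rep = mixed_anova(_table(y, ["blind"] * 8 + ["blindfolded"] * 8))
        assert rep.effect("group")["F"] == pytest.approx(0.0, abs=1e-10)

    def test_epsilon_one_under_compound_symmetry(self):
        k = 11
        cov = 0.3 * np.ones((k, k)) + 0.7 * np.eye(k)
        assert gg_epsilon(cov) == pytest.approx(1.0)

    def test_epsilon_lower_bound_for_rank_one_covariance(self):
        k = 11
        v = np.linspace(1, 2, k)[:, None]
        assert gg_epsilon(v @ v.T) == pytest.approx(1.0 / (k - 1))

    def test_epsilon_estimate_within_bounds_on_data(self):
        local = np.random.default_rng(77)
        y = local.normal(size=(22, 11)) * np.linspace(1, 3, 11)
        rep = mixed_anova(_table(y, ["blind"] * 9 + ["blindfolded"] * 13))
        eps = rep.effect("shape")["eps"]
        assert 1 / 10 <= eps <= 1
        for eff in ("shape", "interaction"):
            row = rep.effect(eff)
            # corrected p is the original F referred to eps-scaled dfs
            assert row["p_gg"] == pytest.approx(
                float(stats.f.sf(row["F"], eps * row["df1"], eps * row["df2"]))
            )

    def test_null_calibration_of_corrected_within_effect(self):
        """Under an exchangeable null the uncorrected within-shape p is
        uniform and the GG-corrected test is not anticonservative.
        (250 simulated null experiments of 9 + 13 subjects.)"""
        rng = np.random.default_rng(2024)
        p_unc, p_gg = [], []
        for _ in range(250):
            y = rng.normal(size=(22, 11))
            rep = mixed_anova(_table(y, ["blind"] * 9 + ["blindfolded"] * 13))
            p_unc.append(rep.effect("shape")["p_uncorrected"])
            p_gg.append(rep.effect("shape")["p_gg"])
        ks = stats.kstest(p_unc, "uniform")
        assert ks.pvalue > 0.01
        rate = np.mean(np.array(p_gg) < 0.05)
        assert 0.005 <= rate <= 0.08

    def test_single_subject_group_rejected(self, rng):
        y = rng.normal(size=(3, 11))
        with pytest.raises(ValueError):
            mixed_anova(_table(y, ["blind", "blindfolded", "blindfolded"]))


class TestSubjectwiseSlopes:
    def test_exact_linear_profile_recovers_slope(self):
        ranks = np.arange(1, 12)
        y = np.vstack([0.041 * ranks] * 9 + [0.012 * ranks] * 13)
        rep = subjectwise_slopes(
            _table(y, ["blind"] * 9 + ["blindfolded"] * 13), direction="increasing"
        )
        gs = rep.group_stats.set_index("group")
        assert gs.loc["blind", "mean_slope"] == pytest.approx(0.041)
        assert gs.loc["blindfolded", "mean_slope"] == pytest.approx(0.012)
        assert gs.loc["blind", "df"] == 8
        assert gs.loc["blindfolded", "df"] == 12

    def test_flat_profile_gives_zero_slope(self):
        y = np.full((4, 11), 0.25)
        y[2:] = 0.4
        rep = subjectwise_slopes(_table(y, ["blind"] * 2 + ["blindfolded"] * 2))
        assert rep.subject_slopes.abs().max() == pytest.approx(0.0, abs=1e-12)

    def test_welch_df_within_satterthwaite_bounds(self, rng):
        y = rng.normal(size=(22, 11)) * 0.1 + np.linspace(0, 0.4, 11)
        rep = subjectwise_slopes(_table(y, ["blind"] * 9 + ["blindfolded"] * 13))
        assert min(9, 13) - 1 <= rep.welch_df <= 9 + 13 - 2

    def test_one_tailed_direction_respected(self):
        ranks = np.arange(1, 12)
        y = np.vstack([-0.1 * ranks + rk for rk in np.linspace(0, 0.1, 22)])
        rep = subjectwise_slopes(
            _table(y, ["blind"] * 9 + ["blindfolded"] * 13), direction="decreasing"
        )
        assert (rep.group_stats["p_one_tailed"] < 0.05).all()
        rep_wrong = subjectwise_slopes(
            _table(y, ["blind"] * 9 + ["blindfolded"] * 13), direction="increasing"
        )
        assert (rep_wrong.group_stats["p_one_tailed"] > 0.5).all()

    def test_too_few_levels_rejected(self):
        y = np.random.default_rng(0).normal(size=(4, 11))
        with pytest.raises(ValueError):
            subjectwise_slopes(
                _table(y, ["blind"] * 2 + ["blindfolded"] * 2),
                ranks=np.array([1.0] * 10 + [2.0]),
            )


class TestConfidenceRegression:
    def _tables(self, coefs, n1=9, n2=13, rng=None):
        rng = rng or np.random.default_rng(3)
        n = n1 + n2
        err = rng.uniform(0.1, 0.6, size=n)
        g = np.array([0.0] * n1 + [1.0] * n2)
        a, b_err, b_g, b_int = coefs
        conf = a + b_err * err + b_g * g + b_int * g * err
        t_err = _table(np.tile(err[:, None], (1, 11)), ["blind"] * n1 + ["blindfolded"] * n2)
        t_conf = _table(
            np.tile(conf[:, None], (1, 11)),
            ["blind"] * n1 + ["blindfolded"] * n2,
            measure="confidence",
        )
        return t_err, t_conf

    def test_noiseless_construction_recovered_exactly(self):
        t_err, t_conf = self._tables((8.0, -5.8, 0.5, -0.3))
        out = confidence_regression(t_err, t_conf)
        assert out.loc["const", "coef"] == pytest.approx(8.0)
        assert out.loc["error_rate", "coef"] == pytest.approx(-5.8)
        assert out.loc["group", "coef"] == pytest.approx(0.5)
        assert out.loc["group_x_error", "coef"] == pytest.approx(-0.3)

    def test_df_is_eighteen_for_twenty_two_subjects(self):
        t_err, t_conf = self._tables((8.0, -2.0, 0.1, 0.0))
        out = confidence_regression(t_err, t_conf)
        assert (out["df"] == 18).all()

    def test_constant_confidence_gives_zero_slopes(self):
        t_err, t_conf = self._tables((7.0, 0.0, 0.0, 0.0))
        out = confidence_regression(t_err, t_conf)
        assert out.loc["error_rate", "coef"] == pytest.approx(0.0, abs=1e-10)


class TestCrossmodalCorrelation:
    def test_identical_profiles(self):
        v = np.linspace(0.1, 0.6, 11)
        out = crossmodal_correlation(v, v)
        assert out["r2"] == pytest.approx(1.0)
        assert out["df"] == 9

    def test_orthogonal_profiles(self):
        a = np.tile([1.0, -1.0], 6)[:11]
        b = np.ones(11)
        b[0] += 1e-9  # avoid zero variance
        out = crossmodal_correlation(a, np.array([0, 0, 1, 1] * 3)[:11] * 1.0)
        assert out["r2"] < 0.2

    def test_matches_manual_pearson_formula(self, rng):
        a = rng.uniform(0, 1, 11)
        b = 0.5 * a + rng.normal(0, 0.2, 11)
        out = crossmodal_correlation(a, b)
        r_manual = ((a - a.mean()) * (b - b.mean())).sum() / (
            np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
        )
        assert out["r"] == pytest.approx(float(r_manual), rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            crossmodal_correlation(np.ones(11), np.linspace(0, 1, 11))


class TestModelComparison:
    def test_outcome_equal_to_one_predictor(self, rng):
        x1 = rng.normal(size=44)
        x2 = rng.normal(size=44)
        rep = model_comparison(x1, x1, x2)
        betas = rep.coef.set_index("predictor")["beta_std"]
        assert betas["symbolic"] == pytest.approx(1.0)
        assert betas["perceptual"] == pytest.approx(0.0, abs=1e-10)

    def test_df_is_forty_one_for_forty_four_points(self, rng):
        rep = model_comparison(
            rng.normal(size=44), rng.normal(size=44), rng.normal(size=44)
        )
        assert (rep.coef["df"] == 41).all()

    def test_standardized_betas_affine_invariant(self, rng):
        y = rng.normal(size=44)
        x1 = rng.normal(size=44)
        x2 = 0.4 * x1 + rng.normal(size=44)
        a = model_comparison(y, x1, x2).coef["beta_std"].to_numpy()
        b = model_comparison(
            3.0 * y - 7.0, -2.0 * x1 + 1.0, 0.5 * x2 + 4.0
        ).coef["beta_std"].to_numpy()
        np.testing.assert_allclose(np.abs(a), np.abs(b), rtol=1e-9)

    def test_null_outcome_betas_centered_at_zero(self, rng):
        x1 = rng.normal(size=44)
        x2 = 0.5 * x1 + rng.normal(size=44)
        betas = np.array(
            [
                model_comparison(rng.normal(size=44), x1, x2)
                .coef["beta_std"]
                .to_numpy()
                for _ in range(300)
            ]
        )
        se = betas.std(axis=0, ddof=1) / np.sqrt(len(betas))
        assert np.all(np.abs(betas.mean(axis=0)) < 3.5 * se + 1e-3)

    def test_collinear_predictors_rejected(self, rng):
        x = rng.normal(size=44)
        with pytest.raises(ValueError):
            model_comparison(rng.normal(size=44), x, 2.0 * x + 1.0)

    def test_bootstrap_agrees_with_wald_direction(self, rng):
        x1 = rng.normal(size=44)
        x2 = 0.3 * x1 + rng.normal(size=44)
        y = 0.6 * x1 + 0.2 * x2 + rng.normal(size=44) * 0.5
        wald = model_comparison(y, x1, x2)
        boot = model_comparison(y, x1, x2, n_bootstrap=400, seed=1)
        assert np.sign(wald.z_diff) == np.sign(boot.z_diff)
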