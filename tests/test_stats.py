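"""Statistical layer against exact enumeration, closed forms, and
independent library implementations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dynstates.stats import (
    bh_fdr,
    chi_square_2x2,
    demographic_comparison,
    fc_strength_ttest,
    mann_whitney_u,
    partial_correlation,
    temporal_group_comparison,
)


def exact_mwu_p(x, y):
    """Two-sided p by enumerating all rank assignments (small n only)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * len(y) / 2
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / total


def hand_bh(pvals):
    """Step-up p*m/rank with enforced monotonicity."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


class TestMannWhitney:
    def test_identical_multisets(self):
        u, z, p = mann_whitney_u([1, 2, 2, 3], [1, 2, 2, 3])
        assert z == 0 and p == 1

    def test_fully_separated_small_samples(self):
        u, z, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert abs(exact_mwu_p([1, 2, 3], [4, 5, 6]) - 0.1) < 1e-12
        assert z < 0  # first sample ranks below expectation -> negative z

    def test_sign_convention_spss(self):
        _, z_low, _ = mann_whitney_u([1, 2, 3], [10, 11, 12])
        _, z_high, _ = mann_whitney_u([10, 11, 12], [1, 2, 3])
        assert z_low < 0 < z_high

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            x = rng.standard_normal(6)
            y = rng.standard_normal(6)
            _, _, p = mann_whitney_u(x, y)
            assert abs(p - exact_mwu_p(x, y)) < 0.05

    def test_u_statistic_matches_scipy(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(12), rng.standard_normal(15)
        u, _, _ = mann_whitney_u(x, y)
        assert u == sps.mannwhitneyu(x, y, alternative="two-sided").statistic


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_application(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_exchangeable_equal_ps(self):
        assert np.allclose(bh_fdr([0.2] * 9), 0.2)

    def test_matches_hand_formula_on_random_inputs(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.random(rng.integers(1, 20))
            assert np.allclose(bh_fdr(p), hand_bh(p))

    def test_monotone_and_bounded(self):
        p = np.random.default_rng(3).random(15)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestChiSquare:
    def test_study_sex_table(self):
        # 32/34 male/female patients vs 36/30 controls
        chi2, p = chi_square_2x2([[32, 34], [36, 30]])
        assert abs(p - 0.486) < 1e-3

    def test_hand_formula(self):
        table = np.array([[32, 34], [36, 30]])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2_hand = ((table - expected) ** 2 / expected).sum()
        chi2, _ = chi_square_2x2(table)
        assert abs(chi2 - chi2_hand) < 1e-10
        assert round(chi2, 3) == 0.485

    def test_proportional_table_independent(self):
        chi2, p = chi_square_2x2([[10, 10], [20, 20]])
        assert chi2 == 0 and p == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestPartialCorrelation:
    def test_reduces_to_pearson_without_covariates(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        res = partial_correlation(x, y)
        r, p = sps.pearsonr(x, y)
        assert abs(res.r - r) < 1e-12
        assert abs(res.p - p) < 1e-10

    def test_three_variable_closed_form(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal(200)
        x = 0.5 * z + rng.standard_normal(200)
        y = -0.3 * z + rng.standard_normal(200)
        res = partial_correlation(x, y, z)
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        closed = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert abs(res.r - closed) < 1e-10

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {
                "x": rng.standard_normal(80),
                "y": rng.standard_normal(80),
                "a": rng.standard_normal(80),
                "b": rng.standard_normal(80),
            }
        )
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["a", "b"])
        res = partial_correlation(df.x, df.y, df[["a", "b"]].to_numpy())
        assert abs(res.r - float(ref["r"].iloc[0])) < 1e-10
        assert abs(res.p - float(ref["p_val"].iloc[0])) < 1e-8

    def test_null_after_removing_covariate_effect(self):
        # x independent of a covariate-driven y: the partial test should
        # reject at (close to) its nominal 5% rate
        rejections = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            Z = rng.standard_normal((500, 3))
            y = Z @ [1.0, -0.5, 0.3] + 0.5 * rng.standard_normal(500)
            x = rng.standard_normal(500)
            res = partial_correlation(x, y, Z)
            rejections += res.p < 0.05
        assert rejections / n_seeds <= 0.10

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            partial_correlation([1, 2, 3], [4, 5, 6], np.ones((3, 2)) * [[1], [2], [3]])


class TestFCStrengthTtest:
    def test_null_case_zero_t(self):
        cent = np.zeros((8, 1, 3))
        cent[:4] = [[1.0, 2.0, 3.0]]
        cent[4:] = [[1.0, 2.0, 3.0]]
        cent += np.tile(np.linspace(-1, 1, 8)[:, None, None], (1, 1, 3))
        mask = np.zeros(8, bool)
        mask[:4] = True
        # groups are mirror images -> identical means and variances
        cent[4:] = cent[:4]
        out = fc_strength_ttest(cent, mask)
        assert (out["t"].abs() < 1e-10).all()

    def test_planted_shift_detected_only_where_planted(self):
        rng = np.random.default_rng(7)
        cent = 0.1 * rng.standard_normal((40, 1, 10))
        mask = np.zeros(40, bool)
        mask[:20] = True
        cent[mask, 0, 3] += 1.0
        out = fc_strength_ttest(cent, mask)
        assert (out.loc[out["pair"] == 3, "p_fdr"] < 1e-6).all()
        assert (out.loc[out["pair"] != 3, "p_fdr"] > 0.05).all()

    def test_hand_sized_pooled_variance_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 6.0])
        cent = np.concatenate([a, b])[:, None, None]
        mask = np.array([True] * 3 + [False] * 3)
        out = fc_strength_ttest(cent, mask)
        sp = np.sqrt((2 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 4)
        t_hand = (a.mean() - b.mean()) / (sp * np.sqrt(2 / 3))
        assert abs(out["t"].iloc[0] - t_hand) < 1e-12


class TestDemographicComparison:
    def test_sex_row_matches_chi_square_and_numeric_rows_ttest(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(
            {
                "group": ["patient"] * 30 + ["control"] * 30,
                "sex": rng.integers(0, 2, 60),
                "age": rng.normal(33, 8, 60),
            }
        )
        table = demographic_comparison(df)
        assert set(table["variable"]) == {"sex (M/F)", "age"}
        age_p = float(table.loc[table["variable"] == "age", "p"].iloc[0])
        t, p_ref = sps.ttest_ind(
            df[df.group == "patient"].age, df[df.group == "control"].age
        )
        assert abs(age_p - p_ref) < 1e-12


class TestTemporalGroupComparison:
    def test_nine_row_family(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(40):
            group = "patient" if i < 20 else "control"
            fracs = rng.dirichlet(np.ones(4)) * 100
            row = {"group": group, "n_transitions": int(rng.integers(0, 10))}
            for s in range(1, 5):
                row[f"frac_state_{s}"] = fracs[s - 1]
                row[f"dwell_state_{s}"] = rng.uniform(0, 30)
            rows.append(row)
        table = temporal_group_comparison(pd.DataFrame(rows))
        assert len(table) == 9
        assert (table["p_fdr"] >= table["p_raw"] - 1e-15).all()
        assert (table["p_fdr"] <= 1).all()
        assert set(table["metric"]) == {
            "fractional_windows",
            "mean_dwell_time",
            "n_transitions",
        }
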