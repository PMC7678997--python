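import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fwtract.association import (
    adjusted_regression,
    bivariate_screen,
    fdr_adjust,
    joint_fw_mdt,
    paired_compare,
    measure_contrast_table,
    slope_association_table,
)
from fwtract.synthetic import make_cohort_table


class TestSpearman:
    def test_perfect_monotone(self, rng):
        x = rng.standard_normal(15)
        r = bivariate_screen(x, np.exp(2 * x), kind="spearman")
        assert r.statistic == pytest.approx(1.0)

    def test_exact_small_sample_p_matches_enumeration(self):
        """n = 7: the p-value equals the share of all 7! rank orderings with
        |rho| at least as extreme, enumerated here independently."""
        x = np.array([0.3, -1.2, 0.7, 2.1, -0.4, 1.5, 0.0])
        y = np.array([1.0, -0.8, 0.2, 1.9, 0.6, 1.1, -0.3])
        res = bivariate_screen(x, y, kind="spearman")
        rx, ry = stats.rankdata(x), stats.rankdata(y)

        def rho_of(rank_y):
            rank_y = np.asarray(rank_y, dtype=float)
            return np.corrcoef(rx, rank_y)[0, 1]

        obs = rho_of(ry)
        hits = sum(
            abs(rho_of(p)) >= abs(obs) - 1e-12 for p in itertools.permutations(ry)
        )
        assert res.statistic == pytest.approx(obs)
        assert res.p_value == pytest.approx(hits / math.factorial(7))

    def test_monotone_transform_invariance(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        base = bivariate_screen(x, y, kind="spearman")
        warped = bivariate_screen(np.exp(x), np.arctan(y) ** 3 + 5 * np.arctan(y), kind="spearman")
        assert warped.statistic == pytest.approx(base.statistic, abs=1e-12)
        assert warped.p_value == pytest.approx(base.p_value, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            bivariate_screen(np.ones(8), np.arange(8.0), kind="spearman")


class TestMannWhitney:
    def test_identical_multisets_give_central_u(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0])
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        r = bivariate_screen(x, labels, kind="mannwhitney")
        assert r.statistic == 4 * 4 / 2

    def test_exact_p_for_small_untied_samples(self, rng):
        a = rng.standard_normal(6)
        b = rng.standard_normal(7) + 0.5
        x = np.concatenate([a, b])
        labels = np.array([0] * 6 + [1] * 7)
        r = bivariate_screen(x, labels, kind="mannwhitney")
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert r.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            bivariate_screen(np.arange(4.0), np.zeros(4), kind="mannwhitney")


class TestPairedCompare:
    def test_identical_vectors(self):
        r = paired_compare(np.arange(5.0), np.arange(5.0))
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_clear_shift_detected(self, rng):
        before = rng.standard_normal(30)
        after = before + 1.0 + 1e-4 * rng.standard_normal(30)
        r = paired_compare(before, after)
        assert r.p_value < 1e-6 and r.statistic > 0

    def test_matches_closed_form(self, rng):
        before = rng.standard_normal(10)
        after = before + rng.standard_normal(10) * 0.5
        r = paired_compare(before, after)
        d = after - before
        t = d.mean() / (d.std(ddof=1) / np.sqrt(10))
        assert r.statistic == pytest.approx(t, rel=1e-12)
        assert r.p_value == pytest.approx(2 * stats.t.sf(abs(t), 9), rel=1e-12)

    def test_constant_nonzero_shift_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_compare(np.arange(5.0), np.arange(5.0) + 2.0)


class TestAdjustedRegression:
    def test_identity_fit(self, rng):
        x = rng.standard_normal(25)
        df = pd.DataFrame({"y": x, "x": x})
        r = adjusted_regression(df, "y", "x")
        assert r.beta["x"] == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_orthogonal_predictor(self, rng):
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        xc = x - x.mean()
        y -= xc * (xc @ (y - y.mean())) / (xc @ xc)  # orthogonal after centering
        r = adjusted_regression(pd.DataFrame({"y": y, "x": x}), "y", "x")
        assert abs(r.beta["x"]) < 1e-10

    def test_single_standardized_predictor_equals_pearson_r(self, rng):
        x = rng.standard_normal(50)
        y = 0.6 * x + rng.standard_normal(50)
        r = adjusted_regression(pd.DataFrame({"y": y, "x": x}), "y", "x")
        assert r.beta["x"] == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        """n = 20 with two covariates: beta and R^2 equal the explicit
        (X'X)^-1 X'y solution computed here from scratch."""
        n = 20
        df = pd.DataFrame(
            {
                "y": rng.standard_normal(n),
                "x": rng.standard_normal(n),
                "c1": rng.standard_normal(n),
                "c2": rng.uniform(60, 90, n),
            }
        )
        r = adjusted_regression(df, "y", "x", ["c1", "c2"])
        zy = (df.y - df.y.mean()) / df.y.std(ddof=1)
        zx = (df.x - df.x.mean()) / df.x.std(ddof=1)
        X = np.column_stack([np.ones(n), zx, df.c1, df.c2])
        coef = np.linalg.inv(X.T @ X) @ X.T @ zy.to_numpy()
        fitted = X @ coef
        ss_res = ((zy - fitted) ** 2).sum()
        ss_tot = ((zy - zy.mean()) ** 2).sum()
        assert r.beta["x"] == pytest.approx(coef[1], rel=1e-10)
        assert r.r_squared == pytest.approx(1 - ss_res / ss_tot, rel=1e-10)

    def test_joint_model_supports_two_predictors(self, rng):
        coh = make_cohort_table(68, effect_measure="mdt", effect_beta=-0.4, seed=1)
        out = joint_fw_mdt(coh)
        assert set(out.predictor) == {"fw", "mdt"}
        assert len(out) == 6

    def test_collinear_design_names_columns(self, rng):
        x = rng.standard_normal(30)
        df = pd.DataFrame({"y": rng.standard_normal(30), "x": x, "c1": 2 * x})
        with pytest.raises(ValueError, match="collinear") as exc:
            adjusted_regression(df, "y", "x", ["c1"])
        assert "c1" in str(exc.value)


class TestFdr:
    def test_all_ones_no_rejection(self):
        rej, adj = fdr_adjust(np.ones(12))
        assert not rej.any() and (adj == 1.0).all()

    def test_single_small_p_reduces_to_raw_threshold(self):
        rej, adj = fdr_adjust([0.01], q=0.05)
        assert rej[0] and adj[0] == pytest.approx(0.01)

    def test_matches_step_up_oracle(self):
        """Rejection set equals a literal evaluation of the step-up rule."""
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216])
        rej, adj = fdr_adjust(p, q=0.05)
        m = len(p)
        order = np.argsort(p)
        k_max = 0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= rank * 0.05 / m:
                k_max = rank
        oracle = np.zeros(m, dtype=bool)
        oracle[order[:k_max]] = True
        assert np.array_equal(rej, oracle)
        assert (np.diff(adj[order]) >= -1e-15).all()  # monotone adjusted p

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.2, 1.3])


class TestResultTables:
    def test_measure_contrast_layout_and_direction(self):
        coh = make_cohort_table(68, seed=2)
        t2 = measure_contrast_table(coh)
        assert list(t2.measure) == ["FA", "MD", "RD", "AD", "FW"]
        # corrected FA runs higher, corrected diffusivities lower
        fa = t2[t2.measure == "FA"].iloc[0]
        assert fa.fw_corrected_mean > fa.dti_mean
        md = t2[t2.measure == "MD"].iloc[0]
        assert md.fw_corrected_mean < md.dti_mean

    def test_slope_association_families_and_planted_effect(self):
        coh = make_cohort_table(68, effect_measure="mdt", effect_beta=-0.5, seed=3)
        t3 = slope_association_table(coh)
        assert set(t3.family) == {"dti", "fw_corrected"}
        assert len(t3) == (4 + 5) * 3
        hit = t3[(t3.measure == "mdt") & (t3.score == "slope_ist15")].iloc[0]
        assert hit.beta < -0.25 and hit.reject_fdr
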