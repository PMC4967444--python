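"""Pooled z-scoring, the random-effects panel model, and association statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import synovadce as sv
from synovadce.stats import (association, mean_change, pearson_fisher_ci, pooled_zscore,
                             standardized_change_panel)


def _random_panel(rng, n_subjects=40, types=("a", "b", "c")):
    rows = []
    for i in range(n_subjects):
        for t in types:
            base = rng.normal()
            rows.append({"subject_id": i, "visit": 0, "parameter_type": t, "y": base})
            rows.append({"subject_id": i, "visit": 1, "parameter_type": t,
                         "y": base + rng.normal(-0.4, 0.7)})
    return pd.DataFrame(rows)


def _mean_zdiff(panel, t):
    sub = panel[panel["parameter_type"] == t]
    wide = sub.pivot(index="subject_id", columns="visit", values="y")
    return (wide[1] - wide[0]).mean()


class TestPooledZscore:
    def test_output_is_standardized_over_pooled_sample(self):
        rng = np.random.default_rng(0)
        zb, zf = pooled_zscore(rng.normal(5, 2, 60), rng.normal(4, 2, 60))
        pooled = np.concatenate([zb, zf])
        assert pooled.mean() == pytest.approx(0.0, abs=1e-12)
        assert pooled.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        b, f = rng.normal(size=30), rng.normal(size=30)
        za = pooled_zscore(b, f)
        zb = pooled_zscore(3.2 * b + 7.0, 3.2 * f + 7.0)
        assert np.allclose(za[0], zb[0]) and np.allclose(za[1], zb[1])

    def test_reconstructs_printed_late_enhancement_change(self):
        """Two visits with means 3.10/2.35 and SDs 1.37/1.12 (n=93): the mean
        z-difference over the pooled sample is -0.58 to two decimals."""
        rng = np.random.default_rng(2)
        b = sv.exact_moment_values(93, 3.10, 1.37, rng)
        f = sv.exact_moment_values(93, 2.35, 1.12, rng)
        zb, zf = pooled_zscore(b, f)
        assert round(float((zf - zb).mean()), 2) == -0.58

    def test_zero_variance_is_hard_error(self):
        with pytest.raises(ValueError, match="variance"):
            pooled_zscore(np.ones(10), np.ones(10), name="ve")


class TestPanelModel:
    def test_null_change_gives_zero_estimates(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(20):
            for t in ("a", "b"):
                y = rng.normal()
                rows += [{"subject_id": i, "visit": v, "parameter_type": t, "y": y}
                         for v in (0, 1)]
        out = standardized_change_panel(pd.DataFrame(rows))
        assert np.allclose(out["estimate"], 0.0, atol=1e-12)

    @pytest.mark.parametrize("mode", ["pooled", "per_parameter"])
    def test_coefficient_equals_mean_zdiff_oracle(self, mode):
        rng = np.random.default_rng(4)
        panel = _random_panel(rng)
        out = standardized_change_panel(panel, mode=mode).set_index("parameter_type")
        for t in ("a", "b", "c"):
            assert out.loc[t, "estimate"] == pytest.approx(_mean_zdiff(panel, t), abs=1e-10)

    def test_ci_brackets_estimate(self):
        panel = _random_panel(np.random.default_rng(5))
        out = standardized_change_panel(panel)
        assert (out["ci_low"] <= out["estimate"]).all()
        assert (out["estimate"] <= out["ci_high"]).all()

    def test_unbalanced_panel_rejected(self):
        panel = _random_panel(np.random.default_rng(6))
        with pytest.raises(ValueError, match="balanced"):
            standardized_change_panel(panel.iloc[:-1])

    def test_raw_change_over_pooled_sd_equals_coefficient(self):
        """Balanced-panel identity on the raw scale, asserted to 1e-10."""
        rng = np.random.default_rng(7)
        b = rng.normal(10, 3, 50)
        f = b + rng.normal(-1, 1, 50)
        zb, zf = pooled_zscore(b, f)
        panel = pd.DataFrame({
            "subject_id": np.tile(np.arange(50), 2),
            "visit": np.repeat([0, 1], 50),
            "parameter_type": "x",
            "y": np.concatenate([zb, zf])})
        coef = standardized_change_panel(panel)["estimate"].iloc[0]
        pooled_sd = np.concatenate([b, f]).std(ddof=1)
        assert coef == pytest.approx((f - b).mean() / pooled_sd, abs=1e-10)

    def test_estimates_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(8)
        b = rng.normal(10, 3, 40)
        f = b + rng.normal(-1, 1, 40)
        cohort = pd.DataFrame({
            "subject_id": np.tile([f"S{i}" for i in range(40)], 2),
            "visit": np.repeat(["baseline", "followup"], 40),
            "x": np.concatenate([b, f]),
            "koos_pain": np.concatenate([rng.uniform(30, 60, 40), rng.uniform(40, 80, 40)])})
        r1 = sv.responsiveness_table(cohort, parameters=["x"])
        cohort["x"] = 100.0 * cohort["x"] + 3.0
        r2 = sv.responsiveness_table(cohort, parameters=["x"])
        assert r1.loc[0, "estimate"] == pytest.approx(r2.loc[0, "estimate"], abs=1e-10)

    def test_koos_reported_improvement_negative(self):
        df = sv.exact_moment_cohort(93, seed=9)
        resp = sv.responsiveness_table(df).set_index("parameter_type")
        assert resp.loc["koos_pain", "orientation"] == "improvement-negative"
        assert resp.loc["koos_pain", "estimate"] < 0       # pain improved
        assert resp.loc["koos_pain", "raw_mean_change"] > 0  # KOOS score rose


class TestMeanChange:
    def test_identical_pairs_zero(self):
        m, lo, hi = mean_change(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        assert m == 0.0 and lo <= 0.0 <= hi

    def test_exact_moment_volume_change(self):
        rng = np.random.default_rng(10)
        b = sv.exact_moment_values(93, 9601.0, 5251.0, rng)
        f = sv.exact_moment_values(93, 8119.0, 4353.0, rng)
        m, _, _ = mean_change(b, f)
        assert m == pytest.approx(-1482.0, abs=1e-9)

    def test_ci_width_shrinks_as_sqrt_n(self):
        rng = np.random.default_rng(11)
        widths = []
        for n in (50, 200, 800):
            b = rng.normal(0, 1, n)
            f = b + rng.normal(-1, 2, n)
            _, lo, hi = mean_change(b, f)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]
        assert widths[0] / widths[2] == pytest.approx(4.0, rel=0.35)


class TestAssociation:
    def test_perfect_linearity(self):
        d = np.linspace(-2, 2, 20)
        res = association(d, 2.0 * d)
        assert res.r == pytest.approx(1.0)
        assert res.b == pytest.approx(2.0)

    def test_independent_changes_near_zero(self):
        rng = np.random.default_rng(12)
        res = association(rng.normal(size=5000), rng.normal(size=5000))
        assert abs(res.r) < 0.05

    def test_sign_coherence_b_and_r(self):
        rng = np.random.default_rng(13)
        d = rng.normal(size=200)
        y = -0.5 * d + rng.normal(size=200)
        res = association(d, y)
        assert np.sign(res.b) == np.sign(res.r) == -1

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            association(np.ones(10), np.arange(10.0))

    def test_fisher_ci_matches_scipy(self):
        """Independent route: scipy's pearsonr Fisher interval agrees."""
        rng = np.random.default_rng(14)
        x, y = rng.normal(size=80), rng.normal(size=80)
        r, lo, hi = pearson_fisher_ci(x, y)
        ref = sps.pearsonr(x, y)
        ci = ref.confidence_interval()
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert lo == pytest.approx(ci.low, abs=1e-9)
        assert hi == pytest.approx(ci.high, abs=1e-9)

    def test_b_ci_matches_ols_oracle(self):
        """Slope CI cross-checked against the closed-form OLS t-interval."""
        rng = np.random.default_rng(15)
        x = rng.normal(size=60)
        y = 1.5 * x + rng.normal(size=60)
        res = association(x, y)
        xc = x - x.mean()
        b = float(xc @ (y - y.mean()) / (xc @ xc))
        resid = (y - y.mean()) - b * xc
        se = np.sqrt(resid @ resid / (60 - 2) / (xc @ xc))
        tcrit = sps.t.ppf(0.975, 58)
        assert res.b == pytest.approx(b, abs=1e-10)
        assert res.b_ci_low == pytest.approx(b - tcrit * se, abs=1e-8)
        assert res.b_ci_high == pytest.approx(b + tcrit * se, abs=1e-8)
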