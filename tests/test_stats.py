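"""Repeatability, group comparison, feature tables and model fitting."""

import numpy as np
import pandas as pd
import pytest

from densetile import (
    ModelSpec,
    build_feature_table,
    coefficient_of_variation,
    fit_model,
    repeatability,
    welch_t_test,
)
from densetile.stats import replicate_groups


def anova_oracle(groups):
    """Independent sums-of-squares ANOVA + intraclass correlation."""
    sizes = np.array([len(g) for g in groups], dtype=float)
    N, k = sizes.sum(), len(groups)
    allv = np.concatenate([np.asarray(g, float) for g in groups])
    grand = allv.mean()
    ssb = sum(n * (np.mean(g) - grand) ** 2 for n, g in zip(sizes, groups))
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    msb, msw = ssb / (k - 1), ssw / (N - k)
    n0 = (N - (sizes**2).sum() / N) / (k - 1)
    sa2 = max(0.0, (msb - msw) / n0)
    return sa2 / (msw + sa2) if (msw + sa2) > 0 else 1.0, sa2, msw


class TestRepeatability:
    def test_perfect_replicates(self):
        res = repeatability([[10, 10], [20, 20], [30, 30]])
        assert res.r == 1.0
        assert res.s2_within == 0.0

    def test_identical_group_means_truncates_to_zero(self):
        # groups share the same mean; all variance is within groups
        res = repeatability([[9, 11], [8, 12], [10.5, 9.5]])
        assert res.r == 0.0
        assert res.s2_between_raw <= 0

    def test_all_observations_identical_is_degenerate(self):
        res = repeatability([[5, 5], [5, 5]])
        assert res.r == 1.0
        assert res.degenerate

    def test_unbalanced_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(9)
        groups = [list(rng.normal(m, 1.0, size=n)) for m, n in
                  [(10, 2), (12, 5), (15, 3), (9, 7)]]
        res = repeatability(groups)
        r, sa2, msw = anova_oracle(groups)
        assert res.r == pytest.approx(r, abs=1e-10)
        assert res.s2_between == pytest.approx(sa2, abs=1e-10)
        assert res.s2_within == pytest.approx(msw, abs=1e-10)

    def test_identity_r_times_total_equals_between(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            groups = [list(rng.normal(rng.uniform(0, 50), rng.uniform(0.1, 3), size=rng.integers(2, 8)))
                      for _ in range(int(rng.integers(2, 10)))]
            res = repeatability(groups)
            assert res.r * (res.s2_within + res.s2_between) == pytest.approx(
                res.s2_between, abs=1e-12
            )

    def test_requires_two_groups_and_replication(self):
        with pytest.raises(ValueError):
            repeatability([[1, 2]])
        with pytest.raises(ValueError):
            repeatability([[1], [2]])


class TestCoefficientOfVariation:
    def test_constant_values(self):
        assert coefficient_of_variation([5.0, 5.0, 5.0]) == 0.0

    def test_hand_arithmetic(self):
        assert coefficient_of_variation([90.0, 110.0]) == pytest.approx(14.1421, abs=1e-3)

    def test_scale_invariance(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(10, 100, size=50)
        assert coefficient_of_variation(3.7 * x) == pytest.approx(
            coefficient_of_variation(x), rel=1e-12
        )

    def test_rejects_non_positive_mean(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])


def welch_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df


class TestWelch:
    def test_identical_groups_give_zero(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0

    def test_matches_closed_form(self):
        res = welch_t_test([1, 2, 3], [2, 3, 4])
        t, df = welch_oracle([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-10)
        from scipy import stats as sps

        assert res.p == pytest.approx(2 * sps.t.sf(abs(t), df), abs=1e-12)

    def test_equal_variance_equal_n_matches_pooled(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 30)
        from scipy import stats as sps

        res = welch_t_test(a, b)
        pooled = sps.ttest_ind(a, b, equal_var=True)
        # with equal sizes the Welch statistic equals the pooled statistic
        assert res.t == pytest.approx(pooled.statistic, abs=1e-10)

    def test_null_rejection_rate_calibrated(self):
        """Equal-mean simulations reject at about the nominal 5% level."""
        rng = np.random.default_rng(14)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            a = rng.normal(0, 1, 50)
            b = rng.normal(0, 1.5, 50)
            if welch_t_test(a, b).p < 0.05:
                rejections += 1
        rate = rejections / reps
        assert 0.035 <= rate <= 0.065

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0, 1.0], [1.0, 1.0])


def toy_tables(n_probes=40, n_arrays=4, seed=0, edge_every=10):
    """Minimal probes/features/matrix/samples frames for table building."""
    rng = np.random.default_rng(seed)
    probes = pd.DataFrame(
        {
            "probe_id": [f"chrT:{i * 60}-{i * 60 + 60}" for i in range(n_probes)],
            "offset": [6 if i % 2 else 26 for i in range(n_probes)],
            "segment_id": [i // 5 for i in range(n_probes)],
            "segment_length": 1000,
            "position": [(i % 5) + 1 for i in range(n_probes)],
            "is_edge_5p": [i % edge_every == 0 for i in range(n_probes)],
            "is_edge_3p": False,
            "distance": [200 if i % edge_every == 0 else np.nan for i in range(n_probes)],
        }
    )
    features = pd.DataFrame(
        {
            "probe_id": probes["probe_id"],
            "gc_percent": rng.uniform(20, 70, n_probes),
            "poly_a": rng.integers(1, 8, n_probes),
            "poly_c": rng.integers(0, 6, n_probes),
            "poly_g": rng.integers(0, 6, n_probes),
            "poly_t": rng.integers(1, 8, n_probes),
            "off_target_matches": rng.integers(0, 40, n_probes),
            "free_energy": rng.normal(0.5, 1.0, n_probes),
        }
    )
    rows = []
    for p in probes["probe_id"]:
        for j in range(n_arrays):
            rows.append(
                {
                    "probe_id": p,
                    "array_id": f"A{j}",
                    "raw_signal": float(rng.uniform(100, 1000)),
                    "background": float(rng.uniform(25, 45)),
                }
            )
    matrix = pd.DataFrame(rows)
    samples = pd.DataFrame(
        {
            "array_id": [f"A{j}" for j in range(n_arrays)],
            "dog_id": [f"D{j}" for j in range(n_arrays)],
            "dna_source": ["blood"] * (n_arrays - 1) + ["saliva"],
        }
    )
    return probes, features, matrix, samples


class TestBuildFeatureTable:
    def test_position_preset_is_cross_product(self):
        probes, features, matrix, samples = toy_tables(100, 8)
        table = build_feature_table(probes, features, matrix, samples, preset="position")
        assert len(table) == 800
        assert "position" in table.columns and "log_distance" not in table.columns
        assert table["position"].notna().all()

    def test_distance_preset_restricted_to_edge_probes(self):
        probes, features, matrix, samples = toy_tables(40, 5)
        table = build_feature_table(probes, features, matrix, samples, preset="distance")
        n_edge = int(probes["is_edge_5p"].sum())
        assert len(table) == n_edge * 5
        assert np.allclose(table["log_distance"], np.log(200.0))

    def test_transforms_applied(self):
        probes, features, matrix, samples = toy_tables(10, 2)
        table = build_feature_table(probes, features, matrix, samples, preset="position")
        merged = table.merge(features, on="probe_id")
        assert np.allclose(merged["log_off_targets"], np.log1p(merged["off_target_matches"]))
        assert np.allclose(merged["log_segment_length"], np.log(1000.0))

    def test_repeat_preset_requires_subset_and_drops_off_targets(self):
        probes, features, matrix, samples = toy_tables(20, 2)
        with pytest.raises(ValueError, match="repeat"):
            build_feature_table(probes, features, matrix, samples, preset="repeat")
        subset = pd.DataFrame(
            {
                "probe_id": probes["probe_id"][:8],
                "repeat_class": ["LINE"] * 4 + ["SINE"] * 4,
                "repeat_length": 340,
            }
        )
        table = build_feature_table(
            probes, features, matrix, samples, preset="repeat", repeat_probes=subset
        )
        assert len(table) == 16
        assert "log_off_targets" not in table.columns
        assert "log_repeat_length" in table.columns


def simulate_table(n_probes, n_arrays, beta, sd_probe, sd_resid, seed):
    """Small generating model for fitting tests (linear in all terms)."""
    rng = np.random.default_rng(seed)
    probes, features, matrix, samples = toy_tables(n_probes, n_arrays, seed=seed)
    table = build_feature_table(probes, features, matrix, samples, preset="position")
    probe_eff = dict(
        zip(probes["probe_id"], rng.normal(0, sd_probe, n_probes))
    )
    eta = np.full(len(table), 5.0)
    for term, b in beta.items():
        if term == "offset26":
            eta += b * (table["offset"] == 26).to_numpy()
        else:
            eta += b * table[term].to_numpy(dtype=float)
    eta += table["probe_id"].map(probe_eff).to_numpy()
    eta += rng.normal(0, sd_resid, len(table))
    table["log_intensity"] = eta
    return table


class TestFitModel:
    BETA = {
        "probe_gc": 0.069,
        "log_off_targets": 0.46,
        "free_energy": 0.153,
        "log_background": 0.142,
        "position": 0.01,
        "offset26": 0.19,
    }

    def test_no_random_effects_matches_ols_oracle(self):
        """Without grouping variance REML reduces to ordinary least squares."""
        import statsmodels.api as sm

        table = simulate_table(150, 4, self.BETA, sd_probe=0.0, sd_resid=0.05, seed=21)
        fit = fit_model(table, "position", spline_knots=0)
        terms = fit.terms.set_index("term")
        from densetile.stats import ModelSpec, _build_design

        X, names, _, _, _ = _build_design(table, ModelSpec.for_preset("position"), 0)
        ols = sm.OLS(table["log_intensity"].to_numpy(), X).fit()
        # the estimated variance ratio is near-zero but not exactly zero,
        # so agreement is to a tolerance far below every coefficient's SE
        for i, name in enumerate(names):
            if name in terms.index:
                assert terms.loc[name, "estimate"] == pytest.approx(ols.params[i], abs=1e-4)

    def test_recovers_generating_coefficients(self):
        table = simulate_table(400, 6, self.BETA, sd_probe=0.1, sd_resid=0.02, seed=30)
        fit = fit_model(table, "position")
        terms = fit.terms.set_index("term")
        for term, b in self.BETA.items():
            if term == "offset26":
                est, se = fit.factor_effects["offset"]["26"]
            else:
                est, se = terms.loc[term, "estimate"], terms.loc[term, "se"]
            assert abs(est - b) < 3 * se, term

    def test_reference_offset_level_is_zero(self):
        table = simulate_table(60, 3, self.BETA, 0.05, 0.05, seed=23)
        fit = fit_model(table, "position")
        assert fit.factor_effects["offset"]["6"] == (0.0, 0.0)
        assert fit.factor_effects["offset"]["26"][1] > 0

    def test_variance_components_recovered(self):
        table = simulate_table(500, 6, {}, sd_probe=0.2, sd_resid=0.05, seed=24)
        fit = fit_model(table, "position")
        assert fit.variance_components["probe"] == pytest.approx(0.04, rel=0.35)
        assert fit.variance_components["residual"] == pytest.approx(0.0025, rel=0.25)

    def test_agrees_with_general_mixed_model_backend(self):
        """Profiled REML matches statsmodels MixedLM where the latter converges."""
        table = simulate_table(120, 5, self.BETA, sd_probe=0.1, sd_resid=0.08, seed=25)
        ours = fit_model(table, "position", method="reml", spline_knots=0)
        theirs = fit_model(table, "position", method="mixedlm", spline_knots=0)
        a = ours.terms.set_index("term")["estimate"]
        b = theirs.terms.set_index("term")["estimate"]
        common = [t for t in a.index if np.isfinite(a[t]) and np.isfinite(b[t])]
        assert len(common) >= 8
        assert np.allclose(a[common], b[common], rtol=1e-3, atol=1e-5)
        assert ours.variance_components["probe"] == pytest.approx(
            theirs.variance_components["probe"], rel=0.05
        )

    def test_zero_variance_covariate_dropped(self):
        table = simulate_table(50, 3, self.BETA, 0.05, 0.05, seed=26)
        table["free_energy"] = 1.23
        fit = fit_model(table, "position")
        assert "free_energy" in fit.dropped_terms
        row = fit.terms.set_index("term").loc["free_energy"]
        assert np.isnan(row["estimate"])

    def test_ols_fallback_flagged(self):
        table = simulate_table(50, 3, self.BETA, 0.05, 0.05, seed=27)
        fit = fit_model(table, "position", method="ols")
        assert fit.method == "ols"
        assert "probe" not in fit.variance_components

    def test_spline_detects_nonlinearity(self):
        """A strongly non-linear homopolymer effect yields a small spline p."""
        table = simulate_table(300, 4, {}, sd_probe=0.0, sd_resid=0.02, seed=28)
        x = table["poly_a"].to_numpy(dtype=float)
        table["log_intensity"] = 5.0 + 0.3 * (x - 4.0) ** 2 + np.random.default_rng(1).normal(
            0, 0.02, len(table)
        )
        fit = fit_model(table, "position")
        sp = fit.spline_tests.set_index("term")
        assert sp.loc["s(poly_a)", "p"] < 1e-6
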