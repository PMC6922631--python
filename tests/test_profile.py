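"""ISRA fitting, sparsification, grouping, AIC, permutation and bootstrap."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import nnls

from topoprofile.errors import DataError
from topoprofile.metrics import METRIC_NAMES
from topoprofile.profile import (
    TopologicalProfile,
    aic,
    bootstrap_profiles,
    group_descriptors,
    isra,
    isra_fit,
    late_stage_profile,
    permutation_test,
    single_metric_fits,
    sparsify,
    variance_explained,
)
from topoprofile.progression import ProgressionConfig

from conftest import build_zcohort


class TestIsra:
    def test_identity_design_returns_y(self):
        Y = np.array([0.2, 0.0, 0.7, 0.1, 0.5, 0.3, 0.9, 0.4, 0.6])
        beta, _, _ = isra(Y, np.eye(9))
        assert np.allclose(beta, Y, atol=1e-10)

    def test_ones_column_fits_mean(self):
        beta, _, _ = isra(np.array([0.3, 0.3, 0.3]), np.ones((3, 1)))
        assert beta[0] == pytest.approx(0.3, abs=1e-10)

    def test_exact_recovery_full_rank(self, design_full):
        _, _, design = design_full
        rng = np.random.default_rng(0)
        beta_true = np.abs(rng.random(9)) * 0.5
        Y = design.values @ beta_true
        # the collinear metric columns of a real design need deep convergence
        beta, _, _ = isra(Y, design.values, tol=1e-12, max_iter=500_000)
        ref, _ = nnls(design.values, Y)
        assert np.abs(beta - ref).max() < 1e-4

    def test_oracle_equivalence_random_instances(self):
        for s in range(20):
            rng = np.random.default_rng(500 + s)
            A = rng.random((41, 9))
            Y = rng.random(41)
            beta, history, _ = isra(Y, A)
            ref, _ = nnls(A, Y)
            assert np.abs(beta - ref).max() < 1e-4
            assert all(b <= a + 1e-9 for a, b in zip(history, history[1:]))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 100_000))
    def test_nonnegativity_preserved(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.random((12, 5))
        Y = rng.random(12)
        beta, _, _ = isra(Y, A, max_iter=200)
        assert (beta >= 0).all()

    def test_negative_input_rejected(self):
        with pytest.raises(DataError):
            isra(np.array([-0.1, 0.2]), np.ones((2, 1)))
        with pytest.raises(DataError):
            isra(np.array([0.1, 0.2]), np.ones((2, 1)), init=[0.0])

    def test_all_zero_rates_yield_zero_profile(self, design_small):
        _, _, design = design_small
        prof = isra_fit(np.zeros(design.values.shape[0]), design)
        assert (prof.beta == 0).all()
        assert prof.exact_fit

    def test_parameter_recovery_cohort_conditions(self):
        """Cohort-averaged rates from 50 subjects identify the weights."""
        errs = []
        for s in range(20):
            rng = np.random.default_rng(9000 + s)
            A = rng.random((41, 9))
            A[:, -1] = 1.0
            beta_true = rng.choice([0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7], size=9)
            Yj = A @ beta_true + rng.normal(0, 0.05, (50, 41))
            Y = np.clip(Yj.mean(axis=0), 0, None)
            beta = isra_fit(Y, A, scale_Y=False).beta.to_numpy()
            errs.append(np.abs(beta - beta_true).max())
        assert np.mean(errs) < 0.05


class TestSparsifyAndGroup:
    def _profile(self, mapping):
        beta = pd.Series(0.0, index=list(METRIC_NAMES))
        for k, v in mapping.items():
            beta[k] = v
        return TopologicalProfile(beta=beta)

    def test_threshold_is_strict_below(self):
        prof = self._profile({"closeness": 0.01, "betweenness": 0.21,
                              "weighted_degree": 0.10})
        out = sparsify(prof)
        assert out.beta_sparse["closeness"] == 0.0
        assert out.beta_sparse["betweenness"] == 0.21
        assert out.beta_sparse["weighted_degree"] == 0.10  # boundary kept

    def test_all_below_threshold_zeroes(self, caplog):
        prof = self._profile({"closeness": 0.05})
        with caplog.at_level("WARNING"):
            out = sparsify(prof)
        assert (out.beta_sparse == 0).all()

    def test_worked_example_descriptor_sums(self):
        # two surviving centrality metrics plus a network-proximity weight
        prof = sparsify(self._profile(
            {"betweenness": 0.21, "clustering": 0.19, "shortest_path": 0.65}
        ))
        sums = group_descriptors(prof)
        assert sums["centrality"] == pytest.approx(0.40)
        assert sums["network_proximity"] == pytest.approx(0.65)
        pct = group_descriptors(prof, percentages=True)
        assert pct["centrality"] == 40.0
        assert pct["network_proximity"] == 60.0

    def test_constant_only_profile(self):
        prof = sparsify(self._profile({"constant": 0.19}))
        sums = group_descriptors(prof)
        assert sums["constant_progression"] == pytest.approx(0.19)
        assert sums.drop("constant_progression").abs().sum() == 0.0

    def test_uniform_two_descriptor_split(self):
        prof = sparsify(self._profile({"shortest_path": 0.3, "spatial_distance": 0.3}))
        pct = group_descriptors(prof, percentages=True)
        assert pct["network_proximity"] == 50.0
        assert pct["cortical_proximity"] == 50.0

    def test_zero_total_percentages(self):
        prof = sparsify(self._profile({"closeness": 0.01}))
        pct = group_descriptors(prof, percentages=True)
        assert (pct == 0).all()


class TestVarianceExplained:
    def test_noiseless_full_profile_r2_one(self, design_small):
        _, _, design = design_small
        Y = design.values @ np.array([0.3, 0, 0, 0, 0, 0, 0.5, 0, 0.1])
        r2 = variance_explained(Y, design)
        assert r2["full_profile"] == pytest.approx(1.0, abs=1e-6)

    def test_constant_only_explains_nothing_centered(self, design_small):
        _, _, design = design_small
        rng = np.random.default_rng(1)
        Y = rng.random(design.values.shape[0])
        r2 = variance_explained(Y, design)
        assert r2["constant_only"] == pytest.approx(0.0, abs=1e-6)
        # uncentered view gives the constant model credit for the mean level
        r2u = variance_explained(Y, design, centered=False)
        assert r2u["constant_only"] > 0.5

    def test_uncorrelated_descriptor_r2_small(self, design_small):
        _, _, design = design_small
        rng = np.random.default_rng(2)
        c = design.sigma["spatial_distance"].to_numpy()
        y = rng.random(len(c))
        cc = c - c.mean()
        y = y - (y @ cc) / (cc @ cc) * cc     # decorrelate from the column
        y = y - y.min() + 0.01
        r2 = variance_explained(y, design)
        # the descriptor has no explanatory power (R2 at or below zero;
        # no-intercept fits can score below the mean predictor)
        assert r2["cortical_proximity"] < 0.15

    def test_noise_lowers_r2_on_average(self, design_small):
        _, _, design = design_small
        beta = np.array([0.3, 0, 0, 0, 0, 0, 0.5, 0, 0.1])
        base = design.values @ beta
        means = []
        for sd in (0.05, 0.3):
            vals = []
            for rep in range(20):
                rng = np.random.default_rng(100 * rep + int(sd * 1000))
                Y = np.clip(base + rng.normal(0, sd, len(base)), 0, None)
                vals.append(variance_explained(Y, design)["full_profile"])
            means.append(np.mean(vals))
        assert means[1] < means[0]


class TestAic:
    def test_direct_evaluation(self):
        val, exact = aic(rss=0.41, n_params=5, n_regions=41)
        assert not exact
        assert val == pytest.approx(10 + 41 * np.log(0.01), abs=0.01)
        assert val == pytest.approx(-178.81, abs=0.01)

    def test_parameter_penalty(self):
        a1, _ = aic(0.5, 1, 41)
        a5, _ = aic(0.5, 5, 41)
        assert a5 - a1 == pytest.approx(8.0)

    def test_exact_fit_flag(self):
        val, exact = aic(0.0, 5, 41)
        assert exact and val == -np.inf

    def test_epicenter_metrics_cost_two_params(self, design_small):
        _, _, design = design_small
        rng = np.random.default_rng(3)
        Y = rng.random(design.values.shape[0])
        table = single_metric_fits(Y, design)
        assert table.loc["shortest_path", "n_params"] == 2
        assert table.loc["spatial_distance", "n_params"] == 2
        assert table.loc["betweenness", "n_params"] == 1


class TestPermutation:
    def test_constant_rates_give_p_one(self, design_small):
        _, _, design = design_small
        Y = np.full(design.values.shape[0], 0.4)
        table = permutation_test(Y, design, B=99, seed=0)
        assert (table["p"] == 1.0).all()

    def test_strong_signal_attains_lower_bound(self, design_small):
        _, _, design = design_small
        rng = np.random.default_rng(4)
        Y = design.sigma["betweenness"].to_numpy() + rng.normal(0, 0.01, design.values.shape[0])
        table = permutation_test(np.clip(Y, 0, None), design, B=199, seed=1)
        assert table.loc["betweenness", "p"] == pytest.approx(1 / 200)
        assert table.loc["betweenness", "p_bonferroni"] == pytest.approx(8 / 200)

    def test_p_stable_across_b(self, design_small):
        _, _, design = design_small
        rng = np.random.default_rng(5)
        Y = np.clip(
            0.6 * design.sigma["betweenness"].to_numpy() + rng.normal(0, 0.1, design.values.shape[0]),
            0, None,
        )
        p1 = permutation_test(Y, design, B=99, seed=2).loc["betweenness", "p"]
        p2 = permutation_test(Y, design, B=199, seed=3).loc["betweenness", "p"]
        assert abs(p1 - p2) < 0.08


class TestLateStage:
    def test_single_metric_end_stage_concentrates(self, design_small):
        _, _, design = design_small
        col = design.sigma["spatial_distance"].to_numpy()
        z = build_zcohort([col, col * 1.1], ["p1", "p2"], [60.0, 60.0],
                          list(design.sigma.index))
        prof = late_stage_profile(z, design)
        share = prof.beta["spatial_distance"] / prof.beta.sum()
        assert share > 0.9

    def test_uniform_end_stage_is_constant_dominated(self, design_small):
        _, _, design = design_small
        n = design.values.shape[0]
        z = build_zcohort([np.full(n, 2.0), np.full(n, 2.2)], ["p1", "p2"],
                          [60.0, 60.0], list(design.sigma.index))
        prof = late_stage_profile(z, design)
        assert prof.beta.idxmax() == "constant"

    def test_requires_patients(self, design_small):
        _, _, design = design_small
        n = design.values.shape[0]
        z = build_zcohort([np.ones(n)] * 2, ["c1", "c2"], [60.0, 60.0],
                          list(design.sigma.index),
                          groups=pd.Series({"c1": "control", "c2": "control"}))
        with pytest.raises(DataError):
            late_stage_profile(z, design)


class TestBootstrap:
    def _sigma(self, n_regions=30, seed=11):
        """Well-conditioned random design so sampling noise, not column
        collinearity, dominates the bootstrap spread."""
        rng = np.random.default_rng(seed)
        A = rng.random((n_regions, 9))
        A[:, -1] = 1.0
        return pd.DataFrame(A, index=[f"g{i}" for i in range(n_regions)],
                            columns=list(METRIC_NAMES))

    def _cohort(self, n, sigma, seed=0, identical=False):
        rng = np.random.default_rng(seed)
        regions = list(sigma.index)
        base = sigma.to_numpy() @ np.array([0.3, 0, 0, 0, 0, 0, 0.5, 0, 0.1])
        rows, idx = [], []
        for j in range(n):
            # subject-level rate variability drives the cohort sampling error
            mult = 1.0 if identical else rng.normal(1.0, 0.3)
            off = 0.0 if identical else rng.normal(0, 0.2)
            for v, age in enumerate((60.0, 62.0, 64.0)):
                noise = 0.0 if identical else rng.normal(0, 0.05, len(regions))
                rows.append(base * mult * (0.2 + 0.3 * v) + off + noise)
                idx.append((f"s{j:03d}", age + (0 if identical else rng.normal(0, 0.1))))
        vol = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(idx, names=["subject", "age"]),
                           columns=regions).sort_index()
        return build_zcohort(vol.to_numpy(), vol.index.get_level_values(0),
                             vol.index.get_level_values(1), regions)

    def test_identical_subjects_zero_sd(self):
        sigma = self._sigma()
        z = self._cohort(6, sigma, identical=True)
        _, summary = bootstrap_profiles(
            z, sigma, B=3, seed=0,
            progression_config=ProgressionConfig(max_outer=5, n_draws=5),
        )
        assert summary["sd"].max() == pytest.approx(0.0, abs=1e-9)

    def test_single_replicate_sd_undefined(self):
        sigma = self._sigma()
        z = self._cohort(5, sigma, seed=1)
        _, summary = bootstrap_profiles(
            z, sigma, B=1, seed=0,
            progression_config=ProgressionConfig(max_outer=5, n_draws=5),
        )
        assert summary["sd"].isna().all()

    def test_sd_shrinks_with_cohort_size(self):
        sigma = self._sigma()
        cfg = ProgressionConfig(max_outer=5, n_draws=5)
        sds = {}
        for n in (10, 40):
            z = self._cohort(n, sigma, seed=2)
            _, summary = bootstrap_profiles(z, sigma, B=6, seed=3, progression_config=cfg)
            sds[n] = summary["sd"].mean()
        assert sds[10] / sds[40] > 1.0
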