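"""Cohort table parsing and the three preprocessing steps."""
import numpy as np
import pandas as pd
import pytest

from topoprofile.cohort import (
    adjust_nuisance,
    read_cohort_table,
    select_and_symmetrize,
    zscore_vs_controls,
)
from topoprofile.errors import DataError, SchemaError

from conftest import build_cohort


def _write_long_csv(path, rows, columns=("subject", "age", "region", "volume", "group")):
    pd.DataFrame(rows, columns=list(columns)).to_csv(path, index=False)


class TestReadCohortTable:
    def test_two_subjects_two_visits(self, tmp_path):
        p = tmp_path / "c.csv"
        rows = []
        for s in ("a", "b"):
            for age in (60.0, 62.0):
                for r in ("r1", "r2"):
                    rows.append((s, age, r, 100.0, "patient"))
        _write_long_csv(p, rows)
        cohort = read_cohort_table(p, schema={"covariates": {}})
        assert cohort.n_subjects == 2
        assert all(len(cohort.visit_ages(s)) == 2 for s in cohort.subjects)

    def test_unsorted_visits_are_sorted(self, tmp_path):
        p = tmp_path / "c.csv"
        rows = [("a", 65.0, "r1", 1.0, "patient"), ("a", 61.0, "r1", 2.0, "patient"),
                ("b", 60.0, "r1", 3.0, "control"), ("b", 59.0, "r1", 4.0, "control")]
        _write_long_csv(p, rows)
        cohort = read_cohort_table(p, schema={"covariates": {}})
        assert list(cohort.visit_ages("a")) == [61.0, 65.0]

    def test_single_visit_subject_accepted(self, tmp_path):
        p = tmp_path / "c.csv"
        _write_long_csv(p, [("solo", 70.0, "r1", 5.0, "patient")])
        cohort = read_cohort_table(p, schema={"covariates": {}})
        assert len(cohort.visit_ages("solo")) == 1

    def test_wide_format_matches_long(self, tmp_path):
        wide = tmp_path / "wide.csv"
        pd.DataFrame(
            {
                "subject": ["a", "a", "b"],
                "age": [60.0, 62.0, 61.0],
                "group": ["patient", "patient", "control"],
                "r1": [1.0, 2.0, 3.0],
                "r2": [4.0, 5.0, 6.0],
            }
        ).to_csv(wide, index=False)
        cohort = read_cohort_table(wide, schema={"covariates": {}, "format": "wide"})
        assert sorted(cohort.regions) == ["r1", "r2"]
        assert cohort.volumes.loc[("a", 62.0), "r2"] == 5.0

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "c.csv"
        pd.DataFrame({"subject": ["a"], "age": [60.0]}).to_csv(p, index=False)
        with pytest.raises(SchemaError):
            read_cohort_table(p, schema={"covariates": {}})

    def test_duplicate_measurement_is_data_error(self, tmp_path):
        p = tmp_path / "c.csv"
        _write_long_csv(p, [("a", 60.0, "r1", 1.0, "patient"),
                            ("a", 60.0, "r1", 2.0, "patient")])
        with pytest.raises(DataError, match="duplicate"):
            read_cohort_table(p, schema={"covariates": {}})


class TestAdjustNuisance:
    def _cohort_with_tiv(self, slope, n=12, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        subjects, ages, values, cov = [], [], [], []
        for j in range(n):
            tiv = 1400 + 40 * j
            base = rng.normal(1000, 50)    # covariate-independent signal
            subjects += [f"s{j}"] * 2
            ages += [60.0, 62.0]
            for _ in range(2):
                values.append([base + slope * tiv + rng.normal(0, noise),
                               500 + rng.normal(0, noise)])
                cov.append({"tiv": tiv, "sex": j % 2})
        groups = {f"s{j}": ("control" if j < n // 2 else "patient") for j in range(n)}
        return build_cohort(values, subjects, ages, ["r1", "r2"], groups, cov)

    def test_null_effect_leaves_volumes_unchanged(self):
        # volumes strictly independent of the covariates: adjustment is a no-op
        subjects = [f"s{j}" for j in range(8) for _ in (0, 1)]
        ages = [60.0, 62.0] * 8
        values = [[1000.0, 500.0]] * 16
        cov = [{"tiv": 1400.0 + 40 * (j // 2), "sex": float(j % 2)} for j in range(16)]
        groups = {f"s{j}": ("control" if j < 4 else "patient") for j in range(8)}
        cohort = build_cohort(values, subjects, ages, ["r1", "r2"], groups, cov)
        out = adjust_nuisance(cohort, ("tiv", "sex"))
        assert np.allclose(out.volumes.to_numpy(), cohort.volumes.to_numpy(), atol=1e-9)

    def test_injected_tiv_slope_removed_on_controls(self):
        cohort = self._cohort_with_tiv(slope=0.5)
        out = adjust_nuisance(cohort, ("tiv", "sex"))
        ctrl = out.control_mask().to_numpy()
        r = np.corrcoef(out.volumes.to_numpy()[ctrl, 0],
                        cohort.covariates["tiv"].to_numpy()[ctrl])[0, 1]
        assert abs(r) < 1e-10

    def test_covariate_set_without_age_leaves_age_effect(self):
        # age-linked trend must survive when age is excluded from the design
        rng = np.random.default_rng(5)
        subjects, ages, values, cov, groups = [], [], [], [], {}
        for j in range(12):
            s = f"s{j}"
            a0 = 55.0 + 2.0 * j
            subjects += [s] * 2
            ages += [a0, a0 + 1.0]
            values += [[10 * a0], [10 * (a0 + 1.0)]]
            cov += [{"tiv": float(rng.normal(1500, 50)), "sex": float(j % 2)}] * 2
            groups[s] = "control" if j < 8 else "patient"
        cohort = build_cohort(values, subjects, ages, ["r1"], groups, cov)
        out = adjust_nuisance(cohort, ("tiv", "sex"))
        r = np.corrcoef(out.volumes["r1"], ages)[0, 1]
        assert r > 0.95

    def test_collinear_covariates_error_names_columns(self):
        cohort = self._cohort_with_tiv(slope=0.0)
        cohort.covariates["tiv2"] = cohort.covariates["tiv"] * 2.0
        with pytest.raises(DataError, match="collinear"):
            adjust_nuisance(cohort, ("tiv", "tiv2"))


class TestSelectAndSymmetrize:
    def test_pair_mean(self, toy_atlas):
        cohort = build_cohort([[4.0, 6.0, 1.0, 2.0]], ["s"], [60.0],
                              ["hip_L", "hip_R", "mid_a", "mid_b"], {"s": "patient"})
        out = select_and_symmetrize(cohort, toy_atlas)
        assert out.volumes.loc[("s", 60.0), "hip"] == 5.0
        assert list(out.volumes.columns) == ["hip", "mid_a", "mid_b"]

    def test_identical_hemispheres_identity(self, toy_atlas):
        cohort = build_cohort([[7.0, 7.0, 1.0, 2.0]], ["s"], [60.0],
                              ["hip_L", "hip_R", "mid_a", "mid_b"], {"s": "patient"})
        out = select_and_symmetrize(cohort, toy_atlas)
        assert out.volumes.loc[("s", 60.0), "hip"] == 7.0

    def test_full_atlas_halves_region_count(self, design_full):
        _, atlas, _ = design_full
        rng = np.random.default_rng(0)
        cohort = build_cohort(rng.random((2, 82)), ["a", "b"], [60.0, 61.0],
                              list(atlas.names), {"a": "patient", "b": "patient"})
        out = select_and_symmetrize(cohort, atlas)
        assert len(out.volumes.columns) == 41

    def test_region_count_bookkeeping(self, toy_atlas):
        cohort = build_cohort([[4.0, 6.0, 1.0, 2.0]], ["s"], [60.0],
                              ["hip_L", "hip_R", "mid_a", "mid_b"], {"s": "patient"})
        out = select_and_symmetrize(cohort, toy_atlas, drop_list=["mid_b"])
        # pairs (1) + midline (2) - dropped (1)
        assert len(out.volumes.columns) == 2

    def test_unknown_drop_region_errors(self, toy_atlas):
        cohort = build_cohort([[1.0, 1.0, 1.0, 1.0]], ["s"], [60.0],
                              ["hip_L", "hip_R", "mid_a", "mid_b"], {"s": "patient"})
        with pytest.raises(DataError):
            select_and_symmetrize(cohort, toy_atlas, drop_list=["nope"])


class TestZScore:
    def _mixed_cohort(self):
        rng = np.random.default_rng(3)
        subjects, ages, values = [], [], []
        groups = {}
        for j in range(6):
            s = f"c{j}"
            subjects.append(s)
            ages.append(60.0 + j)
            values.append(rng.normal(100, 10, 2))
            groups[s] = "control"
        subjects += ["p", "p"]
        ages += [60.0, 62.0]
        values += [[80.0, 95.0], [70.0, 90.0]]
        groups["p"] = "patient"
        return build_cohort(values, subjects, ages, ["r1", "r2"], groups)

    def test_controls_standardized(self):
        z = zscore_vs_controls(self._mixed_cohort())
        ctrl = z.volumes[z.control_mask().to_numpy()]
        assert np.allclose(ctrl.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(ctrl.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_atrophy_orientation(self):
        cohort = self._mixed_cohort()
        z = zscore_vs_controls(cohort)
        stats = z.control_stats
        # a volume one control sd below the control mean must score +1
        probe = stats["mean"] - stats["sd"]
        expected = (stats["mean"] - probe) / stats["sd"]
        assert np.allclose(expected, 1.0)
        # the declining patient gets increasing z
        pz = z.volumes.loc["p"]
        assert (pz.iloc[1] > pz.iloc[0]).all()

    def test_idempotent_on_control_subset(self):
        z = zscore_vs_controls(self._mixed_cohort())
        z2 = zscore_vs_controls(z)
        ctrl = z.control_mask().to_numpy()
        assert np.allclose(z2.volumes.to_numpy()[ctrl], z.volumes.to_numpy()[ctrl],
                           atol=1e-12)

    def test_zero_control_sd_errors_with_region_name(self):
        cohort = build_cohort([[1.0], [1.0], [2.0]], ["c1", "c2", "p"],
                              [60.0, 61.0, 60.0], ["flat_region"],
                              {"c1": "control", "c2": "control", "p": "patient"})
        with pytest.raises(DataError, match="flat_region"):
            zscore_vs_controls(cohort)

    def test_too_few_controls(self):
        cohort = build_cohort([[1.0], [2.0]], ["c1", "p"], [60.0, 60.0], ["r"],
                              {"c1": "control", "p": "patient"})
        with pytest.raises(DataError):
            zscore_vs_controls(cohort)


def test_adjust_and_symmetrize_commute_on_linear_data(toy_atlas):
    """On noiseless linear data the two preprocessing steps commute."""
    rng = np.random.default_rng(7)
    subjects, ages, values, cov = [], [], [], []
    groups = {}
    for j in range(8):
        s = f"s{j}"
        tiv = 1400.0 + 30 * j
        subjects.append(s)
        ages.append(60.0 + j)
        base = rng.normal(0, 1, 4)
        values.append(1000.0 + 5 * base + 0.3 * tiv)
        cov.append({"tiv": tiv})
        groups[s] = "control" if j < 4 else "patient"
    cohort = build_cohort(values, subjects, ages,
                          ["hip_L", "hip_R", "mid_a", "mid_b"], groups, cov)
    a = select_and_symmetrize(adjust_nuisance(cohort, ("tiv",)), toy_atlas)
    b = adjust_nuisance(select_and_symmetrize(cohort, toy_atlas), ("tiv",))
    assert np.allclose(a.volumes.to_numpy(), b.volumes.to_numpy(), atol=1e-8)
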