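from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plitree.stats import (
    GROUP_NONSMOKER,
    GROUP_SMOKER,
    SubjectRecord,
    comparison_frame,
    comparison_table,
    correlation_table,
    pearson,
    pooled_t_from_summary,
    two_sample_t,
    welch_t,
)


class TestTwoSampleT:
    def test_identical_groups(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == 1.0

    def test_antisymmetry(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 1, 12)
        t_ab, p_ab = two_sample_t(a, b)
        t_ba, p_ba = two_sample_t(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_matches_closed_form_on_summary_stats(self, rng):
        # dual route: scipy-backed test vs textbook pooled formula
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.4, 1.3, 20)
        t1, p1 = two_sample_t(a, b)
        t2, p2 = pooled_t_from_summary(
            a.mean(), a.std(ddof=1), 20, b.mean(), b.std(ddof=1), 20
        )
        assert t1 == pytest.approx(t2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_reference_alpha_kappa_summary(self):
        # reference group summaries: means 5.829 vs 7.271, sds 1.474 vs
        # 2.286, n = 20 each -> t = -2.371 at three decimals
        t, p = pooled_t_from_summary(5.829, 1.474, 20, 7.271, 2.286, 20)
        assert round(t, 3) == -2.371
        assert p == pytest.approx(0.023, abs=5e-4)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            two_sample_t([1.0], [1.0, 2.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            two_sample_t([2.0, 2.0, 2.0], [2.0, 2.0])

    @given(
        st.floats(-100, 100),
        st.floats(0.1, 50),
    )
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance_of_p(self, shift, scale):
        a = np.array([0.1, 0.5, 0.9, 1.4, 2.2])
        b = np.array([0.3, 0.8, 1.5, 1.9, 2.5])
        _, p0 = two_sample_t(a, b)
        _, p1 = two_sample_t(a * scale + shift, b * scale + shift)
        assert p1 == pytest.approx(p0, rel=1e-9)

    def test_null_type_one_error_calibrated(self):
        # 2000 null replicates, n = 20 vs 20: rejection rate ~ alpha
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            a = rng.standard_normal(20)
            b = rng.standard_normal(20)
            _, p = two_sample_t(a, b)
            rejections += p < 0.05
        rate = rejections / n_rep
        assert 0.03 <= rate <= 0.07


class TestPearson:
    def test_perfect_positive(self):
        r, p = pearson([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        r, _ = pearson([1, 2, 3], [6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_hand_computed(self):
        # deviations give cov 4/3 and variances 5/3, 5/3 -> r = 4/5
        r, _ = pearson([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            pearson([1.0, 2.0], [1.0, 2.0])

    def test_p_matches_t_transform(self, rng):
        x = rng.normal(size=15)
        y = x + rng.normal(size=15)
        r, p = pearson(x, y)
        from scipy import stats as sps

        t = r * np.sqrt((15 - 2) / (1 - r**2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), 13), rel=1e-9)


def make_subjects(n_per_group=5, bands=("alpha",), metrics=("leaf_fraction",),
                  seed=0, covariates=True):
    rng = np.random.default_rng(seed)
    subjects = []
    for g, group in ((0, GROUP_SMOKER), (1, GROUP_NONSMOKER)):
        for k in range(n_per_group):
            vals = {
                (b, m): float(rng.normal(0.5 + 0.1 * g, 0.05))
                for b in bands
                for m in metrics
            }
            cov = (
                {
                    "ftnd": float(rng.integers(1, 10)),
                    "cigarettes_per_day": float(rng.integers(5, 25)),
                    "pack_years": float(rng.uniform(0.5, 10)),
                    "onset_age": float(rng.integers(14, 22)),
                }
                if covariates and group == GROUP_SMOKER
                else {}
            )
            subjects.append(
                SubjectRecord(f"{group}{k}", group, cov, vals)
            )
    return subjects


class TestComparisonTable:
    def test_grid_size_4_bands_8_metrics(self):
        bands = ["delta", "theta", "alpha", "beta"]
        metrics = [
            "pli", "degree", "eccentricity", "bc",
            "kappa", "diameter", "leaf_fraction", "tree_hierarchy",
        ]
        subjects = make_subjects(bands=bands, metrics=metrics)
        rows = comparison_table(subjects, bands, metrics)
        assert len(rows) == 32

    def test_identical_groups_give_zero_t(self):
        subjects = make_subjects()
        # force group values identical
        smokers = [s for s in subjects if s.group == GROUP_SMOKER]
        nonsmokers = [s for s in subjects if s.group == GROUP_NONSMOKER]
        for s, ns in zip(smokers, nonsmokers):
            ns.metrics = dict(s.metrics)
        rows = comparison_table(subjects, ["alpha"], ["leaf_fraction"])
        assert rows[0].t == pytest.approx(0.0)
        assert rows[0].p == pytest.approx(1.0)

    def test_scale_invariance(self):
        subjects = make_subjects()
        rows0 = comparison_table(subjects, ["alpha"], ["leaf_fraction"])
        for s in subjects:
            s.metrics = {k: 2 * v for k, v in s.metrics.items()}
        rows1 = comparison_table(subjects, ["alpha"], ["leaf_fraction"])
        assert rows1[0].t == pytest.approx(rows0[0].t, rel=1e-9)
        assert rows1[0].p == pytest.approx(rows0[0].p, rel=1e-9)

    def test_sign_convention_smoker_minus_nonsmoker(self):
        subjects = make_subjects()  # nonsmoker mean is larger by design
        rows = comparison_table(subjects, ["alpha"], ["leaf_fraction"])
        assert rows[0].mean_a < rows[0].mean_b
        assert rows[0].t < 0

    def test_missing_group_rejected(self):
        subjects = [
            s for s in make_subjects() if s.group == GROUP_SMOKER
        ]
        with pytest.raises(ValueError, match="absent"):
            comparison_table(subjects, ["alpha"], ["leaf_fraction"])

    def test_sd_uses_n_minus_one(self):
        subjects = make_subjects()
        rows = comparison_table(subjects, ["alpha"], ["leaf_fraction"])
        a = np.array(
            [
                s.metrics[("alpha", "leaf_fraction")]
                for s in subjects
                if s.group == GROUP_SMOKER
            ]
        )
        assert rows[0].sd_a == pytest.approx(a.std(ddof=1))

    def test_frame_columns(self):
        subjects = make_subjects()
        df = comparison_frame(
            comparison_table(subjects, ["alpha"], ["leaf_fraction"])
        )
        assert list(df.columns[:8]) == [
            "band", "metric", "mean_smoker", "sd_smoker",
            "mean_nonsmoker", "sd_nonsmoker", "t", "p",
        ]

    def test_constant_metric_yields_nan_not_crash(self):
        subjects = make_subjects()
        for s in subjects:
            s.metrics[("alpha", "leaf_fraction")] = 1.0
        rows = comparison_table(subjects, ["alpha"], ["leaf_fraction"])
        assert np.isnan(rows[0].t)
        assert not rows[0].significant


class TestCorrelationTable:
    def test_grid_4_metrics_4_covariates(self):
        metrics = ["eccentricity", "diameter", "leaf_fraction", "kappa"]
        covs = ["pack_years", "ftnd", "onset_age", "cigarettes_per_day"]
        smokers = [
            s
            for s in make_subjects(metrics=metrics)
            if s.group == GROUP_SMOKER
        ]
        rows = correlation_table(smokers, "alpha", metrics, covs)
        assert len(rows) == 16
        assert all(r.n == len(smokers) for r in rows)

    def test_covariate_equal_to_metric_gives_r_one(self):
        smokers = [
            s for s in make_subjects() if s.group == GROUP_SMOKER
        ]
        for s in smokers:
            s.covariates["ftnd"] = s.metrics[("alpha", "leaf_fraction")]
        rows = correlation_table(smokers, "alpha", ["leaf_fraction"], ["ftnd"])
        assert rows[0].r == pytest.approx(1.0)

    def test_permutation_invariance(self):
        smokers = [
            s for s in make_subjects() if s.group == GROUP_SMOKER
        ]
        rows0 = correlation_table(smokers, "alpha", ["leaf_fraction"], ["ftnd"])
        rows1 = correlation_table(
            smokers[::-1], "alpha", ["leaf_fraction"], ["ftnd"]
        )
        assert rows0[0].r == pytest.approx(rows1[0].r)

    def test_missing_covariate_dropped_pairwise(self):
        smokers = [
            s for s in make_subjects() if s.group == GROUP_SMOKER
        ]
        del smokers[0].covariates["ftnd"]
        rows = correlation_table(smokers, "alpha", ["leaf_fraction"], ["ftnd"])
        assert rows[0].n == len(smokers) - 1

    def test_all_missing_covariate_rejected(self):
        smokers = [
            s for s in make_subjects() if s.group == GROUP_SMOKER
        ]
        for s in smokers:
            s.covariates.pop("ftnd", None)
        with pytest.raises(ValueError, match="ftnd"):
            correlation_table(smokers, "alpha", ["leaf_fraction"], ["ftnd"])


class TestWelchAuxiliary:
    def test_welch_equals_student_for_equal_variance_equal_n(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 1, 20)
        # equal n: Student and Welch t statistics coincide
        t_s, _ = two_sample_t(a, b)
        t_w, _ = welch_t(a, b)
        assert t_s == pytest.approx(t_w, abs=1e-12)
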