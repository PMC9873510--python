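"""Residual pooling, the two-sample t test, BH adjustment, and plotting."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from atrodev import SubjectMeta, plot_residuals, run_analysis
from atrodev import inference as inf

region_test = inf.test_region
from atrodev.errors import ConfigurationError, NoPostDataError, VariantError


def residual_frame(rows):
    """rows: (subject_id, region, phase, z). Other columns filled plausibly."""
    frame = pd.DataFrame(rows, columns=["subject_id", "region_label", "phase", "z"])
    frame["scan_id"] = [f"s{i}" for i in range(len(frame))]
    frame["age_at_scan"] = 40.0 + np.arange(len(frame)) * 0.5
    frame["group_key"] = "3T/TR2300/TI900"
    frame["predicted"] = 1000.0
    frame["raw_residual"] = frame["z"] * 10.0
    return frame


def bh_stepup_oracle(pvals, alpha):
    """Brute-force Benjamini-Hochberg: largest k with p_(k) <= k/m * alpha."""
    m = len(pvals)
    order = np.argsort(pvals)
    selected = np.zeros(m, dtype=bool)
    k_star = 0
    for k in range(1, m + 1):
        if pvals[order[k - 1]] <= k / m * alpha:
            k_star = k
    selected[order[:k_star]] = True
    return selected


class TestTestRegion:
    def test_identical_samples_give_t_zero_p_one(self):
        z = [-1.0, 0.5, 1.2, -0.7]
        result = region_test(z, z)
        assert result.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_pooled_variant_matches_hand_computation_and_scipy(self):
        pre = [-1.0, 0.0, 1.0]
        post = [-4.0, -5.0, -6.0]
        result = region_test(pre, post, variant="pooled")
        assert result.mean_pre_z == pytest.approx(0.0)
        assert result.mean_post_z == pytest.approx(-5.0)
        # pooled sd = 1, se = sqrt(2/3)
        assert result.t_statistic == pytest.approx(-5.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
        assert result.p_value < 0.01
        oracle = stats.ttest_ind(post, pre, equal_var=True)
        assert result.t_statistic == pytest.approx(oracle.statistic, rel=1e-12)
        assert result.p_value == pytest.approx(oracle.pvalue, rel=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(
        pre=st.lists(st.floats(-5, 5), min_size=2, max_size=30),
        post=st.lists(st.floats(-5, 5), min_size=2, max_size=10),
    )
    def test_welch_matches_scipy_reference(self, pre, post):
        if np.var(pre) == 0 and np.var(post) == 0:
            return
        result = region_test(pre, post, variant="welch")
        oracle = stats.ttest_ind(post, pre, equal_var=False)
        assert result.t_statistic == pytest.approx(oracle.statistic, rel=1e-9, abs=1e-12)
        assert result.p_value == pytest.approx(oracle.pvalue, rel=1e-9, abs=1e-12)
        assert 0.0 <= result.p_value <= 1.0

    def test_location_shift_leaves_t_and_p_unchanged(self):
        pre = [-1.0, 0.2, 0.8, -0.3]
        post = [-2.0, -1.5]
        base = region_test(pre, post)
        shifted = region_test([z + 3.7 for z in pre], [z + 3.7 for z in post])
        assert shifted.t_statistic == pytest.approx(base.t_statistic, rel=1e-12)
        assert shifted.p_value == pytest.approx(base.p_value, rel=1e-12)

    def test_single_post_needs_pooled_variant(self):
        pre = [-1.0, 0.0, 1.0]
        with pytest.raises(VariantError, match="pooled"):
            region_test(pre, [-2.0], variant="welch")
        result = region_test(pre, [-2.0], variant="pooled")
        assert np.isfinite(result.p_value)
        assert result.n_post == 1

    def test_no_post_data_is_an_error(self):
        with pytest.raises(NoPostDataError):
            region_test([-1.0, 1.0], [])

    def test_zero_variance_equal_means_defines_p_one(self):
        result = region_test([0.0, 0.0, 0.0], [0.0, 0.0])
        assert result.p_value == 1.0
        assert result.t_statistic == 0.0

    def test_p_invariant_under_permutation(self):
        rng = np.random.default_rng(1)
        pre = rng.normal(size=12)
        post = rng.normal(size=5)
        base = region_test(pre, post)
        shuffled = region_test(rng.permutation(pre), rng.permutation(post))
        assert shuffled.p_value == pytest.approx(base.p_value, rel=1e-12)


class TestBenjaminiHochberg:
    def test_hand_worked_stepup(self):
        # step-up rule applied by hand: {0.01, 0.02, 0.04} -> {0.03, 0.03, 0.04}
        from statsmodels.stats.multitest import multipletests

        _, adjusted, _, _ = multipletests([0.01, 0.02, 0.04], method="fdr_bh")
        np.testing.assert_allclose(adjusted, [0.03, 0.03, 0.04], rtol=1e-12)

    @settings(max_examples=80, deadline=None)
    @given(
        pvals=st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=20),
        alpha=st.sampled_from([0.01, 0.05, 0.1, 0.2]),
    )
    def test_adjusted_p_selection_matches_bruteforce_oracle(self, pvals, alpha):
        from statsmodels.stats.multitest import multipletests

        pvals = np.asarray(pvals)
        _, adjusted, _, _ = multipletests(pvals, method="fdr_bh")
        assert np.all(adjusted >= pvals - 1e-15)
        np.testing.assert_array_equal(adjusted <= alpha, bh_stepup_oracle(pvals, alpha))


class TestRunAnalysis:
    @staticmethod
    def _two_region_residuals(post_shift=0.0, subjects=("A", "B", "C")):
        rng = np.random.default_rng(7)
        rows = []
        for region in ("parahippocampal", "global_gm"):
            for subject in subjects:
                for _ in range(4):
                    rows.append((subject, region, "pre", float(rng.normal())))
                rows.append((subject, region, "post", float(rng.normal() + post_shift)))
        return residual_frame(rows)

    def test_adjust_none_leaves_adjusted_p_absent(self):
        analysis = run_analysis(self._two_region_residuals(), adjust="none")
        assert all(r.adjusted_p is None for r in analysis.results)
        assert "adjusted_p" not in analysis.to_frame().columns

    def test_global_excluded_from_bh_family(self):
        analysis = run_analysis(self._two_region_residuals(), adjust="bh")
        assert analysis["global_gm"].adjusted_p is None
        para = analysis["parahippocampal"]
        # single-region family: adjusted equals raw
        assert para.adjusted_p == pytest.approx(para.p_value)

    def test_subgroup_with_effect_only_in_treated_attenuates_untreated_t(self):
        rng = np.random.default_rng(3)
        rows = []
        treated_ids = {"T1", "T2", "T3"}
        untreated_ids = {"U1", "U2", "U3"}
        for subject in sorted(treated_ids | untreated_ids):
            shift = -3.0 if subject in treated_ids else 0.0
            for _ in range(5):
                rows.append((subject, "parahippocampal", "pre", float(rng.normal())))
            for _ in range(2):
                rows.append((subject, "parahippocampal", "post", float(rng.normal() + shift)))
        residuals = residual_frame(rows)
        subjects = [
            SubjectMeta(s, 45.0, vaccinated=False, treated=s in treated_ids, stable_disease=True)
            for s in sorted(treated_ids | untreated_ids)
        ]
        t_all = abs(run_analysis(residuals, subjects=subjects, subgroup="all")["parahippocampal"].t_statistic)
        t_untreated = abs(
            run_analysis(residuals, subjects=subjects, subgroup="untreated_unvaccinated")[
                "parahippocampal"
            ].t_statistic
        )
        assert t_untreated < t_all

    def test_region_without_post_flagged_not_dropped(self):
        rows = [("A", "r1", "pre", 0.1), ("A", "r1", "pre", -0.1), ("A", "r1", "post", 0.5)]
        rows += [("A", "r2", "pre", 0.2), ("A", "r2", "pre", -0.2)]
        analysis = run_analysis(residual_frame(rows), regions=["r1", "r2"])
        r2 = analysis["r2"]
        assert r2.no_data
        assert r2.n_post == 0
        assert np.isnan(r2.p_value)

    def test_per_subject_mean_pooling_reduces_post_count(self):
        residuals = self._two_region_residuals()
        all_scans = run_analysis(residuals, pooling="all_scans")["parahippocampal"]
        per_subject = run_analysis(residuals, pooling="per_subject_mean")["parahippocampal"]
        assert per_subject.n_post == 3  # one per subject
        assert all_scans.n_post == 3  # one post scan each here, so equal counts
        assert per_subject.n_pre == all_scans.n_pre

    def test_unknown_options_rejected(self):
        residuals = self._two_region_residuals()
        with pytest.raises(ConfigurationError):
            run_analysis(residuals, adjust="bonferroni")
        with pytest.raises(ConfigurationError):
            run_analysis(residuals, pooling="median")
        with pytest.raises(ConfigurationError):
            run_analysis(residuals, subgroup="untreated_unvaccinated")  # no subject metadata


class TestPlotResiduals:
    def test_one_figure_per_region_and_determinism(self, tmp_path):
        residuals = TestRunAnalysis._two_region_residuals()
        analysis = run_analysis(residuals)
        out1 = plot_residuals(analysis, residuals, tmp_path / "a")
        out2 = plot_residuals(analysis, residuals, tmp_path / "b")
        assert len(out1) == 2
        for p1, p2 in zip(out1, out2):
            assert p1.read_bytes() == p2.read_bytes()

    def test_empty_post_region_annotated(self, tmp_path):
        rows = [("A", "r2", "pre", 0.2), ("A", "r2", "pre", -0.2)]
        residuals = residual_frame(rows)
        analysis = run_analysis(residuals, regions=["r2"])
        (path,) = plot_residuals(analysis, residuals, tmp_path)
        assert "no post-event scans" in path.read_text()
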