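"""Baseline fitting, standardization, and region aggregation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atrodev import MatchKey, RegionSeries, aggregate_regions, fit_baseline, standardize
from atrodev.baseline import GLOBAL_REGION_LABEL
from atrodev.errors import (
    ConfigurationError,
    DegenerateDesignError,
    DegenerateStandardizationError,
    EligibilityViolationError,
)
from conftest import cohort_rows, make_cohort

KEY = MatchKey(3.0, 2300.0, 900.0)

#: 34 cortical parcels of the Desikan-Killiany atlas (per hemisphere).
DESIKAN_KILLIANY = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal", "inferiortemporal",
    "insula", "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal",
    "lingual", "medialorbitofrontal", "middletemporal", "paracentral",
    "parahippocampal", "parsopercularis", "parsorbitalis", "parstriangularis",
    "pericalcarine", "postcentral", "posteriorcingulate", "precentral",
    "precuneus", "rostralanteriorcingulate", "rostralmiddlefrontal",
    "superiorfrontal", "superiorparietal", "superiortemporal", "supramarginal",
    "temporalpole", "transversetemporal",
]


def series(points, region="parahippocampal", subject="P1"):
    return RegionSeries(
        subject_id=subject,
        key=KEY,
        region_label=region,
        scan_ids=tuple(f"s{i}" for i in range(len(points))),
        ages=tuple(p[0] for p in points),
        values=tuple(p[1] for p in points),
        phases=tuple(p[2] for p in points),
    )


class TestFitBaseline:
    WORKED = [(40.0, 100.0, "pre"), (41.0, 98.0, "pre"), (42.0, 99.0, "pre")]

    def test_worked_three_point_example(self):
        fit = fit_baseline(series(self.WORKED))
        assert fit.slope == pytest.approx(-0.5, rel=1e-12)
        assert fit.intercept == pytest.approx(119.5, rel=1e-12)
        assert fit.residual_sd == pytest.approx(np.sqrt(1.5), rel=1e-12)
        assert fit.dof == 1

    def test_agrees_with_polyfit_oracle_on_worked_example(self):
        ages = np.array([40.0, 41.0, 42.0])
        vols = np.array([100.0, 98.0, 99.0])
        oracle_slope, oracle_intercept = np.polyfit(ages, vols, 1)
        fit = fit_baseline(series(self.WORKED))
        assert fit.slope == pytest.approx(oracle_slope, rel=1e-9)
        assert fit.intercept == pytest.approx(oracle_intercept, rel=1e-9)

    def test_grid_search_confirms_least_squares_minimum(self):
        """Brute force: no (slope, intercept) near the fit does better on RSS."""
        ages = np.array([40.0, 41.0, 42.0])
        vols = np.array([100.0, 98.0, 99.0])
        fit = fit_baseline(series(self.WORKED))

        def rss(b1, b0):
            r = vols - (b0 + b1 * ages)
            return float(r @ r)

        best = rss(fit.slope, fit.intercept)
        for db1 in np.linspace(-0.3, 0.3, 21):
            for db0 in np.linspace(-0.3, 0.3, 21):
                assert rss(fit.slope + db1, fit.intercept + db0) >= best - 1e-12

    @settings(max_examples=60, deadline=None)
    @given(
        n=st.integers(min_value=3, max_value=6),
        data=st.data(),
    )
    def test_matches_polyfit_on_random_small_series(self, n, data):
        ages = [
            float(a)
            for a in data.draw(
                st.lists(st.integers(min_value=20, max_value=80), min_size=n, max_size=n, unique=True)
            )
        ]
        vols = data.draw(
            st.lists(
                st.floats(min_value=10.0, max_value=1e5, allow_nan=False),
                min_size=n, max_size=n,
            )
        )
        fit = fit_baseline(series([(a, v, "pre") for a, v in zip(ages, vols)]))
        oracle_slope, oracle_intercept = np.polyfit(np.asarray(ages), np.asarray(vols), 1)
        assert fit.slope == pytest.approx(oracle_slope, rel=1e-7, abs=1e-7)
        assert fit.intercept == pytest.approx(oracle_intercept, rel=1e-7, abs=1e-7)

    def test_collinear_points_give_zero_residual_sd(self):
        pts = [(a, 1000.0 - 10.0 * a, "pre") for a in (40.0, 41.0, 42.0, 43.0)]
        fit = fit_baseline(series(pts))
        assert fit.residual_sd == 0.0
        assert fit.slope == pytest.approx(-10.0, rel=1e-9)
        assert fit.intercept == pytest.approx(1000.0, rel=1e-9)

    def test_two_pre_points_violate_eligibility(self):
        with pytest.raises(EligibilityViolationError):
            fit_baseline(series([(40, 100, "pre"), (41, 99, "pre"), (42, 98, "post")]))

    def test_identical_ages_are_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            fit_baseline(series([(40, 100, "pre"), (40, 99, "pre"), (40, 98, "pre")]))


class TestStandardize:
    WORKED = [(40.0, 100.0, "pre"), (41.0, 98.0, "pre"), (42.0, 99.0, "pre"), (43.0, 95.0, "post")]

    def test_worked_post_residual(self):
        s = series(self.WORKED)
        fit = fit_baseline(s)
        table = standardize(fit, s)
        post = table[table["phase"] == "post"].iloc[0]
        assert post["predicted"] == pytest.approx(98.0, rel=1e-12)
        assert post["raw_residual"] == pytest.approx(-3.0, rel=1e-12)
        assert post["z"] == pytest.approx(-3.0 / np.sqrt(1.5), rel=1e-9)
        assert post["z"] == pytest.approx(-2.4495, abs=5e-5)

    def test_pre_raw_residuals_sum_to_zero(self):
        s = series(self.WORKED)
        table = standardize(fit_baseline(s), s)
        assert table.loc[table["phase"] == "pre", "raw_residual"].sum() == pytest.approx(0.0, abs=1e-10)

    @settings(max_examples=40, deadline=None)
    @given(
        scale=st.floats(min_value=0.1, max_value=1e4),
        age_shift=st.floats(min_value=-30, max_value=30),
        trend_slope=st.floats(min_value=-50, max_value=50),
        trend_offset=st.floats(min_value=0, max_value=1e4),
    )
    def test_invariances(self, scale, age_shift, trend_slope, trend_offset):
        """z is unchanged by volume rescaling, age shifts, and added affine trends."""
        base = self.WORKED
        s0 = series(base)
        z0 = standardize(fit_baseline(s0), s0)["z"].to_numpy()

        scaled = [(a, v * scale, p) for a, v, p in base]
        shifted = [(a + age_shift, v, p) for a, v, p in base]
        trended = [(a, v + trend_slope * a + trend_offset, p) for a, v, p in base]
        for variant in (scaled, shifted, trended):
            if any(v <= 0 for _, v, _ in variant):
                continue
            sv = series(variant)
            zv = standardize(fit_baseline(sv), sv)["z"].to_numpy()
            np.testing.assert_allclose(zv, z0, rtol=1e-7, atol=1e-7)

    def test_zero_sd_with_nonzero_residual_is_degenerate(self):
        pts = [(a, 1000.0 - 10.0 * a, "pre") for a in (40.0, 41.0, 42.0)] + [(43.0, 500.0, "post")]
        s = series(pts)
        with pytest.raises(DegenerateStandardizationError):
            standardize(fit_baseline(s), s)

    def test_zero_sd_with_zero_residuals_gives_zero_z(self):
        pts = [(a, 1000.0 - 10.0 * a, p) for a, p in ((40.0, "pre"), (41.0, "pre"), (42.0, "pre"), (43.0, "post"))]
        s = series(pts)
        table = standardize(fit_baseline(s), s)
        assert (table["z"] == 0.0).all()


class TestAggregateRegions:
    @staticmethod
    def _bilateral_cohort():
        rows = []
        for region, (lv, rv) in {"parahippocampal": (2100.0, 2000.0)}.items():
            rows += cohort_rows("P1", [(40, lv, "pre")], region=f"lh_{region}")
            rows += cohort_rows("P1", [(40, rv, "pre")], region=f"rh_{region}")
        return make_cohort(rows)

    def test_bilateral_sum(self):
        out = aggregate_regions(self._bilateral_cohort(), mode="bilateral_sum", include_global=False)
        assert list(out["region_label"]) == ["parahippocampal"]
        assert out["value"].iloc[0] == pytest.approx(4100.0)

    def test_per_hemisphere_is_identity_on_labels(self):
        cohort = self._bilateral_cohort()
        out = aggregate_regions(cohort, mode="per_hemisphere", include_global=False)
        assert sorted(out["region_label"]) == sorted(cohort["region_label"])
        np.testing.assert_allclose(
            out.sort_values("region_label")["value"].to_numpy(),
            cohort.sort_values("region_label")["value"].to_numpy(),
        )

    def test_full_atlas_yields_34_bilateral_regions(self):
        rows = []
        rng = np.random.default_rng(0)
        for region in DESIKAN_KILLIANY:
            for hemi in ("lh", "rh"):
                rows += cohort_rows(
                    "P1", [(40, float(rng.uniform(1e3, 1e4)), "pre")], region=f"{hemi}_{region}"
                )
        out = aggregate_regions(make_cohort(rows), mode="bilateral_sum", include_global=False)
        assert out["region_label"].nunique() == 34
        assert len(out) == 34  # one scan

    def test_global_from_recognized_column(self):
        rows = self._bilateral_cohort().to_dict("records") + cohort_rows(
            "P1", [(40, 500000.0, "pre")], region="CortexVol"
        )
        out = aggregate_regions(make_cohort(rows), include_global=True)
        glob = out[out["region_label"] == GLOBAL_REGION_LABEL]
        assert glob["value"].iloc[0] == pytest.approx(500000.0)

    def test_global_as_parcel_sum_when_no_summary_column(self):
        out = aggregate_regions(self._bilateral_cohort(), include_global=True)
        glob = out[out["region_label"] == GLOBAL_REGION_LABEL]
        assert glob["value"].iloc[0] == pytest.approx(4100.0)

    def test_requested_missing_region_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="hippocampus"):
            aggregate_regions(self._bilateral_cohort(), regions=["hippocampus"], include_global=False)
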