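"""Quality control: modified z-scores, geometry screen, volume outlier flags."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flairwmh.phantom import SubjectRecord
from flairwmh.qc import (
    fit_age_volume,
    flag_age_outliers,
    flag_site_volume_outliers,
    modified_zscore,
    qc_summary,
    screen_geometry,
)


def _rec(i, age=60.0, site=0, inplane=0.7, through=6.3, slices=28, brain=1400.0):
    return SubjectRecord(
        subject_id=f"s{i:03d}",
        age=age,
        sex="F",
        site=site,
        inplane_mm=inplane,
        throughplane_mm=through,
        slices=slices,
        true_brain_cc=brain,
    )


class TestModifiedZ:
    def test_constant_values_all_zero(self):
        assert np.allclose(modified_zscore([1, 1, 1, 1]), 0.0)

    def test_hand_computed_outlier(self):
        z = modified_zscore([1, 2, 3, 4, 100])
        # median 3, MAD 1: score of 100 is 0.6745 * 97
        assert z[-1] == pytest.approx(0.6745 * 97)
        assert abs(z[-1]) > 3.5

    def test_antisymmetric_for_symmetric_data(self):
        z = modified_zscore([-3, -1, 0, 1, 3])
        assert np.allclose(z, -z[::-1])

    def test_mad_zero_sentinel(self):
        z = modified_zscore([5, 5, 5, 9])
        assert z[0] == 0.0 and np.isinf(z[-1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            modified_zscore([])

    @given(st.lists(st.floats(-1e5, 1e5), min_size=2, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_bruteforce_oracle(self, values):
        import statistics

        z = modified_zscore(values)
        med = statistics.median(values)
        mad = statistics.median([abs(v - med) for v in values])
        for v, zi in zip(values, z):
            if mad == 0:
                assert zi == 0.0 if v == med else np.isinf(zi)
            else:
                assert zi == pytest.approx(0.6745 * (v - med) / mad, rel=1e-12, abs=1e-12)


class TestGeometryScreen:
    def test_extreme_slice_spacing_flagged(self):
        records = [_rec(i) for i in range(30)] + [_rec(99, through=65.0)]
        flags = screen_geometry(records)
        assert {f.subject_id for f in flags} == {"s099"}
        assert flags[0].reason == "resolution_throughplane"

    def test_low_slice_boundary(self):
        records = [_rec(i) for i in range(10)]
        records += [_rec(50, slices=3), _rec(51, slices=4)]
        flagged = {f.subject_id for f in screen_geometry(records) if f.reason == "low_slices"}
        assert flagged == {"s050"}

    def test_identical_cohort_no_flags(self):
        assert screen_geometry([_rec(i) for i in range(8)]) == []


class TestAgeVolumeModel:
    def test_noiseless_exact_fit(self):
        ages = np.linspace(30, 90, 40)
        vols = -2.4 * ages + 1630.8
        m = fit_age_volume(ages, vols)
        assert m.m == pytest.approx(-2.4)
        assert m.b == pytest.approx(1630.8)
        assert m.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_two_points_interpolated(self):
        m = fit_age_volume([40.0, 60.0, 80.0], [1500.0, 1450.0, 1400.0])
        assert m.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_constant_ages_rejected(self):
        with pytest.raises(ValueError, match="singular|constant"):
            fit_age_volume([50, 50, 50], [1, 2, 3])

    def test_residual_sd_recovered_at_cohort_scale(self):
        rng = np.random.default_rng(17)
        ages = rng.uniform(30, 90, 2684)
        vols = -2.4 * ages + 1630.8 + rng.normal(0, 167.5, 2684)
        m = fit_age_volume(ages, vols)
        assert 160 <= m.residual_sd <= 175

    def test_two_sd_boundary_contract(self):
        model = fit_age_volume([30, 60, 90], [1558.8, 1486.8, 1414.8])  # exact line
        model.residual_sd = 100.0
        on_line = _rec(0, age=50.0, brain=float(model.predict(50.0)))
        just_out = _rec(1, age=50.0, brain=float(model.predict(50.0) + 201.0))
        just_in = _rec(2, age=50.0, brain=float(model.predict(50.0) + 199.0))
        flagged = {f.subject_id for f in flag_age_outliers(model, [on_line, just_out, just_in])}
        assert flagged == {"s001"}

    def test_gaussian_flag_rate_near_two_sided_two_sigma(self):
        rng = np.random.default_rng(23)
        n = 10_000
        ages = rng.uniform(30, 90, n)
        vols = -2.4 * ages + 1630.8 + rng.normal(0, 167.5, n)
        model = fit_age_volume(ages, vols)
        recs = [_rec(i, age=a, brain=v) for i, (a, v) in enumerate(zip(ages, vols))]
        rate = len(flag_age_outliers(model, recs)) / n
        assert 0.035 <= rate <= 0.055  # 2*Phi(-2) ~ 4.55%


class TestSiteOutliers:
    def test_injected_triple_volume_flagged(self):
        rng = np.random.default_rng(2)
        recs = [_rec(i, site=0, brain=float(rng.normal(1400, 50))) for i in range(30)]
        recs.append(_rec(99, site=0, brain=4200.0))
        flagged = {f.subject_id for f in flag_site_volume_outliers(recs)}
        assert flagged == {"s099"}

    def test_identical_volumes_no_flags(self):
        recs = [_rec(i, site=1, brain=1400.0) for i in range(6)]
        assert flag_site_volume_outliers(recs) == []

    def test_single_subject_site_skipped_with_warning(self):
        recs = [_rec(0, site=0), _rec(1, site=0), _rec(2, site=7)]
        with pytest.warns(UserWarning, match="single subject"):
            flag_site_volume_outliers(recs)

    def test_site_outliers_also_caught_by_age_rule(self):
        """In matched synthetic cohorts, a site-level deviant also exceeds the
        cohort-wide 2-SD age band (echoing the observed containment)."""
        rng = np.random.default_rng(31)
        recs = []
        for i in range(200):
            age = float(rng.uniform(30, 90))
            vol = -2.4 * age + 1630.8 + float(rng.normal(0, 60))
            recs.append(_rec(i, age=age, site=i % 4, brain=vol))
        recs.append(_rec(999, age=60.0, site=0, brain=2600.0))
        site_flagged = {f.subject_id for f in flag_site_volume_outliers(recs)}
        model = fit_age_volume([r.age for r in recs], [r.true_brain_cc for r in recs])
        age_flagged = {f.subject_id for f in flag_age_outliers(model, recs)}
        assert "s999" in site_flagged and site_flagged <= age_flagged


class TestFlagMonotonicityAndAccounting:
    def test_enlarging_deviation_never_unflags(self):
        model = fit_age_volume([30, 60, 90], [1558.8, 1486.8, 1414.8])
        model.residual_sd = 50.0
        for dev in (150.0, 300.0, 3000.0):
            r = _rec(0, age=60.0, brain=float(model.predict(60.0) + dev))
            assert len(flag_age_outliers(model, [r])) == 1

    def test_summary_partitions_cohort(self):
        recs = [_rec(i) for i in range(10)]
        flags = screen_geometry(recs + [_rec(77, slices=2)])
        flags[0].disposition = "excluded"
        s = qc_summary(recs + [_rec(77, slices=2)], flags)
        assert s.n_total == 11
        assert s.n_excluded + s.n_kept_after_review + s.n_pending == s.n_flagged
        assert s.counts_by_reason["low_slices"] == 1
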