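"""Agreement statistics: Dice, ICC, log-log fit, OER/DER, age regression."""

import numpy as np
import pytest

from flairwmh.core import BinaryMask
from flairwmh.metrics import (
    agreement_report,
    dice,
    icc,
    loglog_fit,
    oer_der,
    remove_volume_outliers,
    wmhv_age_regression,
)


def _mask(arr):
    arr = np.asarray(arr, dtype=bool)
    return BinaryMask(arr, (1, 1, 1))


class TestDice:
    def test_identical_nonempty(self, rng):
        a = rng.random((6, 6, 6)) > 0.5
        assert dice(_mask(a), _mask(a)) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros((4, 4, 4), dtype=bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert dice(_mask(a), _mask(b)) == 0.0

    def test_hand_example(self):
        a = np.zeros((4, 4, 1), dtype=bool)
        b = np.zeros((4, 4, 1), dtype=bool)
        a[0, :4, 0] = True  # |a| = 4
        b[0, 2:4, 0] = True
        b[1, :2, 0] = True  # |b| = 4, overlap 2
        assert dice(_mask(a), _mask(b)) == pytest.approx(0.5)

    def test_both_empty_defined_as_one(self):
        z = np.zeros((3, 3, 3), dtype=bool)
        assert dice(_mask(z), _mask(z)) == 1.0

    def test_symmetry_and_grid_check(self, rng):
        a = rng.random((5, 5, 5)) > 0.6
        b = rng.random((5, 5, 5)) > 0.6
        assert dice(_mask(a), _mask(b)) == dice(_mask(b), _mask(a))
        with pytest.raises(ValueError):
            dice(_mask(a), _mask(np.zeros((4, 4, 4), dtype=bool)))


def _icc_bruteforce(x, y):
    """Independent ANOVA decomposition for two-way absolute-agreement ICC."""
    data = np.stack([x, y], 1)
    n, k = data.shape
    grand = data.mean()
    msr = k * sum((data[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((data[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (data[i, j] - data[i].mean() - data[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_columns(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert icc(x, x) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        y = x + rng.normal(0, 20, 200)
        assert abs(icc(x, y)) < 0.2

    def test_hand_worked_four_pairs_vs_anova_oracle(self):
        x = np.array([9.0, 6.0, 8.0, 7.0])
        y = np.array([2.0, 1.0, 4.0, 1.0])
        assert icc(x, y) == pytest.approx(_icc_bruteforce(x, y), abs=1e-10)

    def test_matches_pingouin_reference(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(4)
        x = rng.normal(10, 3, 30)
        y = x + rng.normal(0, 1, 30)
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(30), 2),
                "raters": np.tile(["m", "a"], 30),
                "ratings": np.column_stack([x, y]).ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="ratings")
        icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc(x, y) == pytest.approx(icc2, abs=1e-8)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            icc([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])


class TestLogLogFit:
    def test_identity(self):
        v = np.array([0.5, 2.0, 10.0, 40.0])
        slope, mse = loglog_fit(v, v)
        assert slope == pytest.approx(1.0) and mse == pytest.approx(0.0)

    def test_square_relation_gives_slope_two(self):
        v = np.array([1.5, 3.0, 8.0, 20.0])
        slope, mse = loglog_fit(v, v**2)
        assert slope == pytest.approx(2.0) and mse == pytest.approx(0.0, abs=1e-20)

    def test_power_09_on_ln_scale(self):
        v = np.array([0.7, 2.0, 9.0, 30.0])
        slope, _ = loglog_fit(v, v**0.9)
        assert slope == pytest.approx(0.9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            loglog_fit([1.0, -2.0], [1.0, 2.0])


class TestOerDer:
    def test_identical_masks_zero_errors(self, rng):
        a = rng.random((8, 8, 4)) > 0.7
        assert oer_der(_mask(a), _mask(a)) == (0.0, 0.0)

    def test_hand_enumerated_components(self):
        # manual: lesion A (10 vox) + lesion B (6 vox); automatic: A minus
        # 2 voxels, B missed entirely -> OE 2, DE 6, mean volume 12
        manual = np.zeros((20, 5, 1), dtype=bool)
        auto = np.zeros((20, 5, 1), dtype=bool)
        manual[0:2, 0:5, 0] = True  # A: 10 voxels
        auto[0:2, 0:5, 0] = True
        auto[0, 0, 0] = auto[1, 4, 0] = False  # 2 voxels off
        manual[10:12, 0:3, 0] = True  # B: 6 voxels, far away
        oer, der = oer_der(_mask(manual), _mask(auto))
        assert oer == pytest.approx(2 / 12)
        assert der == pytest.approx(6 / 12)

    def test_spurious_automatic_lesion_counts_to_de(self):
        manual = np.zeros((10, 10, 1), dtype=bool)
        auto = np.zeros((10, 10, 1), dtype=bool)
        auto[5:7, 5:7, 0] = True  # 4 false voxels
        oer, der = oer_der(_mask(manual), _mask(auto))
        assert oer == 0.0
        assert der == pytest.approx(4 / 2.0)  # mean volume (0+4)/2

    def test_both_empty(self):
        z = np.zeros((4, 4, 1), dtype=bool)
        assert oer_der(_mask(z), _mask(z)) == (0.0, 0.0)

    def test_symmetry(self, rng):
        a = rng.random((10, 10, 3)) > 0.8
        b = rng.random((10, 10, 3)) > 0.8
        assert oer_der(_mask(a), _mask(b)) == oer_der(_mask(b), _mask(a))


class TestAgeRegression:
    def test_noiseless_slope_recovered_with_zero_fold_sd(self):
        ages = np.linspace(30, 90, 120)
        wmhv = np.exp(0.051 * ages - 1.5)
        est = wmhv_age_regression(ages, wmhv, seed=0)
        assert est.slope == pytest.approx(0.051)
        assert est.fold_sd == pytest.approx(0.0, abs=1e-12)

    def test_shuffled_ages_give_null_slope(self):
        rng = np.random.default_rng(9)
        ages = rng.uniform(30, 90, 300)
        wmhv = np.exp(0.051 * ages - 1.5 + rng.normal(0, 0.5, 300))
        shuffled = rng.permutation(ages)
        est = wmhv_age_regression(shuffled, wmhv, seed=1)
        assert abs(est.slope) < 2 * max(est.fold_sd, 1e-3)

    def test_duplicated_dataset_same_slope(self):
        rng = np.random.default_rng(3)
        ages = rng.uniform(30, 90, 60)
        wmhv = np.exp(0.05 * ages - 1.0 + rng.normal(0, 0.3, 60))
        a = wmhv_age_regression(ages, wmhv, seed=0)
        b = wmhv_age_regression(np.tile(ages, 2), np.tile(wmhv, 2), seed=0)
        assert b.slope == pytest.approx(a.slope, rel=1e-9)

    def test_fold_sd_shrinks_with_noise(self):
        ages = np.linspace(30, 90, 400)
        sds = []
        for noise in (1.0, 0.1, 0.0):
            rng = np.random.default_rng(5)
            wmhv = np.exp(0.051 * ages - 1.5 + rng.normal(0, noise, 400))
            sds.append(wmhv_age_regression(ages, wmhv, seed=2).fold_sd)
        assert sds[0] > sds[1] > sds[2] - 1e-15
        assert sds[2] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            wmhv_age_regression([40, 50, 60], [1, 2, 3], folds=10)


class TestOutlierRemoval:
    def test_identical_lists_all_kept(self):
        v = np.array([1.0, 2.0, 3.0])
        assert list(remove_volume_outliers(v, v)) == [0, 1, 2]

    def test_single_gross_disagreement_removed(self):
        rng = np.random.default_rng(7)
        manual = rng.uniform(1, 20, 50)
        auto = manual + rng.normal(0, 0.1, 50)
        manual = np.append(manual, 10.0)
        auto = np.append(auto, 100.0)
        kept = remove_volume_outliers(manual, auto)
        assert 50 not in kept and len(kept) == 50

    def test_kept_and_removed_partition(self, rng):
        manual = rng.uniform(1, 10, 30)
        auto = manual * rng.uniform(0.5, 2.0, 30)
        kept = set(remove_volume_outliers(manual, auto))
        assert kept <= set(range(30))


def test_agreement_report_perfect_match(rng):
    v = rng.uniform(0.5, 30, 25)
    rep = agreement_report(v, v)
    assert rep.pearson_r == pytest.approx(1.0)
    assert rep.icc == pytest.approx(1.0)
    assert rep.slope == pytest.approx(1.0)
    assert rep.mse == pytest.approx(0.0, abs=1e-20)
    assert rep.n_outliers_removed == 0
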