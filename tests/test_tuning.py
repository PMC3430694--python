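"""Leave-one-run-out voxel tuning: classification, reliability, curves."""

import numpy as np
import pytest

from voxeltune.design import CONDITIONS
from voxeltune.glm import BetaArray, znormalize
from voxeltune.simulate import make_voxel_population, simulate_betas
from voxeltune.tuning import (
    VoxelTuning,
    classify_preference,
    loocv_tuning,
    null_reliability_enumeration,
    null_reliability_mc,
    reliability_filter,
    summarize_tuning,
    tuning_success,
)


class TestClassifyPreference:
    def test_argmax_of_mean(self):
        b = np.tile(np.array([0.2, 0.1, 0.9, 0.0]), (5, 1))
        pref, excluded = classify_preference(b)
        assert pref == CONDITIONS.index("EG") and not excluded

    def test_exact_tie_is_untuned(self):
        pref, _ = classify_preference(np.ones((5, 4)))
        assert pref == -1

    def test_nan_flags_exclusion(self):
        b = np.ones((5, 4))
        b[2, 1] = np.nan
        pref, excluded = classify_preference(b)
        assert excluded and pref == -1


class TestReliabilityFilter:
    @pytest.mark.parametrize(
        "pref,per_run,expected",
        [
            ("EG", ["EG", "EG", "EG", "CC", "CG"], True),
            ("EG", ["EG", "EG", "CC", "CC", "CG"], False),
            ("EG", ["EG", "EG", "EG", "EG", "EG"], True),
        ],
    )
    def test_majority_rule(self, pref, per_run, expected):
        assert reliability_filter(pref, per_run) is expected

    def test_threshold_is_ceil_half(self):
        # 3 of 5 needed; 2 of 4 would suffice with k=4
        assert reliability_filter(0, [0, 0, 1, 2]) is True
        assert reliability_filter(0, [0, 1, 1, 2]) is False


def _tuned_betas(n_voxels, gain, noise_sd, rng, untuned_frac=0.0):
    props = {c: (1 - untuned_frac) / 4 for c in CONDITIONS}
    props["untuned"] = untuned_frac
    pop = make_voxel_population(n_voxels, props, tuning_gain=gain,
                                noise_sd=noise_sd, rng=rng)
    betas = BetaArray(values=simulate_betas(pop, rng=rng))
    return pop, betas


class TestLoocv:
    def test_noiseless_recovery_all_folds(self):
        pop, betas = _tuned_betas(200, gain=1.0, noise_sd=0.0, rng=0)
        folds = loocv_tuning(znormalize(betas))
        assert len(folds) == 6
        for fold in folds:
            assert np.array_equal(fold.preference, pop.designated_preference)
            assert fold.reliable.all()

    def test_condition_label_permutation_equivariance(self, rng):
        v = rng.standard_normal((6, 4, 50))
        perm = np.array([2, 0, 3, 1])
        f1 = loocv_tuning(znormalize(BetaArray(values=v)))
        f2 = loocv_tuning(znormalize(BetaArray(values=v[:, perm, :])))
        for a, b in zip(f1, f2):
            # condition c in the permuted data is perm[c] in the original
            mapped = np.where(b.preference >= 0, perm[b.preference], -1)
            assert np.array_equal(mapped, a.preference)
            assert np.array_equal(a.reliable, b.reliable)

    def test_curves_come_only_from_held_out_run(self, rng):
        v = rng.standard_normal((6, 4, 30))
        folds = loocv_tuning(BetaArray(values=v))
        v2 = v.copy()
        v2[np.arange(6) != 2] += rng.standard_normal((5, 4, 30)) * 10
        folds2 = loocv_tuning(BetaArray(values=v2))
        assert np.array_equal(folds[2].tuning_curves, folds2[2].tuning_curves)

    def test_nan_voxels_excluded_everywhere(self, rng):
        v = rng.standard_normal((6, 4, 10))
        v[3, 1, 4] = np.nan
        folds = loocv_tuning(BetaArray(values=v))
        for fold in folds:
            assert fold.excluded[4] and not fold.reliable[4]
            assert fold.preference[4] == -1

    def test_too_few_runs(self):
        with pytest.raises(ValueError):
            loocv_tuning(np.zeros((1, 4, 3)))

    def test_null_preferences_uniform(self):
        rng = np.random.default_rng(77)
        betas = BetaArray(values=rng.standard_normal((6, 4, 1000)))
        folds = loocv_tuning(znormalize(betas))
        prefs = folds[0].preference
        counts = np.bincount(prefs[prefs >= 0], minlength=4)
        # multinomial(1000, 1/4): 99% CI half-width ~ 2.58*sqrt(.25*.75*1000)
        assert np.abs(counts - 250).max() < 2.58 * np.sqrt(0.25 * 0.75 * 1000)

    def test_snr_monotonicity(self):
        """Preference-recovery accuracy is non-decreasing in gain/noise ratio
        (common random numbers across the SNR grid)."""
        accs = []
        for gain in [0.0625, 0.125, 0.25, 0.5, 1.0]:
            pop, betas = _tuned_betas(200, gain=gain, noise_sd=1.0, rng=31)
            folds = loocv_tuning(znormalize(betas))
            correct = np.mean(
                [f.preference == pop.designated_preference for f in folds]
            )
            accs.append(correct)
        assert all(b >= a for a, b in zip(accs, accs[1:]))
        assert accs[0] < accs[-1]


class TestSummaries:
    def test_conservation_per_fold(self, rng):
        betas = BetaArray(values=rng.standard_normal((6, 4, 137)))
        folds = loocv_tuning(znormalize(betas))
        for fold in folds:
            tuned = fold.tuned_counts().sum()
            untuned = np.sum(~fold.reliable & ~fold.excluded)
            assert tuned + untuned + fold.excluded.sum() == 137

    def test_single_fold_counts(self):
        pop, betas = _tuned_betas(40, gain=1.0, noise_sd=0.0, rng=1)
        folds = loocv_tuning(znormalize(betas))
        summary = summarize_tuning([folds[0]])
        assert np.array_equal(summary.tuned_counts, [10, 10, 10, 10])

    def test_identical_folds_mean_is_either(self):
        pop, betas = _tuned_betas(40, gain=1.0, noise_sd=0.0, rng=2)
        folds = loocv_tuning(znormalize(betas))
        two = summarize_tuning([folds[0], folds[0]])
        one = summarize_tuning([folds[0]])
        assert np.allclose(two.tuned_counts, one.tuned_counts)
        assert np.allclose(two.mean_curves, one.mean_curves, equal_nan=True)

    def test_sum_aggregation(self):
        pop, betas = _tuned_betas(40, gain=1.0, noise_sd=0.0, rng=3)
        folds = loocv_tuning(znormalize(betas))
        s = summarize_tuning(folds, aggregation="sum")
        m = summarize_tuning(folds, aggregation="mean")
        assert np.allclose(s.tuned_counts, 6 * m.tuned_counts)

    def test_model_results_objects(self):
        pop, betas = _tuned_betas(60, gain=1.0, noise_sd=0.3, rng=4)
        results = VoxelTuning(betas).fit()
        df = results.summary_frame()
        assert list(df.condition) == list(CONDITIONS)
        curves = results.curves_frame()
        assert len(curves) == 16


class TestNullOracles:
    def test_enumeration_value(self):
        # 4 * (C(5,3)*9 + C(5,4)*3 + 1) / 4^5
        assert null_reliability_enumeration(5, 4) == 424 / 1024

    def test_enumeration_upper_bounds_mc(self):
        mc = null_reliability_mc(n_samples=200_000, rng=0)
        assert mc < null_reliability_enumeration(5, 4)
        assert 0.30 < mc < 0.38

    def test_pipeline_matches_mc_oracle(self):
        """Empirical tuned fraction under the null matches the independent
        Monte-Carlo oracle of the argmax-recurrence process."""
        p_rel = null_reliability_mc(n_samples=400_000, rng=1)
        rng = np.random.default_rng(5)
        rates = []
        for _ in range(10):
            betas = BetaArray(values=rng.standard_normal((6, 4, 1000)))
            folds = loocv_tuning(znormalize(betas))
            rates.append(np.mean([f.reliable.mean() for f in folds]))
        se = np.std(rates, ddof=1) / np.sqrt(len(rates))
        assert abs(np.mean(rates) - p_rel) < 3.3 * se + 0.002


class TestTuningSuccess:
    def _summaries(self, n_subjects, gain, noise_sd, seed):
        out = []
        for s in range(n_subjects):
            pop, betas = _tuned_betas(
                60, gain=gain, noise_sd=noise_sd, rng=seed * 1000 + s,
                untuned_frac=0.2,
            )
            out.append(VoxelTuning(betas).fit().summary)
        return out

    def test_identical_curves_give_zero_t(self):
        pop, betas = _tuned_betas(40, gain=1.0, noise_sd=0.0, rng=6)
        summary = VoxelTuning(betas).fit().summary
        flat = summary
        # construct two subjects with identical mean curves but flatten the
        # target/other contrast by zeroing the curves
        flat.mean_curves[:] = 0.0
        res = tuning_success([flat, flat, flat], "CG")
        assert res.t == 0.0 and res.p == 1.0

    def test_true_tuning_detected(self):
        summaries = self._summaries(12, gain=1.0, noise_sd=0.5, seed=1)
        res = tuning_success(summaries, "EG")
        assert res.t > 3.0 and res.p < 0.01 and res.df == 11

    def test_missing_subjects_reduce_df(self):
        good = self._summaries(4, gain=1.0, noise_sd=0.5, seed=2)
        bad = self._summaries(1, gain=1.0, noise_sd=0.5, seed=3)[0]
        bad.mean_curves[CONDITIONS.index("CG"), :] = np.nan
        with pytest.warns(UserWarning, match="lack voxels"):
            res = tuning_success(good + [bad], "CG")
        assert res.df == 3

    def test_needs_two_subjects(self):
        summaries = self._summaries(1, gain=1.0, noise_sd=0.5, seed=4)
        with pytest.raises(ValueError):
            tuning_success(summaries, "CG")
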