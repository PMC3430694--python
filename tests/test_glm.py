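"""HRF, run assignment, design construction, OLS and normalisation."""

import numpy as np
import pandas as pd
import pytest

from voxeltune.design import CONDITIONS, DesignParams, Schedule, generate_schedule
from voxeltune.glm import (
    BetaArray,
    RankDeficientDesignError,
    RunAssignment,
    RunwiseGLM,
    assign_trials_to_runs,
    build_run_design,
    cosine_drift,
    extract_beta_array,
    fit_glm,
    znormalize,
)
from voxeltune.hrf import canonical_hrf
from voxeltune.simulate import (
    make_voxel_population,
    n_volumes_for,
    simulate_bold,
    simulate_trial_amplitudes,
)


class TestHrf:
    def test_starts_at_zero_with_unit_peak(self):
        h = canonical_hrf(0.1)
        assert h[0] == 0.0
        assert np.isclose(h.max(), 1.0)

    def test_peak_location(self):
        dt = 0.05
        h = canonical_hrf(dt)
        assert 5.0 <= h.argmax() * dt <= 6.0

    def test_refinement_consistency(self):
        coarse = canonical_hrf(0.5)
        fine = canonical_hrf(0.25)
        assert np.allclose(coarse, fine[::2], atol=1e-6)

    def test_undershoot_present(self):
        h = canonical_hrf(0.5)
        assert h.min() < -0.01

    def test_matches_reference_spm_kernel(self):
        nilearn = pytest.importorskip("nilearn.glm.first_level.hemodynamic_models")
        ours = canonical_hrf(0.1)
        ref = nilearn.spm_hrf(1.0, oversampling=10, time_length=32.1)
        n = min(len(ours), len(ref))
        r = np.corrcoef(ours[:n], ref[:n])[0, 1]
        assert r > 0.999

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            canonical_hrf(0.0)


class TestRunAssignment:
    def test_study_scale_eight_per_run(self, full_schedule):
        asg = assign_trials_to_runs(full_schedule, None, 6, rng=0)
        cond = np.array([t.condition for t in full_schedule.trials])
        for run in range(6):
            for c in CONDITIONS:
                assert np.sum((asg.run_of_trial == run) & (cond == c)) == 8
        assert not asg.dropped.any() and not asg.erroneous.any()

    def test_seeds_differ_counts_match(self, full_schedule):
        a = assign_trials_to_runs(full_schedule, None, 6, rng=1)
        b = assign_trials_to_runs(full_schedule, None, 6, rng=2)
        assert not np.array_equal(a.run_of_trial, b.run_of_trial)
        assert np.array_equal(
            np.bincount(a.run_of_trial + 1), np.bincount(b.run_of_trial + 1)
        )

    def test_remainder_dropped(self, full_schedule):
        correct = np.ones(full_schedule.n_trials, dtype=bool)
        cg = [t.index for t in full_schedule.trials if t.condition == "CG"]
        correct[cg[0]] = False  # 47 correct CG trials -> 7 per run, 5 dropped
        asg = assign_trials_to_runs(full_schedule, correct, 6, rng=0)
        cond = np.array([t.condition for t in full_schedule.trials])
        in_runs = (asg.run_of_trial >= 0) & (cond == "CG")
        assert in_runs.sum() == 42
        assert (asg.dropped & (cond == "CG")).sum() == 5
        assert not asg.run_of_trial[~correct].max() >= 0

    def test_too_few_correct_trials(self, full_schedule):
        cond = np.array([t.condition for t in full_schedule.trials])
        correct = cond != "EC"  # zero correct EC trials
        with pytest.raises(ValueError, match="EC"):
            assign_trials_to_runs(full_schedule, correct, 6, rng=0)

    def test_behavior_dataframe_accepted(self, small_schedule):
        df = pd.DataFrame(
            {"trial": range(small_schedule.n_trials),
             "correct": [True] * small_schedule.n_trials}
        )
        asg = assign_trials_to_runs(small_schedule, df, 6, rng=0)
        assert (asg.run_of_trial >= 0).all()


class TestDesignMatrix:
    def test_column_structure(self, small_schedule):
        asg = assign_trials_to_runs(small_schedule, None, 6, rng=0)
        X, names = build_run_design(small_schedule, asg, run=0)
        n_vol = n_volumes_for(small_schedule)
        n_drift = cosine_drift(n_vol, 2.0).shape[1]
        assert X.shape == (n_vol, 4 + 1 + n_drift + 1)
        assert names[:4] == list(CONDITIONS) and names[4] == "nuisance"
        assert names[-1] == "intercept"

    def test_all_null_schedule_has_no_task_columns(self):
        params = DesignParams()
        sched = Schedule(
            trials=[], null_events=[(0, 12_500), (12_500, 13_000)], params=params
        )
        asg = RunAssignment(
            run_of_trial=np.empty(0, dtype=int),
            n_runs=6,
            erroneous=np.empty(0, dtype=bool),
            dropped=np.empty(0, dtype=bool),
        )
        X, names = build_run_design(sched, asg, run=0, n_volumes=40)
        assert names[0] == "nuisance" and "CG" not in names

    def test_empty_condition_regressor_raises(self, small_schedule):
        asg = assign_trials_to_runs(small_schedule, None, 6, rng=0)
        cond = np.array([t.condition for t in small_schedule.trials])
        bad = asg.run_of_trial.copy()
        bad[(bad == 0) & (cond == "CG")] = -1
        asg.run_of_trial = bad
        with pytest.raises(ValueError, match="CG"):
            build_run_design(small_schedule, asg, run=0)

    def test_cosine_drift_cutoff(self):
        basis = cosine_drift(n_volumes=400, tr_s=2.0, cutoff_s=128.0)
        assert basis.shape == (400, 12)  # floor(2*800/128)
        # slowest included cosine has period 2*T/1 > 128 s
        assert np.allclose(basis.T @ basis, np.eye(12), atol=1e-10)


class TestFitGlm:
    def test_exact_recovery_on_generated_data(self, small_schedule):
        asg = assign_trials_to_runs(small_schedule, None, 6, rng=0)
        X, names = build_run_design(small_schedule, asg, run=2)
        rng = np.random.default_rng(0)
        true = rng.standard_normal((X.shape[1], 7))
        Y = X @ true
        betas, resid_var = fit_glm(Y, X, names)
        assert np.allclose(betas, true, atol=1e-8)
        assert np.allclose(resid_var, 0.0, atol=1e-16)

    def test_pure_noise_betas_near_zero(self, small_schedule):
        asg = assign_trials_to_runs(small_schedule, None, 6, rng=0)
        X, names = build_run_design(small_schedule, asg, run=0)
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((X.shape[0], 200))
        betas, _ = fit_glm(Y, X, names)
        cond_betas = betas[:4]
        se = cond_betas.std()
        assert np.abs(cond_betas.mean()) < 3 * se / np.sqrt(cond_betas.size)

    def test_duplicated_regressor_raises(self):
        X = np.column_stack([np.ones(50), np.arange(50.0), np.arange(50.0)])
        with pytest.raises(RankDeficientDesignError, match="col"):
            fit_glm(np.zeros((50, 1)), X)

    def test_more_columns_than_volumes_rejected(self):
        with pytest.raises(ValueError):
            fit_glm(np.zeros((3, 1)), np.zeros((3, 5)))


@pytest.fixture(scope="module")
def noiseless():
    rng = np.random.default_rng(10)
    sched = generate_schedule(DesignParams(trials_per_condition=12, n_null=12), rng)
    pop = make_voxel_population(15, tuning_gain=1.0, noise_sd=0.0,
                                baseline=0.5, rng=rng)
    amps = simulate_trial_amplitudes(pop, sched, rng)
    bold = simulate_bold(amps, sched, noise_sd=0.0)
    asg = assign_trials_to_runs(sched, None, 6, rng=rng)
    return sched, pop, bold, asg


class TestExtractBetas:
    def test_shape(self, noiseless):
        sched, pop, bold, asg = noiseless
        betas = extract_beta_array(sched, asg, bold)
        assert betas.values.shape == (6, 4, 15)

    def test_single_variant_recovers_amplitudes_exactly(self, noiseless):
        sched, pop, bold, asg = noiseless
        betas = extract_beta_array(sched, asg, bold, variant="single")
        expected = 0.5 + pop.mu.T  # baseline + condition means, every run
        assert np.abs(betas.values - expected[None]).max() < 1e-6

    def test_per_run_variant_recovers_amplitudes_approximately(self, noiseless):
        sched, pop, bold, asg = noiseless
        betas = extract_beta_array(sched, asg, bold, variant="per-run")
        expected = 0.5 + pop.mu.T
        est = betas.values.mean(axis=0)
        r = np.corrcoef(est.ravel(), expected.ravel())[0, 1]
        assert r > 0.95

    def test_nuisance_absorbs_global_amplitude_shift(self):
        # no null events, so the nuisance column is exactly the unassigned
        # trials' regressor and a global shift of their amplitudes lies in
        # its span: run betas must not move
        rng = np.random.default_rng(4)
        sched = generate_schedule(DesignParams(trials_per_condition=12, n_null=0), rng)
        pop = make_voxel_population(8, tuning_gain=1.0, noise_sd=0.0, rng=rng)
        amps = simulate_trial_amplitudes(pop, sched, rng)
        asg = assign_trials_to_runs(sched, None, 6, rng=rng)
        shifted = amps.copy()
        shifted[asg.run_of_trial != 0] += 5.0
        b0 = extract_beta_array(sched, asg, simulate_bold(amps, sched), variant="per-run")
        b1 = extract_beta_array(sched, asg, simulate_bold(shifted, sched), variant="per-run")
        assert np.allclose(b0.values[0], b1.values[0], atol=1e-8)

    def test_run_label_permutation_equivariance(self, noiseless):
        sched, pop, bold, asg = noiseless
        betas = extract_beta_array(sched, asg, bold)
        perm = np.array([3, 0, 5, 1, 4, 2])
        asg2 = RunAssignment(
            run_of_trial=np.where(
                asg.run_of_trial >= 0, perm[asg.run_of_trial], -1
            ),
            n_runs=6,
            erroneous=asg.erroneous,
            dropped=asg.dropped,
        )
        betas2 = extract_beta_array(sched, asg2, bold)
        assert np.allclose(betas2.values[perm], betas.values, atol=1e-10)

    def test_recovery_correlation_under_noise(self):
        # the spec-level SNR sanity check: per-condition mean betas track mu
        rng = np.random.default_rng(21)
        sched = generate_schedule(DesignParams(), rng)  # study-scale session
        pop = make_voxel_population(100, tuning_gain=1.0, noise_sd=1.0, rng=rng)
        amps = simulate_trial_amplitudes(pop, sched, rng)
        bold = simulate_bold(amps, sched, noise_sd=1.0, rng=rng)
        asg = assign_trials_to_runs(sched, None, 6, rng=rng)
        betas = extract_beta_array(sched, asg, bold)
        est = betas.values.mean(axis=0)
        r = np.corrcoef(est.ravel(), pop.mu.T.ravel())[0, 1]
        assert r > 0.9


class TestZNormalize:
    def test_mean_zero_sd_one(self, rng):
        betas = BetaArray(values=rng.standard_normal((6, 4, 30)) * 3 + 5)
        z = znormalize(betas)
        flat = z.values.reshape(-1, 30)
        assert np.abs(flat.mean(axis=0)).max() < 1e-6
        assert np.abs(flat.std(axis=0) - 1).max() < 1e-6
        assert z.normalized

    def test_affine_invariance(self, rng):
        v = rng.standard_normal((6, 4, 10))
        z1 = znormalize(BetaArray(values=v))
        z2 = znormalize(BetaArray(values=2.5 * v + 7.0))
        assert np.allclose(z1.values, z2.values, atol=1e-12)

    def test_idempotent(self, rng):
        v = rng.standard_normal((6, 4, 10))
        z1 = znormalize(BetaArray(values=v))
        z2 = znormalize(z1)
        assert np.allclose(z1.values, z2.values, atol=1e-12)

    def test_rank_order_preserved(self, rng):
        v = rng.standard_normal((6, 4, 5))
        z = znormalize(BetaArray(values=v))
        for vox in range(5):
            assert np.array_equal(
                np.argsort(v[:, :, vox].ravel()), np.argsort(z.values[:, :, vox].ravel())
            )

    def test_constant_voxel_flagged(self, rng):
        v = rng.standard_normal((6, 4, 3))
        v[:, :, 1] = 2.0
        z = znormalize(BetaArray(values=v))
        assert z.excluded.tolist() == [False, True, False]
        assert np.isnan(z.values[:, :, 1]).all()

    def test_per_run_axis(self, rng):
        v = rng.standard_normal((6, 4, 50))
        z = znormalize(BetaArray(values=v), axis="run")
        assert np.abs(z.values.mean(axis=2)).max() < 1e-6


class TestRunwiseGLMModel:
    def test_fit_returns_normalized_betas(self, small_schedule):
        rng = np.random.default_rng(9)
        pop = make_voxel_population(10, tuning_gain=1.0, noise_sd=0.5, rng=rng)
        amps = simulate_trial_amplitudes(pop, small_schedule, rng)
        bold = simulate_bold(amps, small_schedule, noise_sd=0.5, rng=rng)
        model = RunwiseGLM(small_schedule, bold)
        betas = model.fit(rng=3)
        assert betas.normalized and betas.values.shape == (6, 4, 10)
        assert model.assignment_.n_runs == 6

    def test_long_frame_round_trip(self, rng):
        betas = BetaArray(values=rng.standard_normal((6, 4, 7)))
        df = betas.to_long_frame(subject=3)
        back = BetaArray.from_long_frame(df)
        assert np.allclose(back.values, betas.values)
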