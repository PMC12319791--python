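"""Run splits, least-squares fits, cross-validation schemes and the
felt-vs-perceived contrast."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from emokinetics.config import ValidationError
from emokinetics.fitting import (FitResult, LinearEncodingModel,
                                 between_run_cv, contrast_tasks,
                                 enumerate_run_splits, fit_linear_map,
                                 participant_folds, within_run_cv)


class TestRunSplits:
    def test_five_choose_three_gives_ten(self):
        assert len(enumerate_run_splits(5, 3)) == 10

    def test_three_choose_two_gives_three(self):
        assert len(enumerate_run_splits(3, 2)) == 3

    def test_matches_subset_enumeration_no_duplicates(self):
        runs = [f"run{i}" for i in range(1, 6)]
        splits = enumerate_run_splits(runs, 3)
        oracle = {tuple(c) for c in combinations(runs, 3)}
        got = {s.train for s in splits}
        assert got == oracle and len(splits) == len(got)
        for s in splits:
            assert set(s.train) | set(s.test) == set(runs)
            assert not set(s.train) & set(s.test)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValidationError):
            enumerate_run_splits(3, 3)


class TestLinearMap:
    def test_orthonormal_design_recovers_weights(self, rng):
        Q, _ = np.linalg.qr(rng.normal(size=(60, 4)))
        Q = Q - Q.mean(axis=0)
        B = rng.normal(size=(4, 3))
        beta = fit_linear_map(Q, Q @ B)
        np.testing.assert_allclose(beta, B, atol=1e-10)

    def test_uncorrelated_noise_gives_small_betas(self, rng):
        X = rng.normal(size=(2000, 3))
        Y = rng.normal(size=(2000, 2))
        beta = fit_linear_map(X, Y)
        # betas ~ N(0, 1/sqrt(T)); bound at 3 standard errors
        assert np.abs(beta).max() < 3.0 / np.sqrt(2000) * 3

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_oracle(self, seed):
        r = np.random.default_rng(seed)
        t, p, q = 80, 4, 2
        X, Y = r.normal(size=(t, p)), r.normal(size=(t, q))
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)
        oracle = np.linalg.solve(Xc.T @ Xc, Xc.T @ Yc)
        np.testing.assert_allclose(fit_linear_map(X, Y), oracle, atol=1e-8)

    def test_underdetermined_rejected(self, rng):
        with pytest.raises(ValidationError):
            fit_linear_map(rng.normal(size=(3, 5)), rng.normal(size=(3, 1)))

    def test_estimator_api(self, rng):
        X, Y = rng.normal(size=(50, 3)), rng.normal(size=(50, 2))
        m = LinearEncodingModel().fit(X, Y)
        assert m.coef_.shape == (3, 2)
        assert m.get_params() == {}
        np.testing.assert_allclose(m.predict(X).mean(0), Y.mean(0),
                                   atol=1e-10)


class TestBetweenRunCV:
    def test_noiseless_encode_fits_are_one(self, small_noiseless_study):
        st = small_noiseless_study
        d = {r: st.designs[(r, "perceived")] for r in st.dataset.runs}
        fit = between_run_cv(st.dataset, d, n_train=2, seed=0)
        # every ROI has nonzero beta in this fixture
        assert (np.abs(st.truth.beta["perceived"].to_numpy()).sum(axis=1)
                > 0).all()
        np.testing.assert_allclose(fit.test_fit.to_numpy(), 1.0, atol=1e-6)

    def test_noiseless_decode_fits_are_one(self, small_noiseless_study):
        st = small_noiseless_study
        d = {r: st.designs[(r, "perceived")] for r in st.dataset.runs}
        fit = between_run_cv(st.dataset, d, direction="decode", n_train=2,
                             seed=0)
        np.testing.assert_allclose(fit.mean_fit.to_numpy(), 1.0, atol=1e-6)

    def test_beta_recovery_at_high_snr(self, small_noisy_study):
        from emokinetics.conditioning import condition_dataset
        from emokinetics.simulate import SimulationSpec, simulate_study

        spec = SimulationSpec(n_raters=4, n_emotions=8, n_reliable=5,
                              n_runs=3, n_timepoints_per_run=300,
                              n_participants=5, n_rois=10, snr=5.0,
                              rng_seed=11)
        rel = spec.emotions[:5]
        st = simulate_study(spec, tasks=("perceived",), emotions=rel)
        cond = condition_dataset(st.dataset, bandpass=False)
        d = {r: st.designs[(r, "perceived")].subset(rel) for r in cond.runs}
        fit = between_run_cv(cond, d, n_train=2, seed=0)
        bt = st.truth.beta["perceived"].to_numpy()
        est = fit.beta.to_numpy().T
        assert np.corrcoef(bt.ravel(), est.ravel())[0, 1] >= 0.9

    def test_null_decode_scores_below_null_maximum(self):
        """On pure-noise data, observed decoding stays below the shuffled-
        label null maximum for nearly all emotions."""
        from emokinetics.simulate import SimulationSpec, simulate_study

        below = 0
        total = 0
        for seed in range(3):
            spec = SimulationSpec(n_raters=3, n_emotions=5, n_reliable=5,
                                  n_runs=3, n_timepoints_per_run=150,
                                  n_participants=4, n_rois=8, snr=1.0,
                                  rng_seed=100 + seed)
            st = simulate_study(spec, null=True, tasks=("perceived",))
            d = {r: st.designs[(r, "perceived")] for r in st.dataset.runs}
            fit = between_run_cv(st.dataset, d, direction="decode",
                                 n_train=2, n_null=50, seed=seed)
            below += int((~fit.significant).sum())
            total += len(fit.significant)
        assert below / total >= 0.9

    def test_more_training_runs_do_not_hurt(self):
        from emokinetics.simulate import SimulationSpec, simulate_study

        diffs = []
        for seed in range(3):
            spec = SimulationSpec(n_raters=3, n_emotions=5, n_reliable=5,
                                  n_runs=4, n_timepoints_per_run=150,
                                  n_participants=4, n_rois=8, snr=0.5,
                                  rng_seed=200 + seed, beta_sparsity=0.0)
            st = simulate_study(spec, tasks=("perceived",))
            d = {r: st.designs[(r, "perceived")] for r in st.dataset.runs}
            f1 = between_run_cv(st.dataset, d, n_train=1, seed=0)
            f3 = between_run_cv(st.dataset, d, n_train=3, seed=0)
            diffs.append(f3.test_fit.to_numpy().mean()
                         - f1.test_fit.to_numpy().mean())
        assert np.mean(diffs) >= 0


class TestWithinRunCV:
    def test_fold_sizes_differ_by_at_most_one(self, rng):
        participants = [f"s{i}" for i in range(50)]
        folds = participant_folds(participants, 10, rng)
        assert sorted(len(f) for f in folds) == [5] * 10
        # 50 participants, 10 folds -> training sets of 45
        assert all(50 - len(f) == 45 for f in folds)

    def test_each_participant_in_exactly_one_fold(self, rng):
        participants = [f"s{i}" for i in range(17)]
        folds = participant_folds(participants, 5, rng)
        assert sorted(p for f in folds for p in f) == sorted(participants)
        assert max(len(f) for f in folds) - min(len(f) for f in folds) <= 1

    def test_too_many_folds_rejected(self, rng):
        with pytest.raises(ValidationError):
            participant_folds(["a", "b"], 3, rng)

    def test_noiseless_heldout_fits_are_one(self, small_noiseless_study):
        st = small_noiseless_study
        d = {r: st.designs[(r, "perceived")] for r in st.dataset.runs}
        fit = within_run_cv(st.dataset, d, n_folds=2, n_train=2, seed=0)
        np.testing.assert_allclose(fit.test_fit.to_numpy(), 1.0, atol=1e-6)


def fitresult_from(matrix):
    df = pd.DataFrame(matrix,
                      index=[f"s{i}" for i in range(matrix.shape[0])],
                      columns=[f"roi{j}" for j in range(matrix.shape[1])])
    return FitResult("encode", "between-runs", "x", None, df,
                     matrix[None], [])


class TestContrast:
    def test_identical_inputs_give_zero_t_empty_mask(self, rng):
        m = rng.normal(size=(8, 5))
        res = contrast_tasks(fitresult_from(m), fitresult_from(m.copy()),
                             n_perm=100, seed=0)
        np.testing.assert_allclose(res.t.to_numpy(), 0.0)
        assert (res.mask == 0).all()

    def test_planted_difference_detected(self, rng):
        base = rng.normal(size=(12, 6), scale=0.05)
        felt = base.copy()
        felt[:, :2] += 0.5                     # strong felt-only effect
        res = contrast_tasks(fitresult_from(felt), fitresult_from(base),
                             n_perm=200, seed=0)
        assert (res.mask.iloc[:2] == 1).all()
        assert (res.mask.iloc[2:] == 0).all()

    def test_participant_order_invariance(self, rng):
        a, b = rng.normal(size=(10, 4)), rng.normal(size=(10, 4))
        r1 = contrast_tasks(fitresult_from(a), fitresult_from(b),
                            n_perm=50, seed=1)
        perm = rng.permutation(10)
        r2 = contrast_tasks(fitresult_from(a[perm]), fitresult_from(b[perm]),
                            n_perm=50, seed=1)
        np.testing.assert_allclose(r1.t.to_numpy(), r2.t.to_numpy(),
                                   atol=1e-12)

    def test_single_participant_rejected(self, rng):
        m = rng.normal(size=(1, 3))
        with pytest.raises(ValidationError):
            contrast_tasks(fitresult_from(m), fitresult_from(m), 10, 0)
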