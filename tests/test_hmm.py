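import itertools

import numpy as np
import pytest
from hmmlearn.hmm import GaussianHMM

from eden_gaze.errors import InsufficientDataError
from eden_gaze.hmm import (
    StateModel,
    _log_gaussian,
    _PackedSegments,
    _segment_posteriors,
    _segment_viterbi,
    clamp_covariances,
    decode,
    ellipse_area,
    fit_model,
    match_states,
    model_selection_curve,
    pooled_valid_segments,
    read_model,
    stationary_distribution,
    write_model,
)
from eden_gaze.io import normalize_coordinates
from eden_gaze.synthetic import SynthConfig, simulate_trials

from conftest import make_trial


def random_model(rng, K):
    means = rng.uniform(0.1, 0.9, (K, 2))
    sds = rng.uniform(0.03, 0.12, K)
    covs = np.array([sd**2 * np.eye(2) for sd in sds])
    trans = rng.dirichlet(np.ones(K), size=K)
    init = rng.dirichlet(np.ones(K))
    return StateModel(K=K, means=means, covariances=covs, transition=trans,
                      initial=init, log_likelihood=0.0, n_restarts_used=0, seed=0)


def brute_force_decode(model, X):
    """Enumerate all K^T paths; return (best path, posteriors)."""
    K, T = model.K, len(X)
    logB = _log_gaussian(X, model.means, model.covariances)
    with np.errstate(divide="ignore"):
        logA = np.log(model.transition)
        logpi = np.log(model.initial)
    paths = np.array(list(itertools.product(range(K), repeat=T)))
    logp = logpi[paths[:, 0]] + logB[0, paths[:, 0]]
    for t in range(1, T):
        logp += logA[paths[:, t - 1], paths[:, t]] + logB[t, paths[:, t]]
    w = np.exp(logp - logp.max())
    w /= w.sum()
    post = np.array([[w[paths[:, t] == k].sum() for k in range(K)] for t in range(T)])
    return paths[np.argmax(logp)], post


class TestCovarianceClamps:
    def test_small_area_scaled_up_to_lower_bound(self):
        covs = np.array([1e-6 * np.eye(2), 2e-3 * np.eye(2)])
        out, n_area, _ = clamp_covariances(covs, axis_clamp_sd=10.0)
        assert n_area == 1
        assert ellipse_area(out[0]) == pytest.approx(0.001, rel=1e-9)
        assert ellipse_area(out[1]) == pytest.approx(ellipse_area(covs[1]), rel=1e-9)

    def test_large_area_scaled_down_to_upper_bound(self):
        covs = np.array([0.5 * np.eye(2)])
        out, n_area, _ = clamp_covariances(covs, axis_clamp_sd=10.0)
        assert n_area == 1
        assert ellipse_area(out[0]) == pytest.approx(0.05, rel=1e-9)

    def test_axis_outlier_clipped_toward_pool(self):
        # one state much more elongated than the rest
        covs = np.array([np.diag([4e-3, 4e-3])] * 4 + [np.diag([4e-2, 4e-4])])
        out, _, n_axis = clamp_covariances(covs, area_bounds=(1e-4, 0.9),
                                           axis_clamp_sd=1.0)
        assert n_axis >= 1
        w = np.linalg.eigvalsh(out[-1])
        assert w.max() / w.min() < 4e-2 / 4e-4  # elongation reduced

    def test_within_bounds_is_identity(self):
        covs = np.array([2e-3 * np.eye(2), 3e-3 * np.eye(2)])
        out, n_area, n_axis = clamp_covariances(covs)
        assert n_area == 0 and n_axis == 0
        np.testing.assert_allclose(out, covs, atol=1e-12)


class TestFitModel:
    def test_single_state_closed_form(self):
        rng = np.random.default_rng(1)
        pts = 0.5 + 0.05 * rng.standard_normal((400, 2))
        trial = make_trial(pts[:, 0], pts[:, 1], normalized=True)
        m = fit_model([trial], K=1, n_restarts=1, seed=0)
        np.testing.assert_allclose(m.means[0], pts.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(m.covariances[0], np.cov(pts.T, ddof=0), atol=1e-6)
        np.testing.assert_allclose(m.transition, [[1.0]])
        np.testing.assert_allclose(m.initial, [1.0])

    def test_identical_seed_identical_model(self, small_cohorts_normalized):
        _, norm, _ = small_cohorts_normalized
        sub = [t for t in norm if t.stimulus_id == "S00"][:4]
        m1 = fit_model(sub, K=3, n_restarts=2, seed=5)
        m2 = fit_model(sub, K=3, n_restarts=2, seed=5)
        assert m1.log_likelihood == m2.log_likelihood
        np.testing.assert_array_equal(m1.means, m2.means)
        np.testing.assert_array_equal(m1.transition, m2.transition)

    def test_insufficient_data_raises(self):
        trial = make_trial([0.1, 0.2, 0.3], [0.1, 0.2, 0.3], normalized=True)
        with pytest.raises(InsufficientDataError):
            fit_model([trial], K=5)

    def test_requires_normalized_trials(self, small_cohorts):
        _, trials, _ = small_cohorts
        from eden_gaze.errors import InvalidConfigError
        with pytest.raises(InvalidConfigError):
            fit_model(trials[:2], K=2)

    def test_recovers_well_separated_states(self):
        cfg = SynthConfig(n_participants_per_cohort=8, n_stimuli=1, k_true=3,
                          seed=3)
        trials, gt = simulate_trials(cfg)
        norm = [normalize_coordinates(t, cfg.stim_width_px, cfg.stim_height_px)
                for t in trials]
        m = fit_model(norm, K=3, n_restarts=5, seed=3)
        _, err = match_states(gt.state_means["S00"], m.means)
        assert err < 0.05

    def test_recovery_improves_with_more_trials(self):
        errs = []
        for n_trials in (4, 16, 64):
            cfg = SynthConfig(n_participants_per_cohort=max(n_trials // 2, 2),
                              n_stimuli=1, k_true=3, seed=17)
            trials, gt = simulate_trials(cfg)
            norm = [normalize_coordinates(t, cfg.stim_width_px, cfg.stim_height_px)
                    for t in trials[:n_trials]]
            m = fit_model(norm, K=3, n_restarts=3, seed=17)
            _, err = match_states(gt.state_means["S00"], m.means)
            errs.append(err)
        assert errs[-1] <= errs[0]

    def test_fitted_areas_respect_bounds(self, small_cohorts_normalized):
        _, norm, _ = small_cohorts_normalized
        sub = [t for t in norm if t.stimulus_id == "S00"]
        m = fit_model(sub, K=4, n_restarts=2, seed=1)
        for cov in m.covariances:
            assert 0.001 * (1 - 1e-6) <= ellipse_area(cov) <= 0.05 * (1 + 1e-6)

    def test_model_json_round_trip(self, tmp_path, small_cohorts_normalized):
        _, norm, _ = small_cohorts_normalized
        m = fit_model(norm[:2], K=2, n_restarts=1, seed=0)
        path = tmp_path / "model.json"
        write_model(m, path)
        back = read_model(path)
        np.testing.assert_allclose(back.means, m.means)
        np.testing.assert_allclose(back.transition, m.transition)
        assert back.log_likelihood == m.log_likelihood


class TestDecode:
    def test_single_state_posterior_is_one(self):
        trial = make_trial([0.4, 0.5, 0.6], [0.5, 0.5, 0.5], normalized=True)
        m = StateModel(K=1, means=[[0.5, 0.5]], covariances=[[[0.01, 0], [0, 0.01]]],
                       transition=[[1.0]], initial=[1.0], log_likelihood=0.0,
                       n_restarts_used=1, seed=0)
        seq = decode(m, trial)
        np.testing.assert_allclose(seq.posteriors, 1.0)
        assert (seq.viterbi == 0).all()

    def test_posterior_rows_sum_to_one(self, small_cohorts_normalized):
        _, norm, _ = small_cohorts_normalized
        m = fit_model([norm[0]], K=3, n_restarts=1, seed=2)
        seq = decode(m, norm[0])
        sums = seq.posteriors[seq.valid].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        assert np.isnan(seq.posteriors[~seq.valid]).all()
        assert (seq.viterbi[~seq.valid] == -1).all()

    def test_zero_valid_samples_gives_empty_sequence(self):
        trial = make_trial([np.nan, np.nan], [np.nan, np.nan], normalized=True)
        m = random_model(np.random.default_rng(0), 2)
        seq = decode(m, trial)
        assert seq.empty
        assert np.isnan(seq.posteriors).all() and (seq.viterbi == -1).all()

    def test_viterbi_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            K = int(rng.integers(1, 4))
            T = int(rng.integers(2, 9))
            model = random_model(rng, K)
            X = rng.uniform(0, 1, (T, 2))
            logB = _log_gaussian(X, model.means, model.covariances)
            vit = _segment_viterbi(logB, model.initial, model.transition)
            best_path, post_oracle = brute_force_decode(model, X)
            np.testing.assert_array_equal(vit, best_path)
            post = _segment_posteriors(logB, model.initial, model.transition)
            np.testing.assert_allclose(post, post_oracle, atol=1e-9)

    def test_matches_hmmlearn_reference(self):
        rng = np.random.default_rng(7)
        model = random_model(rng, 3)
        X = rng.uniform(0, 1, (60, 2))
        hm = GaussianHMM(n_components=3, covariance_type="full",
                         init_params="", params="")
        hm.n_features = 2
        hm.startprob_ = model.initial
        hm.transmat_ = model.transition
        hm.means_ = model.means
        hm.covars_ = model.covariances
        logB = _log_gaussian(X, model.means, model.covariances)
        np.testing.assert_allclose(
            _segment_posteriors(logB, model.initial, model.transition),
            hm.predict_proba(X), atol=1e-8,
        )
        np.testing.assert_array_equal(
            _segment_viterbi(logB, model.initial, model.transition), hm.predict(X)
        )

    def test_packed_loglik_matches_hmmlearn_over_segments(self):
        rng = np.random.default_rng(8)
        model = random_model(rng, 3)
        lengths = [5, 17, 3, 40, 1, 9]
        X = rng.uniform(0, 1, (sum(lengths), 2))
        packed = _PackedSegments(X, lengths)
        logB = _log_gaussian(packed.X_packed, model.means, model.covariances)
        ll, gamma, _, _ = packed.estep(logB, model.initial, model.transition)
        hm = GaussianHMM(n_components=3, covariance_type="full",
                         init_params="", params="")
        hm.n_features = 2
        hm.startprob_ = model.initial
        hm.transmat_ = model.transition
        hm.means_ = model.means
        hm.covars_ = model.covariances
        assert ll == pytest.approx(hm.score(X, lengths), abs=1e-6)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_long_run_marginal_approaches_stationary(self):
        model = StateModel(
            K=3,
            means=[[0.2, 0.2], [0.8, 0.2], [0.5, 0.8]],
            covariances=np.tile(0.0025 * np.eye(2), (3, 1, 1)),
            transition=[[0.9, 0.05, 0.05], [0.1, 0.8, 0.1], [0.2, 0.2, 0.6]],
            initial=[1 / 3] * 3,
            log_likelihood=0.0, n_restarts_used=1, seed=0,
        )
        rng = np.random.default_rng(0)
        # autocorrelation of the sticky chain leaves ~1,500 effective draws
        # per 30k samples; 60k keeps Monte-Carlo error well inside the band
        T = 60000
        states = np.empty(T, int)
        states[0] = 0
        A = model.transition
        cum = np.cumsum(A, axis=1)
        u = rng.random(T)
        for t in range(1, T):
            states[t] = np.searchsorted(cum[states[t - 1]], u[t])
        xy = model.means[states] + 0.05 * rng.standard_normal((T, 2))
        trial = make_trial(np.clip(xy[:, 0], 0, 1), np.clip(xy[:, 1], 0, 1),
                           rate_hz=300.0, normalized=True)
        seq = decode(model, trial)
        marginal = seq.posteriors.mean(axis=0)
        np.testing.assert_allclose(marginal, stationary_distribution(A), atol=0.02)


class TestModelSelection:
    def test_likelihood_saturates_beyond_true_k(self):
        cfg = SynthConfig(n_participants_per_cohort=4, n_stimuli=1, k_true=3,
                          duration_s=15.0, seed=19)
        trials, _ = simulate_trials(cfg)
        norm = [normalize_coordinates(t, cfg.stim_width_px, cfg.stim_height_px)
                for t in trials]
        curve = model_selection_curve(norm, [1, 3, 6], seed=19, n_restarts=3)
        ll = curve["log_likelihood"].to_numpy()
        assert ll[1] - ll[0] > ll[2] - ll[1]  # gain 1->3 dwarfs gain 3->6
        # non-decreasing up to restart noise
        assert ll[1] >= ll[0] - 0.001 * abs(ll[0])
        assert ll[2] >= ll[1] - 0.001 * abs(ll[1])

    def test_single_k_matches_fit_model(self, small_cohorts_normalized):
        _, norm, _ = small_cohorts_normalized
        sub = [t for t in norm if t.stimulus_id == "S00"][:3]
        curve = model_selection_curve(sub, [3], seed=4, n_restarts=2)
        m = fit_model(sub, K=3, n_restarts=2, seed=4)
        assert curve.loc[0, "log_likelihood"] == m.log_likelihood


class TestSegmentPooling:
    def test_gaps_split_sequences(self):
        x = [0.1, 0.2, np.nan, 0.4, 0.5, 0.6]
        trial = make_trial(x, x, normalized=True)
        X, lengths = pooled_valid_segments([trial])
        assert lengths == [2, 3]
        assert len(X) == 5
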