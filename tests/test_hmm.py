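import itertools

import numpy as np
import pytest
from scipy.stats import norm

from shpkit.exceptions import (
    DegenerateDataError,
    InsufficientDwellsError,
    InvalidParameterError,
)
from shpkit.hmm import (
    BOUND,
    UNBOUND,
    DwellTimes,
    HMMParams,
    StateSequence,
    Trajectory,
    dwell_times,
    estimate_rates,
    fit_hmm,
    pool_dwells,
    viterbi_decode,
)
from shpkit.synthetic import SimConfig, gen_trajectory


def make_params(mu=(0.0, 100.0), sd=(10.0, 10.0), stay=(0.98, 0.95)):
    a = np.array([[stay[0], 1 - stay[0]], [1 - stay[1], stay[1]]])
    return HMMParams(means=np.array(mu), sds=np.array(sd),
                     transmat=a, startprob=np.array([0.5, 0.5]))


def sample_hmm(params, n, rng):
    states = np.empty(n, dtype=int)
    states[0] = rng.choice(2, p=params.startprob)
    for t in range(1, n):
        states[t] = rng.choice(2, p=params.transmat[states[t - 1]])
    y = params.means[states] + rng.normal(0, 1, n) * params.sds[states]
    return y, states


class TestTypes:
    def test_trajectory_validation(self):
        with pytest.raises(InvalidParameterError):
            Trajectory(intensities=np.zeros(5))
        with pytest.raises(InvalidParameterError):
            Trajectory(intensities=np.full(20, np.nan))

    def test_params_label_convention(self):
        with pytest.raises(InvalidParameterError):
            make_params(mu=(100.0, 0.0))

    def test_params_row_stochastic(self):
        with pytest.raises(InvalidParameterError):
            HMMParams(means=[0, 1], sds=[1, 1],
                      transmat=[[0.9, 0.2], [0.1, 0.9]], startprob=[0.5, 0.5])


class TestFitHMM:
    def test_recovers_generating_parameters(self, rng):
        truth = make_params()
        trajs = [Trajectory(sample_hmm(truth, 2000, rng)[0]) for _ in range(10)]
        fit = fit_hmm(trajs)
        p = fit.params
        assert p.means == pytest.approx(truth.means, abs=2.0)
        assert p.sds == pytest.approx(truth.sds, rel=0.10)
        assert np.diag(p.transmat) == pytest.approx(np.diag(truth.transmat),
                                                    abs=0.01)

    def test_noiseless_two_level_trace(self):
        y = np.array([0.0] * 30 + [100.0] * 40 + [0.0] * 30)
        fit = fit_hmm([Trajectory(np.tile(y, 3))])
        p = fit.params
        assert p.mu_unbound == pytest.approx(0.0, abs=1e-6)
        assert p.mu_bound == pytest.approx(100.0, abs=1e-6)
        assert p.sds[0] < 1.0 and p.sds[1] < 1.0

    def test_loglik_monotone_nondecreasing(self, rng):
        truth = make_params(sd=(20.0, 25.0))
        trajs = [Trajectory(sample_hmm(truth, 1000, rng)[0]) for _ in range(3)]
        fit = fit_hmm(trajs, tol=0.0, max_iter=40)
        ll = fit.log_likelihoods
        assert np.all(np.diff(ll) >= -1e-6 * np.abs(ll[:-1]))

    def test_single_level_data_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_hmm([Trajectory(np.full(300, 5.0))])

    def test_needs_enough_frames(self):
        with pytest.raises(InvalidParameterError):
            fit_hmm([Trajectory(np.arange(50, dtype=float))])

    def test_deterministic(self, rng):
        truth = make_params()
        trajs = [Trajectory(sample_hmm(truth, 500, rng)[0]) for _ in range(2)]
        p1 = fit_hmm(trajs).params
        p2 = fit_hmm(trajs).params
        np.testing.assert_array_equal(p1.means, p2.means)
        np.testing.assert_array_equal(p1.transmat, p2.transmat)


class TestViterbi:
    def test_noiseless_exact_decoding(self):
        params = make_params(sd=(1.0, 1.0))
        states = np.array([0] * 20 + [1] * 30 + [0] * 10)
        y = params.means[states]
        seq = viterbi_decode(Trajectory(y.astype(float)), params)
        np.testing.assert_array_equal(seq.states, states)

    def test_high_snr_accuracy(self, rng):
        truth = make_params(sd=(10.0, 10.0))  # SNR 10
        correct = total = 0
        for _ in range(5):
            y, states = sample_hmm(truth, 2000, rng)
            seq = viterbi_decode(Trajectory(y), truth)
            correct += (seq.states == states).sum()
            total += states.size
        assert correct / total >= 0.99

    def test_matches_exhaustive_enumeration(self, rng):
        # oracle: brute force over all 2^12 state paths
        params = make_params(mu=(0.0, 3.0), sd=(2.0, 2.5), stay=(0.8, 0.7))
        y = rng.normal(1.5, 2.0, 12)
        seq = viterbi_decode(Trajectory(y), params)

        best_ll, best_path = -np.inf, None
        log_a = np.log(params.transmat)
        log_pi = np.log(params.startprob)
        for path in itertools.product((0, 1), repeat=12):
            ll = log_pi[path[0]] + norm.logpdf(
                y[0], params.means[path[0]], params.sds[path[0]])
            for t in range(1, 12):
                ll += log_a[path[t - 1], path[t]] + norm.logpdf(
                    y[t], params.means[path[t]], params.sds[path[t]])
            if ll > best_ll:
                best_ll, best_path = ll, path
        assert seq.states.tolist() == list(best_path)
        assert seq.log_likelihood == pytest.approx(best_ll, rel=1e-9)

    def test_relabeling_symmetry(self, rng):
        params = make_params(mu=(0.0, 50.0), sd=(8.0, 8.0), stay=(0.9, 0.9))
        y, _ = sample_hmm(params, 500, rng)
        seq = viterbi_decode(Trajectory(y), params)
        mirrored = make_params(mu=(-50.0, 0.0), sd=(8.0, 8.0), stay=(0.9, 0.9))
        seq_m = viterbi_decode(Trajectory(-y), mirrored)
        np.testing.assert_array_equal(seq.states, 1 - seq_m.states)


class TestDwellTimes:
    def test_alternating_sequence(self):
        seq = StateSequence(states=np.array([1, 0, 1, 0, 1, 0]),
                            log_likelihood=0.0, frame_interval=0.05)
        d = dwell_times(seq)
        assert np.all(d.bound_s == 0.05) and np.all(d.unbound_s == 0.05)

    def test_all_bound_doubly_censored(self):
        seq = StateSequence(states=np.ones(40, dtype=int), log_likelihood=0.0,
                            frame_interval=0.05)
        d = dwell_times(seq)
        assert d.bound_s.tolist() == [2.0]
        assert d.bound_censored.tolist() == [True]
        assert d.unbound_s.size == 0

    def test_dwell_sum_equals_duration(self, rng):
        states = (rng.random(500) > 0.5).astype(int)
        seq = StateSequence(states=states, log_likelihood=0.0, frame_interval=0.05)
        d = dwell_times(seq)
        assert d.bound_s.sum() + d.unbound_s.sum() == pytest.approx(500 * 0.05)

    def test_censoring_flags_first_last(self):
        seq = StateSequence(states=np.array([0, 0, 1, 1, 0, 1, 1, 1]),
                            log_likelihood=0.0, frame_interval=1.0)
        d = dwell_times(seq)
        # dwells: U(2, censored), B(2), U(1), B(3, censored)
        assert d.bound_censored.tolist() == [False, True]
        assert d.unbound_censored.tolist() == [True, False]

    def test_pooled_simulated_bound_dwell_mean(self):
        # oracle: exponential mean 1/k_off = 5 s
        k_off = 0.2
        pooled = []
        for seed in range(30):
            cfg = SimConfig(seed=seed)
            _, gt = gen_trajectory(1.0, k_off, 0.0, 100.0, 0.0, 400.0, cfg)
            seq = StateSequence(states=gt.params["states"], log_likelihood=0.0,
                                frame_interval=cfg.frame_interval)
            pooled.append(dwell_times(seq))
        d = pool_dwells(pooled)
        bound = d.uncensored(BOUND)
        se = bound.std() / np.sqrt(bound.size)
        assert abs(bound.mean() - 5.0) < 2 * se + 0.05


class TestEstimateRates:
    def test_exact_dwells(self):
        d = DwellTimes(bound_s=np.ones(12), unbound_s=np.full(12, 2.0),
                       bound_censored=np.zeros(12, bool),
                       unbound_censored=np.zeros(12, bool))
        r = estimate_rates(d)
        assert r.k_off == pytest.approx(1.0)
        assert r.k_on_eff == pytest.approx(0.5)
        assert r.k_off_stderr == pytest.approx(1.0 / np.sqrt(12))

    def test_insufficient_dwells(self):
        d = DwellTimes(bound_s=np.ones(3), unbound_s=np.ones(20),
                       bound_censored=np.zeros(3, bool),
                       unbound_censored=np.zeros(20, bool))
        with pytest.raises(InsufficientDwellsError, match="BOUND"):
            estimate_rates(d)

    def test_simulation_recovery(self):
        # oracle: generator rates (0.1, 0.5) /s at 20 Hz
        k_on, k_off = 0.1, 0.5
        pooled = []
        for seed in range(60):
            cfg = SimConfig(seed=seed)
            _, gt = gen_trajectory(k_on, k_off, 0.0, 100.0, 0.0, 300.0, cfg)
            seq = StateSequence(states=gt.params["states"], log_likelihood=0.0,
                                frame_interval=cfg.frame_interval)
            pooled.append(dwell_times(seq))
        rates = estimate_rates(pool_dwells(pooled))
        assert rates.n_bound_dwells >= 500
        assert rates.k_on_eff == pytest.approx(k_on, rel=0.10)
        assert rates.k_off == pytest.approx(k_off, rel=0.10)

    def test_frame_rate_invariance(self):
        # halving the frame interval leaves dwell-based rates unchanged
        rates = {}
        for frame_rate in (20.0, 40.0):
            pooled = []
            for seed in range(40):
                cfg = SimConfig(seed=seed, frame_rate=frame_rate)
                _, gt = gen_trajectory(0.2, 0.2, 0.0, 100.0, 0.0, 200.0, cfg)
                seq = StateSequence(states=gt.params["states"],
                                    log_likelihood=0.0,
                                    frame_interval=cfg.frame_interval)
                pooled.append(dwell_times(seq))
            rates[frame_rate] = estimate_rates(pool_dwells(pooled))
        assert rates[20.0].k_off == pytest.approx(rates[40.0].k_off, rel=0.15)
        assert rates[20.0].k_on_eff == pytest.approx(rates[40.0].k_on_eff, rel=0.15)


class TestFullPipeline:
    def test_occupancy_matches_stationary_fraction(self):
        k_on, k_off = 0.4, 0.6
        cfg = SimConfig(seed=3)
        trajs, gts = [], []
        for i in range(10):
            t, g = gen_trajectory(k_on, k_off, 0.0, 100.0, 10.0, 100.0, cfg,
                                  molecule_id=f"m{i}")
            trajs.append(t)
            gts.append(g)
        fit = fit_hmm(trajs)
        frac = np.mean([viterbi_decode(t, fit.params).states.mean()
                        for t in trajs])
        expected = k_on / (k_on + k_off)
        assert frac == pytest.approx(expected, abs=0.05)
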