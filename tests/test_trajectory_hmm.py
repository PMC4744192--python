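"""Trajectory idealization: filtering, Gaussian-mixture state counting,
HMM fitting (EM), Viterbi decoding against exhaustive search, and dwell
statistics."""

import itertools

import numpy as np
import pytest

from foldscape.trajectory_hmm import (
    HMMResult,
    Trajectory,
    detect_rare_bound_states,
    dwell_and_rates,
    fit_extension_histogram,
    fit_hmm,
    mean_filter,
    read_trajectory,
    viterbi,
    write_trajectory,
)


def _traj(x, rate=1000.0, D=2800.0):
    x = np.asarray(x, float)
    t = np.arange(len(x)) / rate
    return Trajectory(
        time=t, extension=x, force=np.zeros_like(x), trap_separation=D,
        sampling_rate=rate,
    )


def _two_state_chain(rng, n, p_switch, means=(0.0, 5.0), sd=1.0):
    """Symmetric discrete-time two-state chain with Gaussian emissions."""
    states = np.empty(n, int)
    s = 0
    for i in range(n):
        if rng.uniform() < p_switch:
            s = 1 - s
        states[i] = s
    x = np.asarray(means)[states] + rng.standard_normal(n) * sd
    return states, x


class TestMeanFilter:
    def test_hand_example(self):
        tr = _traj([0.0, 2.0, 4.0, 6.0], rate=1000.0)
        out = mean_filter(tr, 2e-3)  # 2-sample boxcar
        assert out.extension == pytest.approx([1.0, 5.0])
        assert out.sampling_rate == 500.0

    def test_identity_window(self):
        tr = _traj(np.arange(10.0))
        out = mean_filter(tr, 1e-3)
        assert np.array_equal(out.extension, tr.extension)

    def test_constant_unchanged(self):
        tr = _traj(np.full(100, 3.3))
        out = mean_filter(tr, 5e-3)
        assert out.extension == pytest.approx(np.full(20, 3.3))

    def test_too_short_window(self):
        tr = _traj(np.arange(10.0))
        with pytest.raises(ValueError):
            mean_filter(tr, 1e-5)


class TestStateCounting:
    def test_single_state(self):
        rng = np.random.default_rng(0)
        tr = _traj(rng.standard_normal(5000) + 700.0)
        fit = fit_extension_histogram(tr, seed=0)
        assert fit.n_components == 1

    def test_degenerate_data(self):
        tr = _traj(np.full(2000, 1.0))
        with pytest.raises(ValueError):
            fit_extension_histogram(tr)

    def test_too_few_samples(self):
        tr = _traj(np.random.default_rng(0).standard_normal(100))
        with pytest.raises(ValueError):
            fit_extension_histogram(tr)

    def test_identical_means_collapse(self):
        # two components drawn at the same mean are unidentifiable and
        # must merge under the separation criterion
        rng = np.random.default_rng(1)
        x = np.concatenate(
            [rng.standard_normal(3000), rng.standard_normal(3000)]
        )
        fit = fit_extension_histogram(_traj(x), seed=1)
        assert fit.n_components == 1

    def test_four_state_wt_trace(self, wt_trace):
        tr, truth = wt_trace
        fit = fit_extension_histogram(mean_filter(tr, 2e-4), seed=0)
        assert fit.n_components == 4
        # recovered means close to the generating state extensions
        # lightly occupied edge states carry a larger position bias
        true_x = truth["state_extensions"]
        assert np.max(np.abs(np.sort(fit.means) - np.sort(true_x))) < 1.5

    def test_weights_sorted_and_normalized(self, wt_trace):
        tr, _ = wt_trace
        fit = fit_extension_histogram(mean_filter(tr, 2e-4), seed=0)
        assert np.all(np.diff(fit.means) > 0)
        assert fit.weights.sum() == pytest.approx(1.0)


class TestFitHmm:
    def test_single_state_matches_sample_stats(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(5000) * 1.5 + 10.0
        res = fit_hmm(_traj(x), 1, seed=0)
        assert res.means[0] == pytest.approx(np.mean(x), abs=1e-6)
        assert res.sds[0] == pytest.approx(np.std(x), rel=1e-3)

    def test_two_state_recovery(self):
        # means 0/5 nm, sd 1 nm, switching 20/s at 5 kHz for 10 s
        rng = np.random.default_rng(3)
        rate, T = 5000.0, 10.0
        p_switch = 20.0 / rate
        states, x = _two_state_chain(rng, int(rate * T), p_switch)
        res = fit_hmm(_traj(x, rate=rate), 2, seed=0)
        assert res.means == pytest.approx([0.0, 5.0], abs=0.1)
        # compare against the rates realized by this particular chain
        dt = 1.0 / rate
        t_in = np.array([np.count_nonzero(states == s) * dt for s in (0, 1)])
        n01 = np.count_nonzero((states[:-1] == 0) & (states[1:] == 1))
        n10 = np.count_nonzero((states[:-1] == 1) & (states[1:] == 0))
        assert res.rate_matrix[0, 1] == pytest.approx(n01 / t_in[0], rel=0.15)
        assert res.rate_matrix[1, 0] == pytest.approx(n10 / t_in[1], rel=0.15)
        assert n01 / t_in[0] == pytest.approx(20.0, rel=0.25)  # sampling noise

    def test_loglik_monotone(self, wt_trace):
        tr, _ = wt_trace
        res = fit_hmm(mean_filter(tr, 2e-4), 4, seed=0)
        hist = res.log_likelihood_history
        assert np.all(np.diff(hist) > -1e-6 * np.abs(hist[:-1]))

    def test_fitted_beats_truth_likelihood(self):
        rng = np.random.default_rng(4)
        rate = 5000.0
        states, x = _two_state_chain(rng, 20000, 20.0 / rate)
        tr = _traj(x, rate=rate)
        res = fit_hmm(tr, 2, seed=0)
        p = 20.0 / rate
        truth = HMMResult(
            n_states=2,
            means=np.array([0.0, 5.0]),
            sds=np.array([1.0, 1.0]),
            transmat=np.array([[1 - p, p], [p, 1 - p]]),
            startprob=np.array([0.5, 0.5]),
            log_likelihood=np.nan,
            log_likelihood_history=np.array([]),
            converged=True,
            sampling_rate=rate,
        )
        from foldscape.trajectory_hmm import _build_model

        truth_logL = _build_model(
            2, truth.means, truth.sds, truth.transmat, truth.startprob
        ).score(x.reshape(-1, 1))
        assert res.log_likelihood >= truth_logL - 1e-6


class TestViterbi:
    def test_single_state_constant_path(self):
        rng = np.random.default_rng(5)
        tr = _traj(rng.standard_normal(500))
        res = fit_hmm(tr, 1, seed=0)
        assert np.all(res.viterbi_path == 0)

    @staticmethod
    def _brute_force(x, means, sds, transmat, startprob):
        n = len(means)
        best_path, best_lp = None, -np.inf
        for path in itertools.product(range(n), repeat=len(x)):
            lp = np.log(startprob[path[0]])
            for a, b in zip(path, path[1:]):
                lp += np.log(transmat[a, b])
            for xi, s in zip(x, path):
                lp += (
                    -0.5 * ((xi - means[s]) / sds[s]) ** 2
                    - np.log(sds[s] * np.sqrt(2 * np.pi))
                )
            if lp > best_lp:
                best_lp, best_path = lp, path
        return np.array(best_path)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(6)
        for trial in range(50):
            n = 3
            means = np.sort(rng.uniform(0, 10, n))
            sds = rng.uniform(0.5, 2.0, n)
            tm = rng.uniform(0.05, 1.0, (n, n))
            tm /= tm.sum(axis=1, keepdims=True)
            sp = rng.uniform(0.05, 1.0, n)
            sp /= sp.sum()
            x = rng.uniform(-2, 12, 10)
            hmm = HMMResult(
                n_states=n, means=means, sds=sds, transmat=tm,
                startprob=sp, log_likelihood=np.nan,
                log_likelihood_history=np.array([]), converged=True,
                sampling_rate=1.0,
            )
            path = viterbi(_traj(x, rate=1.0), hmm)
            brute = self._brute_force(x, means, sds, tm, sp)
            assert np.array_equal(path, brute), f"trial {trial}"


class TestDwellAndRates:
    def test_hand_count(self):
        pops, dwells, rates, visited = dwell_and_rates(
            np.array([0, 0, 1, 1]), 1.0
        )
        assert pops == pytest.approx([0.5, 0.5])
        assert rates[0, 1] == pytest.approx(0.5)  # one jump / 2 s in state 0
        assert visited.all()

    def test_constant_path_flagged(self):
        pops, dwells, rates, visited = dwell_and_rates(
            np.zeros(100, int), 100.0, n_states=2
        )
        assert pops[0] == 1.0
        assert not visited[1]
        assert np.isnan(rates[1, 0])
        assert rates[0, 1] == 0.0
        assert len(dwells[0]) == 0  # single dwell censored at both ends

    def test_exponential_dwell_mean(self):
        # CTMC with 10/s rates both ways: mean dwell 0.1 s
        rng = np.random.default_rng(8)
        rate_hz = 1000.0
        states = []
        s, t = 0, 0.0
        seq = []
        while t < 200.0:
            d = rng.exponential(0.1)
            seq.append((s, t, min(t + d, 200.0)))
            t += d
            s = 1 - s
        path = np.zeros(int(200.0 * rate_hz), int)
        for s, a, b in seq:
            path[int(a * rate_hz) : int(b * rate_hz)] = s
        pops, dwells, rates, _ = dwell_and_rates(path, rate_hz)
        all_dwells = np.concatenate([dwells[0], dwells[1]])
        se = 0.1 / np.sqrt(len(all_dwells))
        assert np.mean(all_dwells) == pytest.approx(0.1, abs=3 * se + 1e-3)


class TestRareBoundStates:
    def _baseline_hmm(self):
        return HMMResult(
            n_states=2, means=np.array([0.0, 5.0]), sds=np.array([1.0, 1.0]),
            transmat=np.eye(2), startprob=np.array([0.5, 0.5]),
            log_likelihood=np.nan, log_likelihood_history=np.array([]),
            converged=True, sampling_rate=1000.0,
        )

    def test_clean_trace_no_intervals(self):
        rng = np.random.default_rng(9)
        states, x = _two_state_chain(rng, 20000, 0.01)
        rep = detect_rare_bound_states(_traj(x), self._baseline_hmm())
        assert rep.intervals == []
        assert np.isnan(rep.mean_dwell)

    def test_short_excursion_not_flagged(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(5000)
        x[1000:1020] = 30.0  # 20 ms < 30 ms minimum
        rep = detect_rare_bound_states(_traj(x), self._baseline_hmm())
        assert rep.intervals == []

    def test_long_excursion_flagged(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(5000)
        x[1000:1060] = 30.0  # 60 ms
        rep = detect_rare_bound_states(_traj(x), self._baseline_hmm())
        assert len(rep.intervals) == 1
        a, b = rep.intervals[0]
        assert a == pytest.approx(1.0, abs=0.01)
        assert rep.mean_dwell == pytest.approx(0.06, abs=0.01)


def test_trajectory_io_roundtrip(tmp_path):
    rng = np.random.default_rng(12)
    tr = Trajectory(
        time=np.arange(100) / 1e4,
        extension=rng.standard_normal(100) + 750.0,
        force=rng.standard_normal(100) * 0.2 + 17.0,
        trap_separation=2820.0,
        sampling_rate=1e4,
        filter_window=1e-4,
    )
    path = tmp_path / "trace.tsv"
    write_trajectory(tr, path)
    back = read_trajectory(path)
    assert back.sampling_rate == tr.sampling_rate
    assert back.trap_separation == tr.trap_separation
    assert back.extension == pytest.approx(tr.extension, abs=1e-3)
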