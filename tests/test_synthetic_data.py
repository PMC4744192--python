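"""Statistical structure of the synthetic instrument: CTMC dwell laws,
stationary occupancies, Gaussian noise, seed reproducibility, ramp
simulations and ligand-bound-state injection."""

import numpy as np
import pytest
from scipy import stats

from foldscape.fixtures import default_tether_config, get_fixture
from foldscape.landscape_model import (
    equilibrium_force,
    predict_states,
    trap_separation_for_force,
)
from foldscape.synthetic_data import (
    BoundStateSpec,
    SimConfig,
    inject_bound_state,
    simulate_fec,
    simulate_trace,
)
from foldscape.trajectory_hmm import dwell_and_rates


@pytest.fixture(scope="module")
def eq_trace(wt, cfg):
    """Long trace at the MD equilibrium where hopping is fastest."""
    _, D = equilibrium_force(wt, cfg, (1, 2))
    sim = SimConfig(
        landscape=wt, tether=cfg, seed=99, duration=60.0, trap_separation=D
    )
    return simulate_trace(sim), D


class TestTraceStatistics:
    def test_seed_reproducibility(self, wt, cfg):
        sim = SimConfig(
            landscape=wt, tether=cfg, seed=5, duration=2.0,
            trap_separation=2824.0,
        )
        a, ta = simulate_trace(sim)
        b, tb = simulate_trace(sim)
        assert np.array_equal(a.extension, b.extension)
        assert np.array_equal(ta["dwell_starts"], tb["dwell_starts"])
        c, _ = simulate_trace(
            SimConfig(
                landscape=wt, tether=cfg, seed=6, duration=2.0,
                trap_separation=2824.0,
            )
        )
        assert not np.array_equal(a.extension, c.extension)

    def test_zero_noise_emits_state_extensions(self, wt, cfg):
        sim = SimConfig(
            landscape=wt, tether=cfg, seed=5, duration=1.0,
            trap_separation=2824.0, noise_sd=0.0,
        )
        tr, truth = simulate_trace(sim)
        allowed = truth["state_extensions"]
        # every decimated sample is a state extension or a boxcar average
        # of two of them across a transition
        ok = np.zeros(len(tr), bool)
        for a in allowed:
            ok |= np.isclose(tr.extension, a, atol=1e-9)
        for a in allowed:
            for b in allowed:
                ok |= np.isclose(tr.extension, 0.5 * (a + b), atol=1e-9)
        assert ok.all()

    def test_stationary_occupancy_matches_boltzmann(self, eq_trace):
        (tr, truth), D = eq_trace
        pops = truth["populations"]
        occ = np.bincount(truth["state_path"], minlength=4) / len(
            truth["state_path"]
        )
        n_dwell = len(truth["dwell_states"])
        se = np.sqrt(pops * (1 - pops) / n_dwell)
        assert np.all(np.abs(occ - pops) < 3 * se + 0.01)

    def test_dwells_exponential(self, eq_trace):
        (tr, truth), D = eq_trace
        states = truth["dwell_states"]
        starts = truth["dwell_starts"]
        dwells = np.diff(starts)
        rates = truth["rate_matrix"].sum(axis=1)
        for s in (1, 2):  # well-populated states
            d = dwells[states[:-1] == s]
            if len(d) < 100:
                continue
            p = stats.kstest(d, "expon", args=(0, 1.0 / rates[s])).pvalue
            assert p > 0.01

    def test_mean_dwell_matches_exit_rate(self, eq_trace):
        (tr, truth), D = eq_trace
        states = truth["dwell_states"]
        dwells = np.diff(truth["dwell_starts"])
        rates = truth["rate_matrix"].sum(axis=1)
        for s in (1, 2):
            d = dwells[states[:-1] == s]
            expect = 1.0 / rates[s]
            se = expect / np.sqrt(len(d))
            assert np.mean(d) == pytest.approx(expect, abs=3 * se)

    def test_noise_is_gaussian_with_configured_sd(self, wt, cfg):
        sim = SimConfig(
            landscape=wt, tether=cfg, seed=17, duration=5.0,
            trap_separation=2824.0,
        )
        tr, truth = simulate_trace(sim)
        # residual about the true state extension, excluding samples whose
        # boxcar window straddles a transition
        x_state = truth["state_extensions"][truth["state_path"]]
        resid = tr.extension - x_state
        # drop samples whose boxcar window straddles a state transition
        path = truth["state_path"]
        steady = np.zeros(len(path), bool)
        steady[1:-1] = (path[1:-1] == path[:-2]) & (path[1:-1] == path[2:])
        resid = resid[steady]
        # raw SD 2.0 at 20 kHz -> sqrt(2) smaller after 2:1 boxcar
        assert np.std(resid) == pytest.approx(2.0 / np.sqrt(2), rel=0.05)
        assert abs(stats.skew(resid)) < 0.05
        assert abs(stats.kurtosis(resid)) < 0.1

    def test_rate_estimates_converge_with_trace_length(self, wt, cfg):
        errs = []
        for T in (5.0, 20.0, 80.0):
            sim = SimConfig(
                landscape=wt, tether=cfg, seed=7, duration=T,
                trap_separation=2827.0,
            )
            tr, truth = simulate_trace(sim)
            pops, dwells, rates, visited = dwell_and_rates(
                truth["state_path"], tr.sampling_rate
            )
            true_r = truth["rate_matrix"]
            # restrict to rates whose source-state dwells are resolvable
            # at the output sampling rate (others carry a fixed
            # discretization bias, not a statistical one)
            resolvable = true_r.sum(axis=1) < 600.0
            sel = (
                (true_r > 1.0)
                & np.isfinite(rates)
                & (rates > 0)
                & resolvable[:, None]
            )
            errs.append(
                np.nanmean(np.abs(np.log(rates[sel] / true_r[sel])))
            )
        assert errs[2] < errs[0]


class TestSequentiality:
    def test_no_skip_transitions_in_idealized_data(self, wt_trace):
        """Non-sequential (state-skipping) transitions are over two orders
        of magnitude rarer than sequential ones in the idealized record,
        the zipper-like signature of sequential assembly."""
        tr, truth = wt_trace
        path = truth["state_path"]
        jumps = np.abs(np.diff(path))
        seq = np.count_nonzero(jumps == 1)
        skip = np.count_nonzero(jumps > 1)
        assert seq > 1000
        assert skip < 0.01 * seq

    def test_skip_flux_option(self, wt, cfg):
        pred = predict_states(wt, 2827.0, cfg, include_skip=True)
        # through-flux skip rates exist but are slower than sequential
        assert pred.rates[0, 2] < pred.rates[0, 1]
        assert pred.rates[3, 1] < pred.rates[3, 2]


class TestBoundStateInjection:
    def test_zero_on_rate_is_identity(self, wt, cfg):
        sim = SimConfig(
            landscape=wt, tether=cfg, seed=21, duration=2.0,
            trap_separation=2824.0,
        )
        tr, truth = simulate_trace(sim)
        spec = BoundStateSpec(
            target_state=1, extension_shift=-2.3, on_rate=0.0, mean_dwell=2.8
        )
        out, t2 = inject_bound_state(tr, truth, spec, seed=1)
        assert np.array_equal(out.extension, tr.extension)
        assert t2["bound_intervals"] == []

    def test_poisson_event_count_and_dwell(self, wt, cfg):
        sim = SimConfig(
            landscape=wt, tether=cfg, seed=22, duration=400.0,
            trap_separation=2824.0,
        )
        tr, truth = simulate_trace(sim)
        spec = BoundStateSpec(
            target_state=1, extension_shift=-2.3, on_rate=0.05,
            mean_dwell=2.8,
        )
        out, t2 = inject_bound_state(tr, truth, spec, seed=2)
        n = len(t2["bound_intervals"])
        lam = 0.05 * 400.0  # = 20 expected arrivals (some merge)
        assert stats.poisson.ppf(0.025, lam) - 3 <= n <= stats.poisson.ppf(
            0.975, lam
        )
        dwells = np.array([b - a for a, b in t2["bound_intervals"]])
        se = 2.8 / np.sqrt(len(dwells))
        assert np.mean(dwells) == pytest.approx(2.8, abs=3 * se + 0.3)

    def test_detector_recovers_injection(self, wt, cfg):
        from foldscape.trajectory_hmm import (
            detect_rare_bound_states,
            fit_hmm,
            mean_filter,
        )

        sim = SimConfig(
            landscape=wt, tether=cfg, seed=23, duration=300.0,
            trap_separation=2824.0,
        )
        tr, truth = simulate_trace(sim)
        spec = BoundStateSpec(
            target_state=3, extension_shift=-25.0, on_rate=0.03,
            mean_dwell=2.8,
        )
        out, t2 = inject_bound_state(tr, truth, spec, seed=3)
        # baseline states fitted on the ligand-free record
        baseline = fit_hmm(
            mean_filter(tr, 1e-3), 4,
            init_means=truth["state_extensions"], seed=0, decode=False,
        )
        rep = detect_rare_bound_states(mean_filter(out, 1e-3), baseline)
        true_n = len(t2["bound_intervals"])
        true_dwell = np.mean([b - a for a, b in t2["bound_intervals"]])
        assert rep.occurrence_rate == pytest.approx(
            true_n / out.duration, rel=0.5
        )
        assert rep.mean_dwell == pytest.approx(true_dwell, rel=0.5)


class TestFecSimulation:
    def test_flicker_centred_at_equilibrium_force(self, wt, cfg):
        f_eq, D_eq = equilibrium_force(wt, cfg, (0, 1))
        lo = D_eq - 30.0
        hi = D_eq + 30.0
        sim = SimConfig(
            landscape=wt, tether=cfg, seed=31, ramp_range=(lo, hi),
        )
        fecs, truth = simulate_fec(sim)
        forces = [
            t["force"]
            for t in truth["transitions"]
            if {t["from_state"], t["to_state"]} == {0, 1}
        ]
        assert len(forces) > 50
        assert np.median(forces) == pytest.approx(f_eq, abs=1.0)

    def test_absorbing_state_blocks_reassembly(self, cfg):
        ls = get_fixture("wt_pull")
        lo = trap_separation_for_force(ls, cfg, 5.0)
        hi = trap_separation_for_force(ls, cfg, 27.0)
        sim = SimConfig(
            landscape=ls, tether=cfg, seed=32, ramp_range=(lo, hi),
            absorbing_states=(4,),
        )
        fecs, truth = simulate_fec(sim)
        pull, relax = fecs
        rip = [t for t in truth["transitions"] if t["to_state"] == 4]
        assert len(rip) == 1
        # nothing happens after full disassembly: the relax phase shows no
        # reassembly transitions
        after = [t for t in truth["transitions"] if t["time"] > rip[0]["time"]]
        assert after == []

    def test_fec_seed_reproducibility(self, wt, cfg):
        sim = SimConfig(
            landscape=wt, tether=cfg, seed=33, ramp_range=(2800.0, 2840.0),
        )
        a, ta = simulate_fec(sim)
        b, tb = simulate_fec(sim)
        assert np.array_equal(a[0].extension, b[0].extension)
        assert ta["transitions"] == tb["transitions"]
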