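"""Synthetic instrument: trajectories and force-extension curves simulated
from an energy landscape.

The generator replaces the optical-tweezers hardware so that every stage of
the analysis can be validated by parameter recovery.  Constant-trap-
separation traces are continuous-time Markov (Gillespie) hopping among the
stable states with rates from the landscape model, emitted at the
acquisition rate with white Gaussian measurement noise and an online boxcar
filter.  Force–extension curves are simulated by following the current
state's elastic branch while the trap separation ramps at constant speed,
with stochastic transitions generated by thinning of the time-inhomogeneous
rates.  Rare long-dwell ligand-bound states can be injected as a Poisson
process that freezes the chain in a target state with a shifted extension.

The measured force co-fluctuates with the measured extension at fixed trap
separation (D = X + F/k_traps + R), so emitted force noise is
-k_traps times the extension noise about the state force.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .landscape_model import EnergyLandscape, predict_states
from .tether_mechanics import TetherConfig
from .trajectory_hmm import Trajectory

__all__ = [
    "SimConfig",
    "BoundStateSpec",
    "FEC",
    "simulate_trace",
    "simulate_fec",
    "inject_bound_state",
]

#: Raw acquisition rate (Hz) and the rate stored after the online filter.
DEFAULT_ACQUISITION_HZ = 20_000.0
DEFAULT_OUTPUT_HZ = 10_000.0

#: White-noise SD per raw 20 kHz sample (nm); equals 1.0 nm at an effective
#: 5 kHz analysis bandwidth after boxcar averaging.
DEFAULT_NOISE_SD = 2.0


@dataclass(frozen=True)
class BoundStateSpec:
    """Rare ligand-bound state: Poisson arrivals at ``on_rate`` freeze the
    chain in ``target_state`` (stable-state index) with the extension mean
    shifted by ``extension_shift`` nm (negative = shortening) for an
    exponential dwell of mean ``mean_dwell`` s."""

    target_state: int
    extension_shift: float  # nm
    on_rate: float  # 1/s
    mean_dwell: float  # s


@dataclass(frozen=True)
class SimConfig:
    landscape: EnergyLandscape
    tether: TetherConfig
    seed: int
    duration: float = 20.0  # s
    trap_separation: float | None = None  # nm (constant-D trace)
    ramp_range: tuple[float, float] | None = None  # nm (FEC)
    ramp_speed: float = 10.0  # nm/s
    sampling_rate: float = DEFAULT_ACQUISITION_HZ  # Hz, raw acquisition
    output_rate: float = DEFAULT_OUTPUT_HZ  # Hz, after online filter
    noise_sd: float | np.ndarray = DEFAULT_NOISE_SD  # nm per raw sample
    bound_state: BoundStateSpec | None = None
    absorbing_states: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for every stochastic run")
        if np.any(np.asarray(self.noise_sd) < 0):
            raise ValueError("noise SD must be >= 0 nm")
        if self.sampling_rate % self.output_rate:
            raise ValueError("sampling_rate must be a multiple of output_rate")


@dataclass
class FEC:
    """Force–extension curve of one pulling or relaxation phase."""

    phase: str  # "pull" | "relax"
    time: np.ndarray  # s
    force: np.ndarray  # pN
    extension: np.ndarray  # nm
    trap_separation: np.ndarray  # nm
    trap_speed: float  # nm/s
    sampling_rate: float  # Hz


def _per_state_noise(sim: SimConfig, n_states: int) -> np.ndarray:
    sd = np.asarray(sim.noise_sd, float)
    if sd.ndim == 0:
        return np.full(n_states, float(sd))
    if len(sd) != n_states:
        raise ValueError("per-state noise SD length must match state count")
    return sd


def _gillespie(rates: np.ndarray, duration: float, rng, start: int,
               absorbing=()) -> tuple[np.ndarray, np.ndarray]:
    """Dwell sequence of a CTMC with constant rate matrix: returns
    (state ids, dwell start times); last dwell runs to ``duration``."""
    exit_rates = rates.sum(axis=1)
    if np.any(exit_rates > 1e9):
        raise RuntimeError(
            "transition rates overflow the simulable range (barrierless "
            "landscape?); use a larger barrier"
        )
    states = [start]
    times = [0.0]
    t, s = 0.0, start
    while True:
        if s in absorbing or exit_rates[s] == 0:
            break
        t += rng.exponential(1.0 / exit_rates[s])
        if t >= duration:
            break
        s = rng.choice(len(exit_rates), p=rates[s] / exit_rates[s])
        states.append(s)
        times.append(t)
    return np.array(states, int), np.array(times, float)


def simulate_trace(sim: SimConfig) -> tuple[Trajectory, dict]:
    """Simulate a constant-trap-separation extension-time trace.

    Returns (trajectory, truth) where truth holds the generating dwell
    sequence, per-sample true state path at the output rate, state
    extensions/forces and the rate matrix used.
    """
    if sim.trap_separation is None:
        raise ValueError("constant-D simulation requires trap_separation")
    rng = np.random.default_rng(sim.seed)
    pred = predict_states(sim.landscape, sim.trap_separation, sim.tether)
    n = len(pred.populations)
    start = int(rng.choice(n, p=pred.populations))
    states, times = _gillespie(
        pred.rates, sim.duration, rng, start, sim.absorbing_states
    )

    n_raw = int(round(sim.duration * sim.sampling_rate))
    t_raw = np.arange(n_raw) / sim.sampling_rate
    idx = np.searchsorted(times, t_raw, side="right") - 1
    state_path_raw = states[idx]

    sds = _per_state_noise(sim, n)
    noise = rng.standard_normal(n_raw) * sds[state_path_raw]
    ext_raw = pred.extensions[state_path_raw] + noise
    force_raw = (
        pred.forces[state_path_raw] - sim.tether.trap_stiffness * noise
    )

    dec = int(sim.sampling_rate // sim.output_rate)
    m = n_raw // dec

    def box(a):
        return a[: m * dec].reshape(m, dec).mean(axis=1)

    tr = Trajectory(
        time=box(t_raw),
        extension=box(ext_raw),
        force=box(force_raw),
        trap_separation=sim.trap_separation,
        sampling_rate=sim.output_rate,
        filter_window=dec / sim.sampling_rate,
    )
    truth = {
        "dwell_states": states,
        "dwell_starts": times,
        "state_path": state_path_raw[: m * dec : dec],
        "state_extensions": pred.extensions,
        "state_forces": pred.forces,
        "rate_matrix": pred.rates,
        "populations": pred.populations,
        "trap_separation": sim.trap_separation,
    }
    return tr, truth


def inject_bound_state(
    tr: Trajectory, truth: dict, spec: BoundStateSpec, seed: int,
    noise_sd: float | None = None,
) -> tuple[Trajectory, dict]:
    """Overlay rare ligand-bound intervals on a simulated trace.

    Arrivals are Poisson at ``spec.on_rate``; each bound interval freezes
    the chain in ``spec.target_state`` with the extension mean shifted by
    ``spec.extension_shift`` and an exponential dwell of mean
    ``spec.mean_dwell``.  Overlapping intervals are merged and counted
    once.  Returns a new trajectory and truth with 'bound_intervals'.
    """
    rng = np.random.default_rng(seed)
    duration = tr.duration
    n_events = rng.poisson(spec.on_rate * duration)
    starts = np.sort(rng.uniform(0.0, duration, n_events))
    dwells = rng.exponential(spec.mean_dwell, n_events)
    intervals: list[tuple[float, float]] = []
    for s, d in zip(starts, dwells):
        e = min(s + d, duration)
        if intervals and s <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], e))
        else:
            intervals.append((s, e))

    ext = tr.extension.copy()
    force = tr.force.copy()
    if noise_sd is None:
        noise_sd = DEFAULT_NOISE_SD / np.sqrt(
            DEFAULT_ACQUISITION_HZ / tr.sampling_rate
        )
    x_bound = (
        truth["state_extensions"][spec.target_state] + spec.extension_shift
    )
    f_bound = truth["state_forces"][spec.target_state]
    for s, e in intervals:
        a, b = int(s * tr.sampling_rate), int(e * tr.sampling_rate)
        nz = rng.standard_normal(b - a) * noise_sd
        ext[a:b] = x_bound + nz
        force[a:b] = f_bound
    new_truth = dict(truth)
    new_truth["bound_intervals"] = intervals
    return replace(tr, extension=ext, force=force), new_truth


# ---------------------------------------------------------------------------
# Force ramp (FEC) simulation


def _state_tables(ls, cfg, D_grid):
    """Per-state force/extension/energy interpolation tables over D."""
    preds = [predict_states(ls, D, cfg) for D in D_grid]
    F = np.array([p.forces for p in preds])
    X = np.array([p.extensions for p in preds])
    R = np.array([p.rates for p in preds])
    return F, X, R


def simulate_fec(sim: SimConfig) -> tuple[list[FEC], dict]:
    """Simulate a pull phase followed by a relax phase at constant trap
    speed, with stochastic state transitions (thinning of the
    time-inhomogeneous rates, evaluated by interpolation over a trap-
    separation grid).  Returns ([pull FEC, relax FEC], truth) where truth
    lists every transition (time, D, force, from, to)."""
    if sim.ramp_range is None:
        raise ValueError("FEC simulation requires ramp_range")
    rng = np.random.default_rng(sim.seed)
    D_lo, D_hi = sim.ramp_range
    if D_hi <= D_lo:
        raise ValueError("ramp_range must satisfy D_lo < D_hi")
    ls, cfg = sim.landscape, sim.tether
    n = len(ls.stable_states)

    grid = np.linspace(D_lo, D_hi, max(int((D_hi - D_lo) / 0.5), 2))
    Ftab, Xtab, Rtab = _state_tables(ls, cfg, grid)
    lam_max = Rtab.sum(axis=2).max(axis=0)  # per-state rate majorant

    dt = 1.0 / sim.sampling_rate
    phase_T = (D_hi - D_lo) / sim.ramp_speed
    exit_tab = Rtab.sum(axis=2)  # (grid, state) total exit rate
    fecs = []
    transitions = []
    # start in the lowest-l (most folded) state at D_lo
    state = 0
    t_global = 0.0
    window = 0.05  # s; local-majorant window for the thinning proposals
    for phase, sign, D0 in (("pull", 1.0, D_lo), ("relax", -1.0, D_hi)):
        n_samp = int(phase_T * sim.sampling_rate)
        t_loc = np.arange(n_samp) * dt
        D_t = D0 + sign * sim.ramp_speed * t_loc
        dwell_states = [state]
        dwell_starts = [0.0]
        t = 0.0
        while t < phase_T:
            if state in sim.absorbing_states:
                break
            # local rate majorant over the next window of the ramp
            D_a = D0 + sign * sim.ramp_speed * t
            D_b = D0 + sign * sim.ramp_speed * min(t + window, phase_T)
            lo_i, hi_i = np.searchsorted(grid, sorted((D_a, D_b)))
            lam = float(
                exit_tab[max(lo_i - 1, 0) : hi_i + 1, state].max()
            )
            if lam <= 0:
                break
            w = rng.exponential(1.0 / lam)
            if w > window:
                t += window
                continue
            t += w
            if t >= phase_T:
                break
            D_now = D0 + sign * sim.ramp_speed * t
            rates_now = np.array(
                [np.interp(D_now, grid, Rtab[:, state, k]) for k in range(n)]
            )
            tot = rates_now.sum()
            if tot > 0 and rng.uniform() < tot / lam:
                new = int(rng.choice(n, p=rates_now / tot))
                transitions.append(
                    {
                        "time": t_global + t,
                        "trap_separation": float(D_now),
                        "force": float(np.interp(D_now, grid, Ftab[:, state])),
                        "from_state": int(state),
                        "to_state": new,
                    }
                )
                state = new
                dwell_states.append(state)
                dwell_starts.append(t)
        idx = np.searchsorted(np.array(dwell_starts), t_loc, side="right") - 1
        state_path = np.array(dwell_states, int)[idx]
        x_state = np.empty(n_samp)
        f_state = np.empty(n_samp)
        for s in range(n):
            mask = state_path == s
            if np.any(mask):
                x_state[mask] = np.interp(D_t[mask], grid, Xtab[:, s])
                f_state[mask] = np.interp(D_t[mask], grid, Ftab[:, s])
        sds = _per_state_noise(sim, n)
        noise = rng.standard_normal(n_samp) * sds[state_path]
        dec = int(sim.sampling_rate // sim.output_rate)
        m = n_samp // dec

        def box(a):
            return a[: m * dec].reshape(m, dec).mean(axis=1)

        fecs.append(
            FEC(
                phase=phase,
                time=box(t_loc) + t_global,
                force=box(f_state - cfg.trap_stiffness * noise),
                extension=box(x_state + noise),
                trap_separation=box(D_t),
                trap_speed=sign * sim.ramp_speed,
                sampling_rate=sim.output_rate,
            )
        )
        t_global += phase_T
    truth = {
        "transitions": transitions,
        "grid": grid,
        "state_forces": Ftab,
        "state_extensions": Xtab,
    }
    return fecs, truth
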