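"""Simultaneous nonlinear least-squares inference of the energy landscape.

The measured per-trap-separation observables — state forces, populations,
transition rates and extension changes from HMM-idealized trajectories —
are fit jointly by the landscape forward model to recover the states'
contour lengths l_i and zero-force free energies V_i, from which the
domain folding energies (differences of V between named stable states)
and barriers follow.

Conventions: rates enter the loss as log-rates (their dynamic range spans
decades); every residual is scaled by the observation's uncertainty;
the gauge is fixed by V = 0 for the most-folded stable state; the folded
core size h is tied to l through the packaged h(l) table; the Kramers
attempt frequency is a fixed input, not a fitted parameter (a uniform
shift of all transition-state V and a rescaling of the prefactor are
exactly degenerate given populations and rates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, linear_sum_assignment

from .fixtures import h_of_l
from .landscape_model import (
    EnergyLandscape,
    LandscapeState,
)
from .tether_mechanics import TetherConfig, solve_states_vectorized
from .trajectory_hmm import (
    HMMResult,
    Trajectory,
    fit_extension_histogram,
    fit_hmm,
    mean_filter,
)

__all__ = [
    "DRecord",
    "ObservationSet",
    "FitResult",
    "idealize_dataset",
    "assemble_observations",
    "fit_landscape",
    "initial_landscape_from_observations",
    "total_zipping_energy",
    "compare_landscapes",
]


@dataclass
class DRecord:
    """Observables measured at one trap separation (NaN = not observed)."""

    trap_separation: float
    forces: np.ndarray  # pN per state
    forces_sd: np.ndarray
    populations: np.ndarray
    populations_sd: np.ndarray
    log_rates: np.ndarray  # ln(1/s), matrix, NaN where unobserved
    log_rates_sd: np.ndarray
    extension_gaps: np.ndarray  # nm, adjacent-state extension changes
    extension_gaps_sd: np.ndarray
    weight: float = 1.0


@dataclass
class ObservationSet:
    n_states: int
    records: list
    domain_names: tuple = ()  # name per adjacent stable pair, low l first

    def __post_init__(self) -> None:
        if not self.domain_names:
            self.domain_names = tuple(
                f"pair{i}" for i in range(self.n_states - 1)
            )


@dataclass
class FitResult:
    landscape: EnergyLandscape
    domain_energies: dict  # name -> kBT (V difference across the pair)
    domain_energies_sd: dict
    barriers: dict  # name -> kBT above the higher-l (unfolded) state
    barriers_sd: dict
    cost: float
    residuals: np.ndarray
    n_observations: int
    param_sd: np.ndarray | None = None
    converged: bool = True


# ---------------------------------------------------------------------------
# Trajectory idealization with a consistent state ladder across separations


def _contour_of_component(
    X_c: float, D: float, cfg: TetherConfig, h_table
) -> float:
    """Invert the tether model: contour length whose state extension at
    trap separation D equals X_c.  The contour length is the trace-
    independent reaction coordinate, so it anchors state identity across
    trap separations."""
    from scipy.optimize import brentq
    from .tether_mechanics import (
        _fjc_extension_arr,
        _wlc_extension_given_L,
        wlc_extension,
    )

    kBT = cfg.kBT
    F_c = cfg.trap_stiffness * (D - cfg.bead_radii_sum - X_c)
    if F_c <= 0.1:
        return 0.1
    x_dna = wlc_extension(F_c, cfg.handle, kBT)

    def gap(l):
        x_m = _wlc_extension_given_L(
            np.array(F_c), np.array(l), cfg.polypeptide_persistence, kBT
        )
        H = _fjc_extension_arr(np.array(F_c), np.array(float(h_table(l))), kBT)
        return float(x_m + H + x_dna - X_c)

    lo, hi = 0.0, 200.0
    if gap(lo) >= 0:
        return 0.1
    if gap(hi) <= 0:
        return hi
    return brentq(gap, lo, hi, xtol=1e-6)


def _cluster_contours(
    values: np.ndarray, weights: np.ndarray, k: int, tol: float = 3.0
) -> np.ndarray:
    """Cluster pooled per-component contour lengths into at most k state
    positions.

    Adjacent folding states are far apart on the contour coordinate
    (several nm) compared with the per-component estimation noise
    (sub-nm), so a greedy merge of sorted values within ``tol`` nm
    separates states cleanly regardless of how unevenly occupancy is
    distributed across traces; if more than k clusters emerge (mixture
    components bridging two states), the k heaviest are kept."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    centers: list[float] = []
    masses: list[float] = []
    for x, wx in zip(v, w):
        if centers and x - centers[-1] <= tol:
            m = masses[-1] + wx
            centers[-1] = (centers[-1] * masses[-1] + x * wx) / m
            masses[-1] = m
        else:
            centers.append(float(x))
            masses.append(float(wx))
    centers = np.array(centers)
    masses = np.array(masses)
    if len(centers) > k:
        keep = np.sort(np.argsort(masses)[-k:])
        centers = centers[keep]
    return centers


def idealize_dataset(
    traces: list[Trajectory],
    n_states: int,
    cfg: TetherConfig,
    filter_window: float = 2e-4,
    seed: int = 0,
    max_gmm_samples: int = 40_000,
    h_table=h_of_l,
    min_slot_occupancy: float = 1e-3,
) -> list[tuple[Trajectory, HMMResult]]:
    """Mean-filter and HMM-idealize a set of constant-D traces with a
    shared state identity.

    State identity across trap separations is anchored in contour-length
    space: every Gaussian-mixture component of every trace is converted to
    an unfolded contour length by inverting the tether model (the contour
    length of a folding state does not depend on D), the pooled l values
    are clustered into ``n_states`` consensus states, and each trace's HMM
    is initialized at the model-predicted extensions of those consensus
    states.  Slots with negligible occupancy in a trace are excluded from
    that trace's HMM and reported as unvisited.
    """
    filtered = [mean_filter(tr, filter_window) for tr in traces]
    comp_l, comp_w = [], []
    for tr in filtered:
        gmfit = fit_extension_histogram(
            tr,
            n_range=range(1, n_states + 3),
            seed=seed,
            max_samples=max_gmm_samples,
            min_separation_sd=1.5,
        )
        for mu, w in zip(gmfit.means, gmfit.weights):
            comp_l.append(
                _contour_of_component(mu, tr.trap_separation, cfg, h_table)
            )
            comp_w.append(w)
    centers = _cluster_contours(
        np.array(comp_l), np.array(comp_w), n_states
    )
    if len(centers) < n_states:
        raise RuntimeError(
            f"only {len(centers)} distinct states resolved across the "
            f"dataset; cannot idealize with n_states={n_states}"
        )

    from .tether_mechanics import solve_states_vectorized

    out = []
    h_centers = np.array([float(h_table(l)) for l in centers])
    for tr in filtered:
        sol = solve_states_vectorized(
            tr.trap_separation, centers, h_centers, cfg
        )
        slot_X = sol["extension"]
        occ = np.bincount(
            np.argmin(
                np.abs(tr.extension[:, None] - slot_X[None, :]), axis=1
            ),
            minlength=n_states,
        ) / len(tr.extension)
        active = np.flatnonzero(occ >= min_slot_occupancy)
        res_a = fit_hmm(
            tr, len(active), init_means=slot_X[active], seed=seed
        )
        # fitted states -> active slots by nearest mean (global assignment)
        cost_m = np.abs(res_a.means[:, None] - slot_X[active][None, :])
        row, col = linear_sum_assignment(cost_m)
        perm = np.empty(len(active), int)
        perm[col] = row
        res_a = _permute_hmm(res_a, perm)
        out.append((tr, _expand_hmm(res_a, active, n_states)))
    return out


def _expand_hmm(res: HMMResult, active: np.ndarray, n_states: int) -> HMMResult:
    """Embed an HMM fitted on a subset of state slots into the full slot
    space; inactive slots get zero population and NaN parameters."""
    if len(active) == n_states:
        return res
    means = np.full(n_states, np.nan)
    sds = np.full(n_states, np.nan)
    transmat = np.full((n_states, n_states), np.nan)
    startprob = np.zeros(n_states)
    pops = np.zeros(n_states)
    mean_dwell = np.full(n_states, np.nan)
    rates = np.full((n_states, n_states), np.nan)
    visited = np.zeros(n_states, bool)
    dwells = [np.array([]) for _ in range(n_states)]
    means[active] = res.means
    sds[active] = res.sds
    transmat[np.ix_(active, active)] = res.transmat
    startprob[active] = res.startprob
    pops[active] = res.populations
    mean_dwell[active] = res.mean_dwell
    rates[np.ix_(active, active)] = res.rate_matrix
    visited[active] = res.visited
    for slot, d in zip(active, res.dwell_times):
        dwells[slot] = d
    path = active[res.viterbi_path] if res.viterbi_path is not None else None
    return HMMResult(
        n_states=n_states,
        means=means,
        sds=sds,
        transmat=transmat,
        startprob=startprob,
        log_likelihood=res.log_likelihood,
        log_likelihood_history=res.log_likelihood_history,
        converged=res.converged,
        sampling_rate=res.sampling_rate,
        viterbi_path=path,
        populations=pops,
        dwell_times=dwells,
        mean_dwell=mean_dwell,
        rate_matrix=rates,
        visited=visited,
    )


def _permute_hmm(res: HMMResult, perm: np.ndarray) -> HMMResult:
    """Reorder HMM states so index == ladder slot."""
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    return HMMResult(
        n_states=res.n_states,
        means=res.means[perm],
        sds=res.sds[perm],
        transmat=res.transmat[np.ix_(perm, perm)],
        startprob=res.startprob[perm],
        log_likelihood=res.log_likelihood,
        log_likelihood_history=res.log_likelihood_history,
        converged=res.converged,
        sampling_rate=res.sampling_rate,
        viterbi_path=(
            inv[res.viterbi_path] if res.viterbi_path is not None else None
        ),
        populations=res.populations[perm],
        dwell_times=[res.dwell_times[p] for p in perm],
        mean_dwell=res.mean_dwell[perm],
        rate_matrix=res.rate_matrix[np.ix_(perm, perm)],
        visited=res.visited[perm],
    )


def assemble_observations(
    idealized: list[tuple[Trajectory, HMMResult]],
    domain_names: tuple = (),
    min_population: float = 2e-3,
    min_population_means: float = 0.08,
    min_transitions: int = 5,
    min_dwell_samples: float = 8.0,
    force_sd_floor: float = 0.1,
    population_sd_floor: float = 0.005,
    gap_sd_floor: float = 0.1,
) -> ObservationSet:
    """Merge idealized trajectories into one weighted observation set.

    Per trace: per-state mean forces (from the force channel over the
    Viterbi assignment), occupancies, adjacent-state extension changes and
    log transition rates.  Rates are kept only when backed by at least
    ``min_transitions`` events and a mean dwell of ``min_dwell_samples``
    samples (shorter dwells are severely undercounted at finite
    bandwidth).  Mean-based observables (state forces, extension changes)
    additionally require an occupancy of ``min_population_means``: the
    fitted emission mean of a nearly-empty state is pulled toward its
    heavily-populated neighbour and would enter the fit as a precisely
    wrong number.  Records sharing a trap separation are pooled rather
    than double-weighted.
    """
    if len(idealized) < 3:
        raise ValueError(
            "need >= 3 trap separations spanning the transition region"
        )
    n_states = idealized[0][1].n_states
    n_seen = np.zeros(n_states)
    records = []
    for tr, res in idealized:
        path = res.viterbi_path
        pops = res.populations
        n_dwell_tot = max(
            sum(len(d) for d in res.dwell_times), 1
        )
        forces = np.full(n_states, np.nan)
        forces_sd = np.full(n_states, np.nan)
        pops_sd = np.full(n_states, np.nan)
        observed = np.zeros(n_states, bool)
        for s in range(n_states):
            sel = path == s
            if pops[s] < min_population or not np.any(sel):
                continue
            n_seen[s] += 1
            observed[s] = True
            pops_sd[s] = max(
                np.sqrt(pops[s] * (1 - pops[s]) / n_dwell_tot),
                population_sd_floor,
            )
            if pops[s] < min_population_means:
                continue
            forces[s] = np.mean(tr.force[sel])
            n_eff = max(len(res.dwell_times[s]), 1)
            forces_sd[s] = max(
                np.std(tr.force[sel]) / np.sqrt(n_eff), force_sd_floor
            )
        pops_obs = np.where(observed, pops, np.nan)

        log_rates = np.full((n_states, n_states), np.nan)
        log_rates_sd = np.full((n_states, n_states), np.nan)
        dt = 1.0 / res.sampling_rate
        time_in = pops * len(path) * dt
        for i in range(n_states):
            if not observed[i]:
                continue
            if res.mean_dwell[i] < min_dwell_samples * dt:
                continue  # missed-event regime
            for j in (i - 1, i + 1):
                if not (0 <= j < n_states):
                    continue
                r = res.rate_matrix[i, j]
                if not np.isfinite(r) or r <= 0:
                    continue
                n_ij = r * time_in[i]
                if n_ij < min_transitions:
                    continue
                log_rates[i, j] = np.log(r)
                log_rates_sd[i, j] = 1.0 / np.sqrt(n_ij)

        # state positions for extension changes: medians of the Viterbi-
        # assigned samples resist the one-sided contamination from samples
        # bridging a transition inside one filter window
        gaps = np.full(n_states - 1, np.nan)
        gaps_sd = np.full(n_states - 1, np.nan)
        medians = np.full(n_states, np.nan)
        for s in range(n_states):
            if not np.isnan(forces[s]):
                medians[s] = np.median(tr.extension[path == s])
        for i in range(n_states - 1):
            if np.isnan(medians[i]) or np.isnan(medians[i + 1]):
                continue
            gaps[i] = medians[i + 1] - medians[i]
            n_i = np.count_nonzero(path == i)
            n_j = np.count_nonzero(path == i + 1)
            gaps_sd[i] = max(
                1.25
                * np.sqrt(res.sds[i] ** 2 / n_i + res.sds[i + 1] ** 2 / n_j),
                gap_sd_floor,
            )
        records.append(
            DRecord(
                trap_separation=tr.trap_separation,
                forces=forces,
                forces_sd=forces_sd,
                populations=pops_obs,
                populations_sd=pops_sd,
                log_rates=log_rates,
                log_rates_sd=log_rates_sd,
                extension_gaps=gaps,
                extension_gaps_sd=gaps_sd,
            )
        )
    if np.count_nonzero(n_seen > 0) < 2:
        raise ValueError("fewer than 2 states observed across the dataset")

    # pool duplicated trap separations (inverse-variance weighting)
    pooled: dict = {}
    for rec in records:
        key = round(rec.trap_separation, 6)
        if key not in pooled:
            pooled[key] = rec
        else:
            pooled[key] = _pool_records(pooled[key], rec)
    return ObservationSet(
        n_states=n_states,
        records=sorted(pooled.values(), key=lambda r: r.trap_separation),
        domain_names=domain_names,
    )


def _pool_records(a: DRecord, b: DRecord) -> DRecord:
    def ivw(xa, sa, xb, sb):
        wa, wb = 1.0 / sa**2, 1.0 / sb**2
        x = np.where(
            np.isnan(xa), xb,
            np.where(np.isnan(xb), xa, (xa * wa + xb * wb) / (wa + wb)),
        )
        s = np.where(
            np.isnan(sa), sb,
            np.where(np.isnan(sb), sa, np.sqrt(1.0 / (wa + wb))),
        )
        return x, s

    with np.errstate(invalid="ignore", divide="ignore"):
        f, fs = ivw(a.forces, a.forces_sd, b.forces, b.forces_sd)
        p, ps = ivw(a.populations, a.populations_sd, b.populations, b.populations_sd)
        r, rs = ivw(a.log_rates, a.log_rates_sd, b.log_rates, b.log_rates_sd)
        g, gs = ivw(a.extension_gaps, a.extension_gaps_sd, b.extension_gaps, b.extension_gaps_sd)
    return DRecord(a.trap_separation, f, fs, p, ps, r, rs, g, gs)


# ---------------------------------------------------------------------------
# Forward model on a grid (vectorized across trap separations)


def _build_landscape(
    params: np.ndarray, n_states: int, attempt_frequency: float, h_table
) -> EnergyLandscape:
    """Parameter vector -> landscape.

    params = [l0, gaps (n-1), V (n-1, cumulative from 0),
              ts fractions (n-1), barrier offsets (n-1)]
    with V_ts(pair) = max(V_i, V_j) + barrier_offset.
    """
    n = n_states
    l0 = params[0]
    gaps = params[1 : n]
    V = np.concatenate(([0.0], params[n : 2 * n - 1]))
    fracs = params[2 * n - 1 : 3 * n - 2]
    offs = params[3 * n - 2 : 4 * n - 3]
    ls = np.concatenate(([l0], l0 + np.cumsum(gaps)))
    states = []
    for i in range(n):
        states.append(
            LandscapeState(
                "stable", ls[i], V[i], float(h_table(ls[i])), f"S{i}"
            )
        )
    for i in range(n - 1):
        tl = ls[i] + fracs[i] * gaps[i]
        tv = max(V[i], V[i + 1]) + offs[i]
        states.append(
            LandscapeState(
                "transition", tl, tv, float(h_table(tl)), f"TS{i}"
            )
        )
    return EnergyLandscape(
        tuple(sorted(states, key=lambda s: s.l)),
        attempt_frequency=attempt_frequency,
    )


def _predict_grid(ls: EnergyLandscape, D_arr: np.ndarray, cfg: TetherConfig):
    """Vectorized forward model: forces, populations, log-rates and
    extension gaps for all stable states at every trap separation."""
    all_states = ls.states
    l_arr = np.array([s.l for s in all_states])
    h_arr = np.array([s.h for s in all_states])
    V_arr = np.array([s.V for s in all_states])
    sol = solve_states_vectorized(
        D_arr[:, None], l_arr[None, :], h_arr[None, :], cfg
    )
    G = sol["g_m"] + V_arr[None, :] + sol["g_dna"] + sol["g_beads"]
    stable_idx = [k for k, s in enumerate(all_states) if s.kind == "stable"]
    ts_idx = [k for k, s in enumerate(all_states) if s.kind == "transition"]
    Gs = G[:, stable_idx]
    Gt = G[:, ts_idx]
    F = sol["force"][:, stable_idx]
    X = sol["extension"][:, stable_idx]
    w = np.exp(-(Gs - Gs.min(axis=1, keepdims=True)))
    pops = w / w.sum(axis=1, keepdims=True)
    lnA = np.log(ls.attempt_frequency)
    # sequential rates through the ts between stable i and i+1
    ln_fwd = lnA - (Gt - Gs[:, :-1])  # i -> i+1
    ln_bwd = lnA - (Gt - Gs[:, 1:])  # i+1 -> i
    gaps = np.diff(X, axis=1)
    return F, X, pops, ln_fwd, ln_bwd, gaps


def fit_landscape(
    obs: ObservationSet,
    init: EnergyLandscape,
    cfg: TetherConfig,
    n_restarts: int = 20,
    seed: int = 0,
    h_table=h_of_l,
    n_bootstrap: int = 0,
    max_nfev: int = 400,
) -> FitResult:
    """Simultaneous weighted nonlinear least-squares fit of the landscape
    to the observation set.

    The state count and order (topology) are taken from ``init`` and are
    not searched.  Multi-start (``n_restarts`` seeded perturbations of the
    initial landscape) guards against local minima.  Parameter SDs come
    from the Gauss–Newton covariance at the optimum, or from a parametric
    bootstrap when ``n_bootstrap`` > 0.
    """
    n = obs.n_states
    stables = init.stable_states
    if len(stables) != n:
        raise ValueError(
            f"init topology has {len(stables)} stable states, data has {n}"
        )
    A = init.attempt_frequency
    D_arr = np.array([r.trap_separation for r in obs.records])

    # pack observations into masked arrays for a fixed-size residual vector
    F_obs = np.array([r.forces for r in obs.records])
    F_sd = np.array([r.forces_sd for r in obs.records])
    P_obs = np.array([r.populations for r in obs.records])
    P_sd = np.array([r.populations_sd for r in obs.records])
    lnR_f = np.array(
        [[r.log_rates[i, i + 1] for i in range(n - 1)] for r in obs.records]
    )
    lnR_f_sd = np.array(
        [[r.log_rates_sd[i, i + 1] for i in range(n - 1)] for r in obs.records]
    )
    lnR_b = np.array(
        [[r.log_rates[i + 1, i] for i in range(n - 1)] for r in obs.records]
    )
    lnR_b_sd = np.array(
        [[r.log_rates_sd[i + 1, i] for i in range(n - 1)] for r in obs.records]
    )
    X_obs = np.array([r.extension_gaps for r in obs.records])
    X_sd = np.array([r.extension_gaps_sd for r in obs.records])

    masks = [np.isfinite(a) for a in (F_obs, P_obs, lnR_f, lnR_b, X_obs)]
    n_obs_total = int(sum(m.sum() for m in masks))

    def residuals(params):
        try:
            ls = _build_landscape(params, n, A, h_table)
            F, X, pops, ln_fwd, ln_bwd, gaps = _predict_grid(ls, D_arr, cfg)
        except (ValueError, RuntimeError):
            return np.full(n_obs_total, 1e3)
        pieces = [
            ((F - F_obs) / F_sd)[masks[0]],
            ((pops - P_obs) / P_sd)[masks[1]],
            ((ln_fwd - lnR_f) / lnR_f_sd)[masks[2]],
            ((ln_bwd - lnR_b) / lnR_b_sd)[masks[3]],
            ((gaps - X_obs) / X_sd)[masks[4]],
        ]
        out = np.concatenate(pieces)
        if not np.all(np.isfinite(out)):
            return np.full(n_obs_total, 1e3)
        return out

    # initial parameter vector from the init landscape
    l_init = np.array([s.l for s in stables])
    V_init = np.array([s.V for s in stables])
    V_init = V_init - V_init[0]
    fr_init, off_init = [], []
    for i in range(n - 1):
        ts = init.barrier_between(i, i + 1)
        fr_init.append(
            (ts.l - stables[i].l) / (stables[i + 1].l - stables[i].l)
        )
        off_init.append(ts.V - max(stables[i].V, stables[i + 1].V))
    p0 = np.concatenate(
        [
            [l_init[0]],
            np.diff(l_init),
            V_init[1:],
            np.clip(fr_init, 0.08, 0.92),
            np.clip(off_init, -1.9, 14.0),
        ]
    )
    lb = np.concatenate(
        [[1.0], np.full(n - 1, 2.0), np.full(n - 1, 1.0),
         np.full(n - 1, 0.05), np.full(n - 1, -2.0)]
    )
    ub = np.concatenate(
        [[80.0], np.full(n - 1, 40.0), np.full(n - 1, 150.0),
         np.full(n - 1, 0.95), np.full(n - 1, 15.0)]
    )
    x_scale = np.concatenate(
        [[2.0], np.full(n - 1, 2.0), np.full(n - 1, 2.0),
         np.full(n - 1, 0.05), np.full(n - 1, 0.5)]
    )

    if not np.all(np.isfinite(p0)):
        raise ValueError("initial landscape produced non-finite parameters")
    rng = np.random.default_rng(seed)
    best = None
    last_exc = None
    for k in range(max(n_restarts, 1)):
        if k == 0:
            x0 = p0.copy()
        else:
            x0 = p0.copy()
            x0[0] *= 1 + 0.1 * rng.standard_normal()
            x0[1:n] *= 1 + 0.15 * rng.standard_normal(n - 1)
            x0[n : 2 * n - 1] += 2.0 * rng.standard_normal(n - 1)
            x0[2 * n - 1 : 3 * n - 2] += 0.1 * rng.standard_normal(n - 1)
            x0[3 * n - 2 :] += 1.0 * rng.standard_normal(n - 1)
        x0 = np.clip(x0, lb + 1e-9, ub - 1e-9)
        try:
            sol = least_squares(
                residuals, x0, bounds=(lb, ub), x_scale=x_scale,
                max_nfev=max_nfev,
            )
        except Exception as exc:  # infeasible start; try the next one
            last_exc = exc
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(
            f"landscape fit failed from every start (last error: {last_exc})"
        )

    param_sd = _covariance_sd(best)
    if n_bootstrap > 0:
        param_sd = _bootstrap_sd(
            residuals, best, lb, ub, x_scale, rng, n_bootstrap,
            (F_sd, P_sd, lnR_f_sd, lnR_b_sd, X_sd), masks, n_obs_total,
        )

    return _make_fit_result(
        best, param_sd, n, A, h_table, obs, n_obs_total
    )


def _covariance_sd(sol) -> np.ndarray:
    """Gauss–Newton parameter SDs from the jacobian at the optimum,
    scaled by the reduced chi-square."""
    J = sol.jac
    dof = max(J.shape[0] - J.shape[1], 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = np.linalg.pinv(J.T @ J) * s2
        return np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        return np.full(J.shape[1], np.nan)


def _bootstrap_sd(
    residuals, best, lb, ub, x_scale, rng, n_bootstrap, sds, masks, n_obs
):
    """Parametric bootstrap: perturb observations by their uncertainties
    and refit from the optimum."""
    samples = []
    for _ in range(n_bootstrap):
        shift = rng.standard_normal(n_obs)

        def perturbed(params):
            return residuals(params) - shift

        try:
            sol = least_squares(
                perturbed, best.x, bounds=(lb, ub), x_scale=x_scale,
                max_nfev=100,
            )
            samples.append(sol.x)
        except Exception:
            continue
    if len(samples) < 3:
        return _covariance_sd(best)
    return np.std(np.array(samples), axis=0, ddof=1)


def _make_fit_result(best, param_sd, n, A, h_table, obs, n_obs_total):
    ls = _build_landscape(best.x, n, A, h_table)
    V = np.concatenate(([0.0], best.x[n : 2 * n - 1]))
    V_sd = np.concatenate(([0.0], param_sd[n : 2 * n - 1]))
    offs = best.x[3 * n - 2 : 4 * n - 3]
    offs_sd = param_sd[3 * n - 2 : 4 * n - 3]
    domain_energies, domain_sd, barriers, barrier_sd = {}, {}, {}, {}
    for i, name in enumerate(obs.domain_names):
        domain_energies[name] = float(V[i + 1] - V[i])
        domain_sd[name] = float(np.hypot(V_sd[i + 1], V_sd[i]))
        # barrier height above the higher-l (unfolded) stable state at
        # zero force: V_ts - V_{i+1}
        v_ts = max(V[i], V[i + 1]) + offs[i]
        barriers[name] = float(v_ts - V[i + 1])
        barrier_sd[name] = float(np.hypot(offs_sd[i], 0.0))
    return FitResult(
        landscape=ls,
        domain_energies=domain_energies,
        domain_energies_sd=domain_sd,
        barriers=barriers,
        barriers_sd=barrier_sd,
        cost=float(best.cost),
        residuals=best.fun,
        n_observations=n_obs_total,
        param_sd=param_sd,
        converged=bool(best.success),
    )


def initial_landscape_from_observations(
    obs: ObservationSet,
    cfg: TetherConfig,
    attempt_frequency: float = 1e6,
    h_table=h_of_l,
) -> EnergyLandscape:
    """Crude data-derived starting landscape for :func:`fit_landscape`.

    Contour gaps from the median extension changes (divided by the WLC
    fractional extension of the polypeptide at the median observed force),
    the baseline contour from the best-populated record's lowest-state
    force, V differences from the work F·Δx at the population crossover,
    transition states mid-gap with a 2 kBT offset.
    """
    from .tether_mechanics import wlc_force
    from scipy.optimize import brentq

    n = obs.n_states
    kBT = cfg.kBT
    F_all = np.array([r.forces for r in obs.records])
    gaps_all = np.array([r.extension_gaps for r in obs.records])
    med_F = float(np.nanmedian(F_all))
    med_gaps = np.nanmedian(gaps_all, axis=0)
    if np.any(~np.isfinite(med_gaps)):
        raise ValueError("extension changes missing for some adjacent pair")
    # fractional extension of the polypeptide WLC at the median force
    poly = cfg.polypeptide(1000.0)
    x_frac = (
        brentq(
            lambda x: wlc_force(x, poly, kBT) - med_F, 0.0, 999.9
        )
        / 1000.0
    )
    dl = med_gaps / x_frac
    # baseline l from matching the most-folded state's force at its D:
    # start from a generic 10 nm and let the fit refine it
    l0 = 10.0
    ls_arr = np.concatenate(([l0], l0 + np.cumsum(dl)))
    # V from the work at the pair's occupancy crossover force
    V = [0.0]
    for i in range(n - 1):
        pop_ratio = np.array(
            [
                r.populations[i + 1] / r.populations[i]
                if np.isfinite(r.populations[i])
                and np.isfinite(r.populations[i + 1])
                and r.populations[i] > 0
                else np.nan
                for r in obs.records
            ]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            F_pair = np.array(
                [
                    np.nanmean([r.forces[i], r.forces[i + 1]])
                    for r in obs.records
                ]
            )
        good = np.isfinite(pop_ratio) & (pop_ratio > 0) & np.isfinite(F_pair)
        if good.sum() >= 2:
            # interpolate ln occupancy ratio to zero (it increases with
            # force for an unfolding pair)
            lnr = np.log(pop_ratio[good])
            f = F_pair[good]
            order = np.argsort(lnr)
            f_eq = float(np.interp(0.0, lnr[order], f[order]))
        else:
            f_eq = med_F
        V.append(V[-1] + f_eq * med_gaps[i] / kBT * 0.8)
    states = []
    for i in range(n):
        states.append(
            LandscapeState(
                "stable", ls_arr[i], V[i], float(h_table(ls_arr[i])), f"S{i}"
            )
        )
        if i < n - 1:
            tl = 0.5 * (ls_arr[i] + ls_arr[i + 1])
            states.append(
                LandscapeState(
                    "transition",
                    tl,
                    max(V[i], V[i + 1]) + 2.0,
                    float(h_table(tl)),
                    f"TS{i}",
                )
            )
    return EnergyLandscape(
        tuple(sorted(states, key=lambda s: s.l)),
        attempt_frequency=attempt_frequency,
    )


def total_zipping_energy(fit: FitResult, ld_energy: float = 8.0) -> float:
    """Total zippering free energy (kBT): sum of the fitted domain
    energies plus the linker-domain energy (fixed, not refit)."""
    if not fit.domain_energies:
        raise ValueError("fit carries no domain energies")
    return float(sum(fit.domain_energies.values()) + ld_energy)


def compare_landscapes(fit_a: FitResult, fit_b: FitResult) -> dict:
    """Per-domain energy differences between two fits.

    Returns {'delta': {domain: V_b - V_a}, 'only_a': [...], 'only_b':
    [...], 'same_topology': bool}; domains present in only one fit (merged
    cooperative units, e.g. a CTD_MD pair replacing CTD and MD) are
    reported, never silently aligned."""
    da, db = fit_a.domain_energies, fit_b.domain_energies
    common = [k for k in da if k in db]
    return {
        "delta": {k: db[k] - da[k] for k in common},
        "only_a": [k for k in da if k not in db],
        "only_b": [k for k in db if k not in da],
        "same_topology": set(da) == set(db),
    }
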