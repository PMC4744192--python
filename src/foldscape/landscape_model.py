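"""Simplified folding energy landscape and its force-dependent predictions.

The landscape is a sequence of states along the reaction coordinate l, the
contour length of the unfolded (and stretched) polypeptide.  Each state i
carries a zero-force free energy V_i (kBT) and a folded-core size h_i (nm);
stable and transition states strictly alternate with increasing l.  Given a
tether configuration and a trap separation D, the model predicts for every
state its force and extension (tether force balance), for every stable
state its Boltzmann population, and for every adjacent pair of stable
states the Kramers barrier-crossing rates through the intervening
transition state:

    rate(i -> j) = A * exp(-(G_ts - G_i)),   G in kBT,

with a single attempt frequency A shared by all transitions.  Detailed
balance rate(i->j)/rate(j->i) = exp(-(G_j - G_i)) holds by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .tether_mechanics import (
    TetherConfig,
    solve_state_force,
    solve_states_vectorized,
    state_total_energy,
)

__all__ = [
    "LandscapeState",
    "EnergyLandscape",
    "StatePrediction",
    "predict_states",
    "boltzmann_populations",
    "kramers_rates",
    "predict_force_dependence",
    "equilibrium_force",
    "equilibrium_force_region",
    "NM_PER_RESIDUE",
]

#: Contour length per amino acid for l <-> residue-number conversion (nm/aa).
NM_PER_RESIDUE = 0.365


@dataclass(frozen=True)
class LandscapeState:
    kind: str  # "stable" | "transition"
    l: float  # unfolded contour length, nm
    V: float  # zero-force free energy, kBT
    h: float  # folded-core size along pulling axis, nm
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("stable", "transition"):
            raise ValueError("state kind must be 'stable' or 'transition'")
        if self.l < 0 or self.h < 0:
            raise ValueError("contour length and core size must be >= 0 nm")


@dataclass(frozen=True)
class EnergyLandscape:
    """Ordered landscape states plus the shared Kramers attempt frequency."""

    states: tuple[LandscapeState, ...]
    attempt_frequency: float = 1e6  # 1/s
    nm_per_residue: float = NM_PER_RESIDUE

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if self.attempt_frequency <= 0:
            raise ValueError("attempt_frequency must be > 0 /s")
        ls = [s.l for s in self.states]
        if any(b <= a for a, b in zip(ls, ls[1:])):
            raise ValueError("state contour lengths must strictly increase")
        kinds = [s.kind for s in self.states]
        if kinds[0] != "stable" or kinds[-1] != "stable":
            raise ValueError("landscape must begin and end with stable states")
        for a, b in zip(kinds, kinds[1:]):
            if a == b:
                raise ValueError(
                    "stable and transition states must strictly alternate"
                )
        if len(self.stable_states) < 2:
            raise ValueError("landscape needs at least 2 stable states")

    @property
    def stable_states(self) -> tuple[LandscapeState, ...]:
        return tuple(s for s in self.states if s.kind == "stable")

    @property
    def transition_states(self) -> tuple[LandscapeState, ...]:
        return tuple(s for s in self.states if s.kind == "transition")

    def barrier_between(self, i: int, j: int) -> LandscapeState:
        """Transition state between stable states i and j (stable indices)."""
        lo, hi = sorted((i, j))
        stables = self.stable_states
        ts = [
            s
            for s in self.states
            if s.kind == "transition"
            and stables[lo].l < s.l < stables[hi].l
        ]
        if not ts:
            raise ValueError(f"no transition state between stable {i} and {j}")
        return max(ts, key=lambda s: s.V)

    def residue_of(self, l: float, anchor_residue: float = 0.0) -> float:
        """Convert contour length to a residue number offset from an anchor."""
        return anchor_residue + l / self.nm_per_residue

    def to_json(self) -> str:
        return json.dumps(
            {
                "attempt_frequency_per_s": self.attempt_frequency,
                "nm_per_residue": self.nm_per_residue,
                "states": [
                    {
                        "kind": s.kind,
                        "l_nm": s.l,
                        "V_kBT": s.V,
                        "h_nm": s.h,
                        "label": s.label,
                    }
                    for s in self.states
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "EnergyLandscape":
        d = json.loads(text)
        return cls(
            states=tuple(
                LandscapeState(
                    kind=s["kind"],
                    l=s["l_nm"],
                    V=s["V_kBT"],
                    h=s["h_nm"],
                    label=s.get("label", ""),
                )
                for s in d["states"]
            ),
            attempt_frequency=d.get("attempt_frequency_per_s", 1e6),
            nm_per_residue=d.get("nm_per_residue", NM_PER_RESIDUE),
        )

    def with_shifted_V(self, which: str, dV: float) -> "EnergyLandscape":
        """Return a copy with all states whose label contains ``which``
        shifted by dV (used to derive mutant fixtures)."""
        new = tuple(
            replace(s, V=s.V + dV) if which in s.label else s
            for s in self.states
        )
        return replace(self, states=new)


@dataclass
class StatePrediction:
    """Model predictions at one trap separation."""

    trap_separation: float  # nm
    labels: list  # stable-state labels
    forces: np.ndarray  # pN, per stable state
    extensions: np.ndarray  # nm, tether extension per stable state
    energies: np.ndarray  # kBT, total energy per stable state
    populations: np.ndarray  # per stable state, sums to 1
    barrier_energies: dict  # (i, j) stable-index pair -> G_ts (kBT)
    rates: np.ndarray  # 1/s, rates[i, j] = rate of i -> j (0 where none)
    lifetimes: np.ndarray  # s, 1/sum of exit rates (inf if no exit)

    @property
    def mean_force(self) -> float:
        """Population-weighted mean force (pN), the observable 'mean force'
        of a constant-trap-separation trace."""
        return float(np.sum(self.populations * self.forces))


def boltzmann_populations(G) -> np.ndarray:
    """Equilibrium populations from total energies (kBT): softmax(-G).

    Invariant under a uniform shift of all energies; normalized to 1.
    """
    G = np.asarray(G, dtype=float)
    if G.size == 0:
        raise ValueError("need at least one state energy")
    if not np.all(np.isfinite(G)):
        raise ValueError("state energies must be finite")
    w = np.exp(-(G - G.min()))
    return w / w.sum()


def predict_states(
    ls: EnergyLandscape,
    D: float,
    cfg: TetherConfig,
    include_skip: bool = False,
) -> StatePrediction:
    """Solve every state of the landscape at trap separation D and derive
    populations, Kramers rates and lifetimes of the stable states."""
    stables = ls.stable_states
    n = len(stables)
    all_states = ls.states
    l_arr = np.array([s.l for s in all_states])
    h_arr = np.array([s.h for s in all_states])
    try:
        sol = solve_states_vectorized(D, l_arr, h_arr, cfg)
    except (ValueError, RuntimeError) as exc:
        raise RuntimeError(f"force balance failed at D={D} nm: {exc}") from exc
    V_arr = np.array([s.V for s in all_states])
    G_all = sol["g_m"] + V_arr + sol["g_dna"] + sol["g_beads"]
    stable_idx = [k for k, s in enumerate(all_states) if s.kind == "stable"]
    forces = sol["force"][stable_idx]
    extensions = sol["extension"][stable_idx]
    energies = G_all[stable_idx]

    populations = boltzmann_populations(energies)

    barrier_energies: dict = {}
    rates = np.zeros((n, n))
    pairs = [(i, i + 1) for i in range(n - 1)]
    if include_skip:
        pairs += [
            (i, j) for i in range(n) for j in range(i + 2, n)
        ]
    A = ls.attempt_frequency
    ts_G = {
        all_states[k].l: G_all[k]
        for k, s in enumerate(all_states)
        if s.kind == "transition"
    }
    for i, j in (p for p in pairs if abs(p[0] - p[1]) == 1):
        ts = ls.barrier_between(i, j)
        G_ts = ts_G[ts.l]
        barrier_energies[(i, j)] = G_ts
        try:
            rates[i, j] = A * math.exp(-(G_ts - energies[i]))
            rates[j, i] = A * math.exp(-(G_ts - energies[j]))
        except OverflowError:
            rates[i, j] = np.inf
        if not np.isfinite(rates[i, j]) or not np.isfinite(rates[j, i]):
            raise RuntimeError(
                f"rate overflow between stable states {i} and {j}: "
                "barrier below state energy is too large; use a larger barrier"
            )
    for i, j in (p for p in pairs if abs(p[0] - p[1]) > 1):
        # effective skip rate: flux that crosses every intervening stable
        # state without equilibrating there, i.e. the sequential rate into
        # the first intermediate times the splitting probability of
        # continuing forward at each intermediate
        step = 1 if j > i else -1
        rate = rates[i, i + step]
        for m in range(i + step, j, step):
            fwd, bwd = rates[m, m + step], rates[m, m - step]
            rate *= fwd / (fwd + bwd)
        rates[i, j] = rate
        barrier_energies[(i, j)] = np.nan

    exit_rates = rates.sum(axis=1)
    lifetimes = np.where(exit_rates > 0, 1.0 / np.where(exit_rates > 0, exit_rates, 1.0), np.inf)
    return StatePrediction(
        trap_separation=D,
        labels=[s.label for s in stables],
        forces=forces,
        extensions=extensions,
        energies=energies,
        populations=populations,
        barrier_energies=barrier_energies,
        rates=rates,
        lifetimes=lifetimes,
    )


def kramers_rates(
    ls: EnergyLandscape, pred: StatePrediction, include_skip: bool = False
) -> np.ndarray:
    """Rate matrix (1/s) over stable states of ``ls`` at the trap separation
    of ``pred`` (recomputed from the barrier energies stored there)."""
    n = len(pred.energies)
    rates = np.zeros((n, n))
    A = ls.attempt_frequency
    for (i, j), G_ts in pred.barrier_energies.items():
        if abs(i - j) > 1 and not include_skip:
            continue
        rates[i, j] = A * math.exp(-(G_ts - pred.energies[i]))
        rates[j, i] = A * math.exp(-(G_ts - pred.energies[j]))
    return rates


def predict_force_dependence(
    ls: EnergyLandscape, cfg: TetherConfig, D_grid
) -> dict:
    """Populations, rates and lifetimes across a grid of trap separations.

    Returns a dict of arrays keyed by 'trap_separation', 'mean_force',
    'forces', 'populations', 'rates', 'lifetimes'; first axis is the grid.
    """
    preds = [predict_states(ls, D, cfg) for D in np.asarray(D_grid, float)]
    return {
        "trap_separation": np.array([p.trap_separation for p in preds]),
        "mean_force": np.array([p.mean_force for p in preds]),
        "forces": np.array([p.forces for p in preds]),
        "extensions": np.array([p.extensions for p in preds]),
        "populations": np.array([p.populations for p in preds]),
        "rates": np.array([p.rates for p in preds]),
        "lifetimes": np.array([p.lifetimes for p in preds]),
        "predictions": preds,
    }


def _energy_gap(ls, cfg, pair, D):
    pred_states = ls.stable_states
    i, j = pair
    gi = gj = None
    for idx in (i, j):
        s = pred_states[idx]
        ms = solve_state_force(D, s.l, s.h, cfg)
        g = state_total_energy(ms, s.V, cfg)
        if idx == i:
            gi = g
        else:
            gj = g
    return gj - gi


def equilibrium_force(
    ls: EnergyLandscape,
    cfg: TetherConfig,
    pair: tuple[int, int],
    D_range: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Equilibrium force (pN) of an adjacent stable pair: the force of the
    folded (lower-l) member at the trap separation where the two states'
    total energies are equal.  Returns (force, trap_separation).

    Bisection over D; raises if the energy gap does not change sign in the
    scanned range or if the two states are degenerate.
    """
    i, j = pair
    stables = ls.stable_states
    if not (0 <= i < len(stables) and 0 <= j < len(stables)) or i == j:
        raise ValueError("pair must be two distinct stable-state indices")
    if abs(i - j) != 1:
        raise ValueError("pair must be adjacent stable states")
    si, sj = stables[min(i, j)], stables[max(i, j)]
    if si.l == sj.l and si.V == sj.V and si.h == sj.h:
        raise ValueError("degenerate pair: states are identical")
    if D_range is None:
        R = cfg.bead_radii_sum
        L = cfg.handle.contour_length
        # upper bound allows ~40 pN of bead displacement on top of a nearly
        # fully stretched tether; lower bound is a slack tether
        D_range = (
            R + 0.5 * L,
            R + 1.02 * L + max(s.l for s in stables) + 40.0 / cfg.trap_stiffness,
        )
    lo, hi = D_range
    gap = lambda D: _energy_gap(ls, cfg, (min(i, j), max(i, j)), D)
    # coarse scan for a sign change (gap is monotone decreasing in D:
    # higher force favors the unfolded, higher-l state)
    Ds = np.linspace(lo, hi, 60)
    vals = [gap(D) for D in Ds]
    bracket = None
    for a, b, va, vb in zip(Ds, Ds[1:], vals, vals[1:]):
        if va == 0.0:
            bracket = (a, a)
            break
        if va * vb < 0:
            bracket = (a, b)
            break
    if bracket is None:
        raise RuntimeError(
            f"no equilibrium found for pair {pair} in D range {D_range}"
        )
    if bracket[0] == bracket[1]:
        D_eq = bracket[0]
    else:
        D_eq = brentq(gap, *bracket, xtol=1e-6)
    F_eq = solve_state_force(D_eq, si.l, si.h, cfg).force
    return F_eq, D_eq


def trap_separation_for_force(
    ls: EnergyLandscape,
    cfg: TetherConfig,
    mean_force: float,
    D_range: tuple[float, float] | None = None,
) -> float:
    """Trap separation at which the population-weighted mean force equals
    ``mean_force`` (bisection; mean force increases with D)."""
    if D_range is None:
        R = cfg.bead_radii_sum
        L = cfg.handle.contour_length
        D_range = (
            R + 0.5 * L,
            R + 1.02 * L + max(s.l for s in ls.stable_states)
            + 40.0 / cfg.trap_stiffness,
        )
    f = lambda D: predict_states(ls, D, cfg).mean_force - mean_force
    lo, hi = D_range
    Ds = np.linspace(lo, hi, 40)
    vals = [f(D) for D in Ds]
    for a, b, va, vb in zip(Ds, Ds[1:], vals, vals[1:]):
        if va * vb <= 0:
            return float(brentq(f, a, b, xtol=1e-4))
    raise RuntimeError(
        f"mean force {mean_force} pN not attainable in D range {D_range}"
    )


def equilibrium_force_region(
    ls: EnergyLandscape, cfg: TetherConfig, pairs
) -> float:
    """Population-weighted equilibrium force (pN) of a multi-pair transition
    region (e.g. overlapping MD and NTD transitions): each adjacent pair
    contributes its own equilibrium force, weighted by the summed population
    of its two states at that pair's equilibrium trap separation."""
    forces, weights = [], []
    for pair in pairs:
        F_eq, D_eq = equilibrium_force(ls, cfg, pair)
        pred = predict_states(ls, D_eq, cfg)
        w = pred.populations[pair[0]] + pred.populations[pair[1]]
        forces.append(F_eq)
        weights.append(w)
    forces = np.asarray(forces)
    weights = np.asarray(weights)
    return float(np.sum(forces * weights) / np.sum(weights))
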