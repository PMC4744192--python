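"""Packaged landscape fixtures for the SNARE four-helix bundle.

The wild-type (WT) four-state landscape covers the states visited in
constant-trap-separation traces: state 2 (LD unfolded), state 3 (CTD
unfolded, half-zippered), state 4 (MD unfolded) and state 5 (NTD unfolded,
fully unzipped v-SNARE on a folded t-SNARE).  Zero-force free energies are
the measured domain folding energies (CTD 22, MD 13, NTD 25 kBT, cumulative
from state 2); the MD transition state sits 5 kBT above the MD-unfolded
state while CTD and NTD folding are downhill at zero force (their
transition-state V equals the unfolded member's V).

Contour lengths and folded-core sizes are NOT the crystallographic values:
they were calibrated numerically so that, under the default tether
configuration, the pair equilibrium forces and extension changes reproduce
the measured ones (CTD 16.5 pN / 6.7 nm; MD 17.2 pN / 3.6 nm; NTD
17.2 pN).  The folded-core size h(l) is shipped as the monotone
piecewise-linear table through the state (l, h) knots.

Mutant fixtures shift domain energies by the measured amounts relative to
WT (geometry kept fixed): V39A/V42A weakens NTD by 3 kBT; L70A, F77A and
M71A/I192A weaken CTD by 10, 12 and 13 kBT; T251I strengthens CTD by
5 kBT.  L60A (and L63A) abolish the independent MD intermediate so CTD and
MD fold as one cooperative unit (state 4 kept, state 3 removed); M46A
merges MD with NTD the same way (state 4 removed).
"""

from __future__ import annotations

import numpy as np

from .landscape_model import EnergyLandscape, LandscapeState
from .tether_mechanics import TetherConfig

__all__ = [
    "default_tether_config",
    "get_fixture",
    "list_fixtures",
    "h_of_l",
    "WT_L",
    "WT_H",
    "WT_V",
]

#: Calibrated WT stable-state geometry (states 2..5).
WT_L = (12.0, 26.2143, 33.7746, 49.1243)  # nm
WT_H = (3.0, 2.7, 2.55, 2.15)  # nm
WT_V = (0.0, 22.0, 35.0, 60.0)  # kBT, V(state 2) = 0 gauge
#: Transition-state contour lengths and zero-force energies.
WT_TS_L = (20.5286, 31.8846, 43.9054)  # nm
WT_TS_V = (22.0, 40.0, 60.0)  # kBT
WT_LABELS = ("state2", "state3", "state4", "state5")
WT_TS_LABELS = ("TS_CTD", "TS_MD", "TS_NTD")

#: Extension of the table beyond state 5 for FEC fixtures: full t-SNARE
#: unfolding (state 6) releases a further ~25 nm of contour.
STATE6_L = WT_L[3] + 25.0
STATE6_V = WT_V[3] + 25.0
TS56_L = WT_L[3] + 0.30 * 25.0
TS56_DV = 31.0  # barrier above state 5, kBT; set so the rip falls 20-30 pN

ATTEMPT_FREQUENCY = 1e6  # 1/s, shared Kramers prefactor

#: Zero-force LD folding energy (kBT), fixed from prior characterization,
#: not refit.
LD_ENERGY = 8.0


def h_of_l(l) -> np.ndarray | float:
    """Folded-core size along the pulling axis as a function of unfolded
    contour length: monotone piecewise-linear through the WT knots,
    clamped at the ends (h -> 0 once the t-SNARE is gone)."""
    knots_l = WT_L + (STATE6_L,)
    knots_h = WT_H + (0.0,)
    out = np.interp(l, knots_l, knots_h)
    return float(out) if np.isscalar(l) else out


def default_tether_config() -> TetherConfig:
    """Tether configuration used by all fixtures: k1 = k2 = 0.5 pN/nm,
    R = 2000 nm, T = 296 K, DNA handle P = 40 nm / L = 768.4 nm,
    polypeptide P = 0.6 nm.  Trap stiffness and bead radii are free
    instrument parameters; these values were calibrated together with the
    WT geometry against the measured equilibrium forces and extension
    changes."""
    return TetherConfig(
        trap_stiffness_1=0.5,
        trap_stiffness_2=0.5,
        bead_radii_sum=2000.0,
        temperature=296.0,
    )


def _wt_states() -> list[LandscapeState]:
    states = []
    for i in range(4):
        states.append(
            LandscapeState("stable", WT_L[i], WT_V[i], WT_H[i], WT_LABELS[i])
        )
        if i < 3:
            states.append(
                LandscapeState(
                    "transition",
                    WT_TS_L[i],
                    WT_TS_V[i],
                    float(h_of_l(WT_TS_L[i])),
                    WT_TS_LABELS[i],
                )
            )
    return states


def _landscape(states) -> EnergyLandscape:
    return EnergyLandscape(
        tuple(sorted(states, key=lambda s: s.l)),
        attempt_frequency=ATTEMPT_FREQUENCY,
    )


def _shift_from(index: int, dv: float, states) -> list[LandscapeState]:
    """Shift V of every state with l >= states[index].l by dv (cumulative
    energies: changing one domain's energy moves everything beyond it)."""
    pivot_l = states[index].l
    out = []
    for s in states:
        if s.l >= pivot_l:
            s = LandscapeState(s.kind, s.l, s.V + dv, s.h, s.label)
        out.append(s)
    return out


def _merged(drop_label: str, merged_label: str):
    """Remove a stable intermediate and its flanking transition states,
    replacing them with a single downhill transition state for the merged
    cooperative transition."""
    states = [s for s in _wt_states()]
    drop = next(s for s in states if s.label == drop_label)
    keep = [
        s
        for s in states
        if s.kind == "stable" and s.label != drop_label
    ]
    keep_l = sorted(s.l for s in keep)
    lo = max(l for l in keep_l if l < drop.l)
    hi = min(l for l in keep_l if l > drop.l)
    hi_state = next(s for s in keep if s.l == hi)
    ts_l = lo + 0.65 * (hi - lo)
    ts = LandscapeState(
        "transition", ts_l, hi_state.V, float(h_of_l(ts_l)), merged_label
    )
    new = [s for s in keep] + [
        s
        for s in states
        if s.kind == "transition" and not (lo < s.l < hi)
    ]
    new.append(ts)
    return _landscape(new)


def list_fixtures() -> list[str]:
    return [
        "wt",
        "wt_pull",
        "v39a_v42a",
        "m46a",
        "l60a",
        "l70a",
        "f77a",
        "m71a_i192a",
        "t251i",
    ]


def get_fixture(name: str) -> EnergyLandscape:
    """Return a packaged landscape fixture by name (see
    :func:`list_fixtures`)."""
    name = name.lower()
    wt = _wt_states()
    if name == "wt":
        return _landscape(wt)
    if name == "wt_pull":
        # WT plus the irreversibly unfolding t-SNARE (state 6); use with
        # absorbing_states=(4,) in the simulator to model SNAP-25 loss
        states = wt + [
            LandscapeState(
                "transition",
                TS56_L,
                WT_V[3] + TS56_DV,
                float(h_of_l(TS56_L)),
                "TS_tSNARE",
            ),
            LandscapeState("stable", STATE6_L, STATE6_V, 0.0, "state6"),
        ]
        return _landscape(states)
    if name in ("v39a_v42a",):
        # NTD destabilized by 3 kBT: state 5 (and its downhill TS) lowered
        states = [
            LandscapeState(
                s.kind, s.l, s.V - 3.0 if s.label in ("state5", "TS_NTD") else s.V,
                s.h, s.label,
            )
            for s in wt
        ]
        return _landscape(states)
    if name == "t251i":
        idx = next(i for i, s in enumerate(wt) if s.label == "TS_CTD")
        return _landscape(_shift_from(idx, +5.0, wt))
    if name in ("l70a", "f77a", "m71a_i192a"):
        dv = {"l70a": -10.0, "f77a": -12.0, "m71a_i192a": -13.0}[name]
        idx = next(i for i, s in enumerate(wt) if s.label == "TS_CTD")
        return _landscape(_shift_from(idx, dv, wt))
    if name == "l60a" or name == "l63a":
        return _merged("state3", "TS_CTD_MD")
    if name == "m46a":
        return _merged("state4", "TS_MD_NTD")
    raise KeyError(f"unknown fixture '{name}'; see list_fixtures()")
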