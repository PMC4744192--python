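"""Mechanics of the bead–DNA–protein dumbbell.

A protein of interest is tethered between two optically trapped beads
through a double-stranded DNA handle.  At a given trap separation ``D`` the
measured force and extension follow from a force balance between

* the unfolded polypeptide, a worm-like chain (WLC) of contour length ``l``
  (the reaction coordinate of folding),
* the folded protein core, an orientable rigid body treated as a one-segment
  freely jointed chain (FJC) of size ``h`` along the pulling axis,
* the DNA handle, a WLC with fixed persistence and contour length, and
* the displacement of the two beads out of their trap centers.

Units throughout: lengths nm, forces pN, energies kBT, stiffness pN/nm,
temperature K.  Thermal energy is always computed from the configured
temperature, never hard-coded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BOLTZMANN_PN_NM",
    "thermal_energy",
    "thermal_energy_kcal_per_mol",
    "PolymerParams",
    "FoldedCore",
    "TetherConfig",
    "MechanicalState",
    "wlc_force",
    "wlc_extension",
    "fjc_core_extension",
    "wlc_stretch_energy",
    "solve_state_force",
    "solve_state_force_many",
    "state_total_energy",
]

#: Boltzmann constant in pN·nm/K (1.380649e-23 J/K, 1 J = 1e21 pN·nm).
BOLTZMANN_PN_NM = 1.380649e-2

#: Avogadro constant (1/mol) and joules per kcal, for unit conversion only.
_AVOGADRO = 6.02214076e23
_J_PER_KCAL = 4184.0

#: Upper force bound for root searches (pN); tethers break long before this.
F_MAX = 200.0


def thermal_energy(temperature: float) -> float:
    """Thermal energy kB*T in pN·nm at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return BOLTZMANN_PN_NM * temperature


def thermal_energy_kcal_per_mol(temperature: float) -> float:
    """Thermal energy kB*T expressed in kcal/mol."""
    joules = 1.380649e-23 * temperature
    return joules * _AVOGADRO / _J_PER_KCAL


@dataclass(frozen=True)
class PolymerParams:
    """Worm-like chain parameters of a semi-flexible polymer.

    ``contour_length`` may be zero to represent an empty chain (e.g. the
    unfolded polypeptide of a fully folded state), in which case force,
    extension and energy contributions all vanish.
    """

    persistence_length: float  # nm
    contour_length: float  # nm

    def __post_init__(self) -> None:
        if self.persistence_length <= 0:
            raise ValueError("persistence_length must be > 0 nm")
        if self.contour_length < 0:
            raise ValueError("contour_length must be >= 0 nm")


@dataclass(frozen=True)
class FoldedCore:
    """Folded protein portion, characterized by its size h along the pulling
    axis.  h = 0 represents no folded core (contribution vanishes)."""

    size_along_axis: float  # nm

    def __post_init__(self) -> None:
        if self.size_along_axis < 0:
            raise ValueError("folded-core size h must be >= 0 nm")


@dataclass(frozen=True)
class TetherConfig:
    """Measurement system: two traps, two beads, one DNA handle.

    The effective trap stiffness is the series combination
    k_traps = k1*k2/(k1+k2); the total bead displacement at force F is
    F/k_traps and the sum of bead radii R offsets the trap separation.
    """

    trap_stiffness_1: float  # pN/nm
    trap_stiffness_2: float  # pN/nm
    bead_radii_sum: float  # nm
    temperature: float = 296.0  # K
    handle: PolymerParams = field(
        default_factory=lambda: PolymerParams(40.0, 768.4)
    )
    polypeptide_persistence: float = 0.6  # nm

    def __post_init__(self) -> None:
        if self.trap_stiffness_1 <= 0 or self.trap_stiffness_2 <= 0:
            raise ValueError("trap stiffnesses must be > 0 pN/nm")
        if self.bead_radii_sum <= 0:
            raise ValueError("bead_radii_sum must be > 0 nm")
        thermal_energy(self.temperature)  # validates T > 0

    @property
    def trap_stiffness(self) -> float:
        """Effective (series) stiffness of the two traps, pN/nm."""
        k1, k2 = self.trap_stiffness_1, self.trap_stiffness_2
        return k1 * k2 / (k1 + k2)

    @property
    def kBT(self) -> float:
        """Thermal energy in pN·nm."""
        return thermal_energy(self.temperature)

    def polypeptide(self, contour_length: float) -> PolymerParams:
        """WLC parameters for an unfolded polypeptide of contour length l."""
        return PolymerParams(self.polypeptide_persistence, contour_length)

    def to_json(self) -> str:
        d = {
            "trap_stiffness_1_pN_per_nm": self.trap_stiffness_1,
            "trap_stiffness_2_pN_per_nm": self.trap_stiffness_2,
            "bead_radii_sum_nm": self.bead_radii_sum,
            "temperature_K": self.temperature,
            "handle_persistence_length_nm": self.handle.persistence_length,
            "handle_contour_length_nm": self.handle.contour_length,
            "polypeptide_persistence_nm": self.polypeptide_persistence,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TetherConfig":
        d = json.loads(text)
        return cls(
            trap_stiffness_1=d["trap_stiffness_1_pN_per_nm"],
            trap_stiffness_2=d["trap_stiffness_2_pN_per_nm"],
            bead_radii_sum=d["bead_radii_sum_nm"],
            temperature=d.get("temperature_K", 296.0),
            handle=PolymerParams(
                d.get("handle_persistence_length_nm", 40.0),
                d.get("handle_contour_length_nm", 768.4),
            ),
            polypeptide_persistence=d.get("polypeptide_persistence_nm", 0.6),
        )


@dataclass
class MechanicalState:
    """Solved mechanical state of the dumbbell at one trap separation."""

    force: float  # pN
    tether_extension: float  # nm, X = x_m + H + x_DNA
    x_polypeptide: float  # nm
    core_extension: float  # nm (H)
    x_handle: float  # nm
    g_polypeptide: float  # kBT, WLC stretching entropy
    g_handle: float  # kBT
    g_beads: float  # kBT, F^2 / (2 k_traps)


# ---------------------------------------------------------------------------
# Chain force-extension laws


def wlc_force(x, p: PolymerParams, kBT: float):
    """Marko–Siggia worm-like chain force at extension x (nm) -> pN.

    F = kBT/P * [ 1/(4 (1 - x/L)^2) + x/L - 1/4 ],  0 <= x < L.
    Strictly increasing in x and divergent as x -> L.
    """
    x = np.asarray(x, dtype=float)
    L = p.contour_length
    if L == 0.0:
        if np.any(x != 0.0):
            raise ValueError("empty chain (L=0) only admits x=0")
        return np.zeros_like(x) if x.ndim else 0.0
    if np.any(x < 0) or np.any(x >= L):
        raise ValueError("extension must satisfy 0 <= x < L")
    t = x / L
    f = kBT / p.persistence_length * (0.25 / (1.0 - t) ** 2 + t - 0.25)
    return f if f.ndim else float(f)


def _wlc_force_derivative(t: np.ndarray, p: PolymerParams, kBT: float):
    """dF/dx of the Marko–Siggia law at fractional extension t."""
    return kBT / p.persistence_length * (0.5 / (1.0 - t) ** 3 + 1.0) / p.contour_length


def wlc_extension(F, p: PolymerParams, kBT: float):
    """Inverse of :func:`wlc_force`: extension (nm) at force F (pN).

    Solved by safeguarded Newton iteration from an upper bound on the
    fractional extension; the Marko–Siggia force is increasing and convex in
    x so the iteration converges monotonically.  Relative tolerance 1e-12.
    """
    F = np.asarray(F, dtype=float)
    scalar = F.ndim == 0
    F = np.atleast_1d(F)
    if np.any(F < 0):
        raise ValueError("force must be >= 0 pN")
    L, P = p.contour_length, p.persistence_length
    if L == 0.0:
        out = np.zeros_like(F)
        return float(out[0]) if scalar else out
    f = F * P / kBT  # dimensionless force
    # Upper bounds on the root: f(t) >= 3t/2 and f(t) >= 1/(4(1-t)^2) - 1/4.
    t = np.minimum(2.0 * f / 3.0, 1.0 - 0.5 / np.sqrt(f + 0.25))
    t = np.clip(t, 0.0, 1.0 - 1e-15)
    for _ in range(100):
        g = 0.25 / (1.0 - t) ** 2 + t - 0.25 - f
        dg = 0.5 / (1.0 - t) ** 3 + 1.0
        step = g / dg
        t_new = np.clip(t - step, 0.0, 1.0 - 1e-15)
        if np.all(np.abs(t_new - t) <= 1e-14 * (1.0 + t)):
            t = t_new
            break
        t = t_new
    x = t * L
    return float(x[0]) if scalar else x


def fjc_core_extension(F, core: FoldedCore, kBT: float):
    """Extension of the folded core along the pulling axis (nm).

    One-segment freely jointed chain: H = -kBT/F + h coth(F h / kBT).
    The F -> 0 limit is 0 (Taylor series used below F h / kBT < 1e-3 to
    avoid catastrophic cancellation); H -> h as F -> infinity.
    """
    h = core.size_along_axis
    F = np.asarray(F, dtype=float)
    scalar = F.ndim == 0
    F = np.atleast_1d(F)
    if np.any(F < 0):
        raise ValueError("force must be >= 0 pN")
    if h == 0.0:
        out = np.zeros_like(F)
        return float(out[0]) if scalar else out
    z = F * h / kBT
    small = z < 1e-3
    out = np.empty_like(z)
    # coth(z) - 1/z = z/3 - z^3/45 + 2 z^5/945 + ...
    zs = z[small]
    out[small] = h * (zs / 3.0 - zs**3 / 45.0 + 2.0 * zs**5 / 945.0)
    zl = z[~small]
    out[~small] = h / np.tanh(zl) - kBT / F[~small]
    return float(out[0]) if scalar else out


def _fjc_extension_derivative(F: np.ndarray, h: np.ndarray, kBT: float):
    """dH/dF of the one-segment FJC, elementwise (h may be an array)."""
    F = np.asarray(F, dtype=float)
    h = np.asarray(h, dtype=float)
    z = F * h / kBT
    out = np.empty(np.broadcast(F, h).shape)
    small = z < 1e-3
    # d/dF [h coth(z) - kBT/F] = kBT/F^2 - h^2/kBT * csch^2(z)
    # series: h^2/(3 kBT) - z^2 h^2/(15 kBT) + ...
    hb = np.broadcast_to(h, out.shape)
    zb = np.broadcast_to(z, out.shape)
    out[small] = hb[small] ** 2 / (3.0 * kBT) * (1.0 - zb[small] ** 2 / 5.0)
    Fb = np.broadcast_to(F, out.shape)
    zl = zb[~small]
    out[~small] = kBT / Fb[~small] ** 2 - hb[~small] ** 2 / kBT / np.sinh(zl) ** 2
    return out


def wlc_stretch_energy(x, p: PolymerParams, kBT: float):
    """Entropic stretching free energy of a WLC at extension x (nm) -> kBT.

    G = (kBT L / 4P) * [3 (x/L)^2 - 2 (x/L)^3] / (1 - x/L),
    which is the exact integral of the Marko–Siggia force from 0 to x.
    """
    x = np.asarray(x, dtype=float)
    L = p.contour_length
    if L == 0.0:
        if np.any(x != 0.0):
            raise ValueError("empty chain (L=0) only admits x=0")
        return np.zeros_like(x) if x.ndim else 0.0
    if np.any(x < 0) or np.any(x >= L):
        raise ValueError("extension must satisfy 0 <= x < L")
    t = x / L
    g_pn_nm = (L / (4.0 * p.persistence_length)) * kBT * (
        (3.0 * t**2 - 2.0 * t**3) / (1.0 - t)
    )
    g = g_pn_nm / kBT  # kBT units
    return g if g.ndim else float(g)


# ---------------------------------------------------------------------------
# Force balance at fixed trap separation


def _tether_D_of_F(F, l, h, cfg: TetherConfig):
    """Trap separation that would put the system at force F (vectorized)."""
    kBT = cfg.kBT
    F = np.asarray(F, dtype=float)
    l = np.asarray(l, dtype=float)
    h = np.asarray(h, dtype=float)
    shape = np.broadcast(F, l, h).shape
    flat_F = np.broadcast_to(F, shape)
    flat_l = np.broadcast_to(l, shape)
    x_m = np.where(
        flat_l > 0,
        _wlc_extension_given_L(flat_F, flat_l, cfg.polypeptide_persistence, kBT),
        0.0,
    )
    H = _fjc_extension_arr(flat_F, np.broadcast_to(h, shape), kBT)
    x_dna = wlc_extension(flat_F, cfg.handle, kBT)
    return x_m + H + x_dna + flat_F / cfg.trap_stiffness + cfg.bead_radii_sum


def _wlc_extension_given_L(F, L, P, kBT):
    """Vectorized WLC inversion with per-element contour length L."""
    F = np.asarray(F, dtype=float)
    L = np.asarray(L, dtype=float)
    f = F * P / kBT
    t = np.minimum(2.0 * f / 3.0, 1.0 - 0.5 / np.sqrt(f + 0.25))
    t = np.clip(t, 0.0, 1.0 - 1e-15)
    for _ in range(100):
        g = 0.25 / (1.0 - t) ** 2 + t - 0.25 - f
        dg = 0.5 / (1.0 - t) ** 3 + 1.0
        t_new = np.clip(t - g / dg, 0.0, 1.0 - 1e-15)
        if np.all(np.abs(t_new - t) <= 1e-14 * (1.0 + t)):
            t = t_new
            break
        t = t_new
    return t * L


def _fjc_extension_arr(F, h, kBT):
    F = np.asarray(F, dtype=float)
    h = np.asarray(h, dtype=float)
    z = F * h / kBT
    out = np.empty(z.shape)
    small = z < 1e-3
    out[small] = np.broadcast_to(h, z.shape)[small] * (
        z[small] / 3.0 - z[small] ** 3 / 45.0
    )
    big = ~small
    out[big] = np.broadcast_to(h, z.shape)[big] / np.tanh(z[big]) - kBT / F[big]
    return out


def solve_state_force_many(
    D, l, h, cfg: TetherConfig, tol: float = 1e-9
) -> np.ndarray:
    """Vectorized force balance: find F >= 0 with D = X(F) + F/k_traps + R.

    D, l, h broadcast elementwise.  Bracketed Newton iteration on F; the
    right-hand side is strictly increasing in F so the root is unique.
    Residual tolerance ``tol`` nm.
    """
    D = np.asarray(D, dtype=float)
    l = np.asarray(l, dtype=float)
    h = np.asarray(h, dtype=float)
    shape = np.broadcast(D, l, h).shape
    D, l, h = (np.broadcast_to(a, shape).astype(float) for a in (D, l, h))
    R = cfg.bead_radii_sum
    if np.any(D < R - 1e-9):
        raise ValueError("trap separation D must be >= bead_radii_sum R")
    kBT = cfg.kBT
    P = cfg.polypeptide_persistence
    k = cfg.trap_stiffness

    lo = np.zeros(shape)
    hi = np.full(shape, F_MAX)
    F = np.full(shape, 5.0)
    slack = D <= R
    for _ in range(200):
        Dcalc = _tether_D_of_F(F, l, h, cfg)
        resid = Dcalc - D
        if np.all(np.abs(resid) < tol):
            break
        # derivative dD/dF
        t_m = np.where(l > 0, _wlc_extension_given_L(F, l, P, kBT) / np.where(l > 0, l, 1.0), 0.0)
        dxm = np.where(
            l > 0,
            1.0 / (kBT / P * (0.5 / (1.0 - t_m) ** 3 + 1.0)) * l,
            0.0,
        )
        t_d = wlc_extension(F, cfg.handle, kBT) / cfg.handle.contour_length
        dxd = 1.0 / (
            kBT / cfg.handle.persistence_length * (0.5 / (1.0 - t_d) ** 3 + 1.0)
        ) * cfg.handle.contour_length
        dH = _fjc_extension_derivative(np.maximum(F, 1e-12), h, kBT)
        dD = dxm + dxd + dH + 1.0 / k
        # update bracket
        hi = np.where(resid > 0, np.minimum(hi, F), hi)
        lo = np.where(resid < 0, np.maximum(lo, F), lo)
        F_new = F - resid / dD
        bad = (F_new <= lo) | (F_new >= hi) | ~np.isfinite(F_new)
        F_new = np.where(bad, 0.5 * (lo + hi), F_new)
        F = F_new
    else:
        resid = _tether_D_of_F(F, l, h, cfg) - D
        if np.any(np.abs(resid) >= tol):
            raise RuntimeError(
                "force balance did not converge; residual max "
                f"{np.max(np.abs(resid)):.3g} nm (F in [0, {F_MAX}] pN)"
            )
    F = np.where(slack, 0.0, F)
    return F


def solve_states_vectorized(D, l, h, cfg: TetherConfig) -> dict:
    """Solve the force balance for many states at once and return component
    extensions and energies as arrays (keys: force, extension, x_m, H,
    x_dna, g_m, g_dna, g_beads).  D, l, h broadcast elementwise."""
    kBT = cfg.kBT
    F = solve_state_force_many(D, l, h, cfg)
    shape = F.shape
    l = np.broadcast_to(np.asarray(l, float), shape)
    h = np.broadcast_to(np.asarray(h, float), shape)
    x_m = np.where(
        l > 0, _wlc_extension_given_L(F, l, cfg.polypeptide_persistence, kBT), 0.0
    )
    H = _fjc_extension_arr(F, h, kBT)
    x_dna = wlc_extension(F, cfg.handle, kBT)
    t_m = np.where(l > 0, x_m / np.where(l > 0, l, 1.0), 0.0)
    P = cfg.polypeptide_persistence
    g_m = np.where(
        l > 0,
        (l / (4.0 * P)) * (3.0 * t_m**2 - 2.0 * t_m**3) / (1.0 - t_m),
        0.0,
    )
    t_d = x_dna / cfg.handle.contour_length
    g_dna = (cfg.handle.contour_length / (4.0 * cfg.handle.persistence_length)) * (
        3.0 * t_d**2 - 2.0 * t_d**3
    ) / (1.0 - t_d)
    g_beads = F**2 / (2.0 * cfg.trap_stiffness) / kBT
    return {
        "force": F,
        "extension": x_m + H + x_dna,
        "x_m": x_m,
        "H": H,
        "x_dna": x_dna,
        "g_m": g_m,
        "g_dna": g_dna,
        "g_beads": g_beads,
    }


def solve_state_force(
    D: float, l: float, core: FoldedCore | float, cfg: TetherConfig
) -> MechanicalState:
    """Solve the force balance at trap separation D for a state with
    unfolded contour length l and folded-core size h; returns the full
    mechanical state (force, component extensions and energies)."""
    h = core.size_along_axis if isinstance(core, FoldedCore) else float(core)
    if h < 0:
        raise ValueError("folded-core size h must be >= 0 nm")
    if l < 0:
        raise ValueError("unfolded contour length l must be >= 0 nm")
    F = float(solve_state_force_many(D, l, h, cfg))
    kBT = cfg.kBT
    poly = cfg.polypeptide(l)
    x_m = wlc_extension(F, poly, kBT) if l > 0 else 0.0
    H = fjc_core_extension(F, FoldedCore(h), kBT)
    x_dna = wlc_extension(F, cfg.handle, kBT)
    g_m = wlc_stretch_energy(x_m, poly, kBT) if l > 0 else 0.0
    g_dna = wlc_stretch_energy(x_dna, cfg.handle, kBT)
    g_beads = F**2 / (2.0 * cfg.trap_stiffness) / kBT
    return MechanicalState(
        force=F,
        tether_extension=x_m + H + x_dna,
        x_polypeptide=x_m,
        core_extension=H,
        x_handle=x_dna,
        g_polypeptide=g_m,
        g_handle=g_dna,
        g_beads=g_beads,
    )


def state_total_energy(ms: MechanicalState, V: float, cfg: TetherConfig) -> float:
    """Total system energy of a solved state (kBT):

    G = G_m + V + G_DNA + F^2/(2 k_traps),

    i.e. polypeptide and handle stretching entropy, the state's zero-force
    free energy V, and the potential energy of the beads in their traps.
    Differences of G between states at the same trap separation drive
    Boltzmann populations and Kramers rates.
    """
    return ms.g_polypeptide + V + ms.g_handle + ms.g_beads
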