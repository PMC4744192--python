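"""Force–extension curve (FEC) analysis.

A pulling or relaxation ramp at constant trap speed traces the elastic
branch of whichever folding state the molecule occupies; discrete
unfolding rips (extension jumps up at nearly constant force) and refolding
zips separate the branches, and near-equilibrium transitions appear as
rapid flickering between two branches.  This module segments FECs into
branches and rips, fits each branch's unfolded contour length with the
tether model (handle parameters fixed), extracts equilibrium forces and
extension changes from flickering regions, and converts them into
unfolding work and zero-force free-energy differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.mixture import GaussianMixture

from .tether_mechanics import (
    TetherConfig,
    solve_states_vectorized,
)
from .fixtures import h_of_l
from .synthetic_data import FEC

__all__ = [
    "BranchFit",
    "RipEvent",
    "segment_fec",
    "fit_branch_contour",
    "equilibrium_from_flicker",
    "work_energy",
    "bound_state_extension_shift",
    "read_fec",
    "write_fec",
]


@dataclass
class BranchFit:
    start: int
    stop: int  # sample range [start, stop)
    contour_length: float  # nm, fitted unfolded polypeptide contour
    residual_rms: float  # nm (extension residual)
    mean_force_range: tuple[float, float]


@dataclass
class RipEvent:
    index: int  # sample index of the jump
    force: float  # pN at the rip
    extension_jump: float  # nm, positive = unfolding
    direction: str  # "unfold" | "refold"


def _smooth(a: np.ndarray, n: int) -> np.ndarray:
    """Centered running mean with shrinking windows at the edges (no
    zero-padding artifacts)."""
    if n <= 1:
        return a.copy()
    c = np.concatenate(([0.0], np.cumsum(a)))
    i = np.arange(len(a))
    lo = np.clip(i - n // 2, 0, None)
    hi = np.clip(i + n - n // 2, None, len(a))
    return (c[hi] - c[lo]) / (hi - lo)


def segment_fec(
    fec: FEC,
    jump_sd: float = 5.0,
    max_jump_time: float = 0.002,
    min_branch_points: int = 30,
    detect_filter: float = 1e-3,
) -> tuple[list[BranchFit], list[RipEvent]]:
    """Split an FEC into continuous elastic branches separated by discrete
    rips.

    Rips are detected as steps of the extension signal larger than
    ``jump_sd`` local noise SDs within at most ``max_jump_time`` seconds;
    every sample belongs to exactly one branch or one rip.  Branch contour
    lengths are not fitted here (see :func:`fit_branch_contour`); the
    returned BranchFit carries NaN contour length placeholders.
    """
    x = fec.extension
    if len(x) < 100:
        raise ValueError("need at least 100 points to segment an FEC")
    x_det = _smooth(x, max(int(detect_filter * fec.sampling_rate), 1))
    lag = max(int(max_jump_time * fec.sampling_rate), 1)
    step = x_det[lag:] - x_det[:-lag]
    # robust step SD: jumps are rare enough that the MAD ignores them
    step_sd = 1.4826 * np.median(np.abs(step - np.median(step)))
    if step_sd == 0:
        step_sd = np.std(np.diff(x)) + 1e-12
    thresh = jump_sd * step_sd
    jumpy = np.abs(step) > thresh
    # candidate rip centers: local maxima of |step| inside jumpy runs
    rips: list[RipEvent] = []
    i = 0
    while i < len(jumpy):
        if not jumpy[i]:
            i += 1
            continue
        j = i
        while j < len(jumpy) and jumpy[j]:
            j += 1
        seg = slice(i, j)
        center = i + int(np.argmax(np.abs(step[seg])))
        jump = float(step[center])
        rips.append(
            RipEvent(
                index=center + lag // 2,
                force=float(fec.force[center]),
                extension_jump=jump,
                direction="unfold" if jump > 0 else "refold",
            )
        )
        i = j
    # branches between rips
    cuts = [0]
    for r in rips:
        cuts.extend([max(r.index - lag, 0), min(r.index + lag, len(x))])
    cuts.append(len(x))
    branches = []
    for a, b in zip(cuts[::2], cuts[1::2]):
        if b - a >= min_branch_points:
            branches.append(
                BranchFit(
                    start=a,
                    stop=b,
                    contour_length=np.nan,
                    residual_rms=np.nan,
                    mean_force_range=(
                        float(np.min(fec.force[a:b])),
                        float(np.max(fec.force[a:b])),
                    ),
                )
            )
    if not branches:
        raise RuntimeError("no continuous branches found in FEC")
    return branches, rips


def fit_branch_contour(
    fec: FEC,
    branch: BranchFit,
    cfg: TetherConfig,
    h_table=h_of_l,
    l_bounds: tuple[float, float] = (0.0, 120.0),
) -> BranchFit:
    """Least-squares fit of the unfolded contour length l to one branch.

    The handle parameters stay fixed; the model extension at the measured
    force is X(F; l) with the folded-core size taken from the packaged
    h(l) table, and the residual is measured extension minus model
    extension.  Raises if the branch spans < 2 pN of force
    (non-identifiable).
    """
    sl = slice(branch.start, branch.stop)
    F = fec.force[sl]
    X = fec.extension[sl]
    if np.ptp(F) < 2.0:
        raise ValueError(
            "branch spans < 2 pN of force; contour length not identifiable"
        )
    # decimate long branches for speed
    if len(F) > 2000:
        sel = np.linspace(0, len(F) - 1, 2000).astype(int)
        F, X = F[sel], X[sel]
    kBT = cfg.kBT
    from .tether_mechanics import (
        _wlc_extension_given_L,
        _fjc_extension_arr,
        wlc_extension,
    )

    x_dna = wlc_extension(F, cfg.handle, kBT)

    def resid(params):
        (l,) = params
        h = float(h_table(l))
        x_m = (
            _wlc_extension_given_L(F, l, cfg.polypeptide_persistence, kBT)
            if l > 0
            else 0.0
        )
        H = _fjc_extension_arr(F, np.full_like(F, h), kBT)
        return x_m + H + x_dna - X

    l0 = max(np.mean(l_bounds) / 2.0, 1.0)
    sol = least_squares(resid, [l0], bounds=([l_bounds[0]], [l_bounds[1]]))
    r = resid(sol.x)
    return BranchFit(
        start=branch.start,
        stop=branch.stop,
        contour_length=float(sol.x[0]),
        residual_rms=float(np.sqrt(np.mean(r**2))),
        mean_force_range=branch.mean_force_range,
    )


def _ashman_d(means, sds):
    """Bimodality separation of a two-Gaussian fit; > 2 means resolvable."""
    return np.sqrt(2.0) * abs(means[1] - means[0]) / np.sqrt(
        sds[0] ** 2 + sds[1] ** 2
    )


def equilibrium_from_flicker(
    force: np.ndarray,
    extension: np.ndarray,
    seed: int = 0,
    kBT: float | None = None,
) -> tuple[float, float]:
    """Equilibrium force and extension change of a reversible two-state
    flickering region.

    The extension histogram is fit with two Gaussians; the extension
    change is the distance between the two Gaussian means.  The
    equilibrium force is the mean force of the folded (lower-extension)
    samples, corrected to the equal-occupancy point through the measured
    occupancy ratio: F_eq = F + kBT ln(p_folded/p_unfolded) / Δx, which
    makes the estimate independent of exactly where in the flicker the
    window was placed.  Raises if the region is not bimodal (degenerate
    Δx)."""
    from .tether_mechanics import thermal_energy

    if kBT is None:
        kBT = thermal_energy(296.0)
    force = np.asarray(force, float)
    extension = np.asarray(extension, float)
    gm = GaussianMixture(n_components=2, n_init=3, random_state=seed).fit(
        extension.reshape(-1, 1)
    )
    means = np.sort(gm.means_.ravel())
    dx = float(means[1] - means[0])
    sds = np.sqrt(gm.covariances_.reshape(-1))
    if _ashman_d(means, sds) < 2.0 or np.min(gm.weights_) < 0.01:
        raise ValueError("flicker region is not bimodal (degenerate Δx)")
    mid = 0.5 * (means[0] + means[1])
    upper = extension > mid
    if upper.all() or (~upper).all():
        raise ValueError("no occupancy of one flicker state")
    p_f = np.count_nonzero(~upper) / len(extension)
    f_folded = float(np.mean(force[~upper]))
    f_eq = f_folded + kBT * np.log(p_f / (1.0 - p_f)) / dx
    return float(f_eq), dx


def work_energy(
    F_eq: float,
    dx: float,
    l_pair: tuple[float, float],
    cfg: TetherConfig,
    h_pair: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Unfolding work and zero-force free-energy difference (kBT).

    work = F_eq * dx is the reversible mechanical work of the transition at
    the equilibrium force.  The zero-force ΔV additionally removes the
    stretching-entropy difference of the unfolded polypeptide and the
    handle/bead relaxation at fixed trap separation:

        ΔV = (G_m + G_DNA + G_beads)_folded - (...)_unfolded + 0
           = -(Δ mechanical energy at the equilibrium trap separation),

    evaluated exactly with the tether model at the trap separation where
    the two states' forces bracket F_eq.
    """
    if F_eq <= 0 or dx < 0:
        raise ValueError("need F_eq > 0 and dx >= 0")
    kBT = cfg.kBT
    work = F_eq * dx / kBT
    l_lo, l_hi = l_pair
    if h_pair is None:
        h_pair = (float(h_of_l(l_lo)), float(h_of_l(l_hi)))
    # locate the trap separation at which the folded member is at F_eq
    from scipy.optimize import brentq
    from .tether_mechanics import solve_state_force

    R = cfg.bead_radii_sum
    L = cfg.handle.contour_length
    lo_D, hi_D = R + 0.5 * L, R + 1.02 * L + l_hi + 40.0 / cfg.trap_stiffness
    D_eq = brentq(
        lambda D: solve_state_force(D, l_lo, h_pair[0], cfg).force - F_eq,
        lo_D,
        hi_D,
        xtol=1e-6,
    )
    sol = solve_states_vectorized(
        D_eq, np.array([l_lo, l_hi]), np.array(h_pair), cfg
    )
    mech = sol["g_m"] + sol["g_dna"] + sol["g_beads"]
    dV = float(mech[0] - mech[1])
    return work, dV


def bound_state_extension_shift(
    extension_baseline: np.ndarray,
    extension_bound: np.ndarray,
    reference_mean: float | None = None,
    seed: int = 0,
) -> float:
    """Extension shortening caused by ligand binding (nm, positive =
    shortening, i.e. folding-type shift).

    The bound segment is expected unimodal; its peak mean is compared with
    ``reference_mean`` (the reference state's Gaussian mean in the
    baseline segment; defaults to the baseline segment's dominant peak).
    A multimodal bound segment triggers a warning and uses the dominant
    peak."""
    def dominant_mean(x, warn_label=None):
        x = np.asarray(x, float)
        gm2 = GaussianMixture(
            n_components=2, n_init=3, random_state=seed
        ).fit(x.reshape(-1, 1))
        means2 = gm2.means_.ravel()
        sds2 = np.sqrt(gm2.covariances_.reshape(-1))
        if _ashman_d(np.sort(means2), sds2) >= 2.0 and np.min(
            gm2.weights_
        ) > 0.1:
            if warn_label:
                warnings.warn(
                    f"{warn_label} segment is multimodal; using its "
                    "dominant peak"
                )
            return float(means2[np.argmax(gm2.weights_)])
        return float(np.mean(x))

    bound_mean = dominant_mean(extension_bound, warn_label="bound")
    if reference_mean is None:
        reference_mean = dominant_mean(extension_baseline)
    return float(reference_mean - bound_mean)


# ---------------------------------------------------------------------------
# FEC I/O


def write_fec(fecs: list[FEC], path) -> None:
    frames = []
    for fec in fecs:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": fec.time,
                    "force_pN": fec.force,
                    "extension_nm": fec.extension,
                    "trap_sep_nm": fec.trap_separation,
                    "phase": fec.phase,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz\t{fecs[0].sampling_rate}\n")
        fh.write(f"# trap_speed_nm_per_s\t{abs(fecs[0].trap_speed)}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_fec(path) -> list[FEC]:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("\t")
                meta[key] = float(val)
            else:
                rows.append(line)
    import io as _io

    df = pd.read_csv(_io.StringIO("".join(rows)), sep="\t")
    fecs = []
    for phase, g in df.groupby("phase", sort=False):
        speed = meta.get("trap_speed_nm_per_s", np.nan)
        fecs.append(
            FEC(
                phase=str(phase),
                time=g["time_s"].to_numpy(),
                force=g["force_pN"].to_numpy(),
                extension=g["extension_nm"].to_numpy(),
                trap_separation=g["trap_sep_nm"].to_numpy(),
                trap_speed=speed if phase == "pull" else -speed,
                sampling_rate=meta["sampling_rate_hz"],
            )
        )
    return fecs
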