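"""Idealization of constant-trap-separation extension trajectories.

Pipeline mirroring standard single-molecule practice: boxcar mean-filter
the raw extension record, count states by fitting the extension histogram
with a Gaussian mixture (BIC model selection), fit a Gaussian-emission
hidden Markov model by expectation–maximization, idealize with the Viterbi
algorithm, and read populations, dwell times and transition rates off the
idealized path.  A separate detector flags rare long-dwell intervals that
are inconsistent with every baseline state (ligand-bound states).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from sklearn.mixture import GaussianMixture

__all__ = [
    "Trajectory",
    "GaussianMixtureFit",
    "HMMResult",
    "BoundStateReport",
    "mean_filter",
    "fit_extension_histogram",
    "fit_hmm",
    "viterbi",
    "dwell_and_rates",
    "detect_rare_bound_states",
    "read_trajectory",
    "write_trajectory",
]


@dataclass
class Trajectory:
    """Uniformly sampled extension/force record at fixed trap separation."""

    time: np.ndarray  # s
    extension: np.ndarray  # nm
    force: np.ndarray  # pN
    trap_separation: float  # nm
    sampling_rate: float  # Hz
    filter_window: float = 0.0  # s, 0 = unfiltered

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.extension = np.asarray(self.extension, float)
        self.force = np.asarray(self.force, float)
        if len(self.extension) != len(self.force) or len(self.time) != len(
            self.extension
        ):
            raise ValueError("time, extension and force must be equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0 Hz")

    @property
    def duration(self) -> float:
        return len(self.extension) / self.sampling_rate

    def __len__(self) -> int:
        return len(self.extension)


@dataclass
class GaussianMixtureFit:
    n_components: int
    means: np.ndarray  # nm, sorted ascending
    sds: np.ndarray  # nm
    weights: np.ndarray  # sum to 1
    bic: float
    bic_by_n: dict = field(default_factory=dict)


@dataclass
class HMMResult:
    n_states: int
    means: np.ndarray  # nm, emission mean per state (ascending)
    sds: np.ndarray  # nm
    transmat: np.ndarray  # per-sample transition probabilities
    startprob: np.ndarray
    log_likelihood: float
    log_likelihood_history: np.ndarray
    converged: bool
    sampling_rate: float
    viterbi_path: np.ndarray | None = None
    populations: np.ndarray | None = None
    dwell_times: list | None = None  # list of arrays, per state (s)
    mean_dwell: np.ndarray | None = None  # s, NaN where undefined
    rate_matrix: np.ndarray | None = None  # 1/s, NaN where undefined
    visited: np.ndarray | None = None  # bool per state


@dataclass
class BoundStateReport:
    intervals: list  # (t_start, t_end) seconds
    occurrence_rate: float  # events / total time, 1/s
    mean_dwell: float  # s, NaN if no events


# ---------------------------------------------------------------------------


def mean_filter(tr: Trajectory, window: float) -> Trajectory:
    """Boxcar-average the trajectory over ``window`` seconds and decimate to
    the window rate.  window of exactly one sample is the identity."""
    n = int(round(window * tr.sampling_rate))
    if n < 1:
        raise ValueError("filter window shorter than one sample")
    if n == 1:
        return replace(tr, filter_window=window)
    m = len(tr) // n
    if m == 0:
        raise ValueError("trajectory shorter than one filter window")

    def box(a):
        return a[: m * n].reshape(m, n).mean(axis=1)

    return Trajectory(
        time=box(tr.time),
        extension=box(tr.extension),
        force=box(tr.force),
        trap_separation=tr.trap_separation,
        sampling_rate=tr.sampling_rate / n,
        filter_window=window,
    )


def fit_extension_histogram(
    tr: Trajectory,
    n_range=range(1, 7),
    seed: int = 0,
    max_samples: int = 50_000,
    min_separation_sd: float = 2.0,
) -> GaussianMixtureFit:
    """Count folding states by fitting the extension distribution with a
    sum of Gaussians; the number of components is chosen by BIC over
    ``n_range``.  Components closer than ``min_separation_sd`` pooled
    standard deviations are merged (unidentifiable splits)."""
    x = tr.extension
    if len(x) < 1000:
        raise ValueError("need >= 1000 samples to fit the extension histogram")
    if np.std(x) == 0:
        raise ValueError("degenerate (zero-variance) extension data")
    rng = np.random.default_rng(seed)
    if len(x) > max_samples:
        x = rng.choice(x, size=max_samples, replace=False)
    X = x.reshape(-1, 1)
    best = None
    bic_by_n: dict = {}
    for n in n_range:
        gm = GaussianMixture(
            n_components=n,
            covariance_type="full",
            n_init=3,
            random_state=seed,
            reg_covar=1e-4,
        ).fit(X)
        bic = gm.bic(X)
        bic_by_n[n] = bic
        if best is None or bic < best[0]:
            best = (bic, gm)
    bic, gm = best
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.reshape(-1)[order])
    weights = gm.weights_[order]
    # merge indistinguishable components
    merged_m, merged_s, merged_w = [means[0]], [sds[0]], [weights[0]]
    for mu, sd, w in zip(means[1:], sds[1:], weights[1:]):
        pooled = np.sqrt(0.5 * (merged_s[-1] ** 2 + sd**2))
        if mu - merged_m[-1] < min_separation_sd * pooled:
            tot = merged_w[-1] + w
            merged_m[-1] = (merged_m[-1] * merged_w[-1] + mu * w) / tot
            merged_s[-1] = np.sqrt(
                (merged_s[-1] ** 2 * merged_w[-1] + sd**2 * w) / tot
            )
            merged_w[-1] = tot
        else:
            merged_m.append(mu)
            merged_s.append(sd)
            merged_w.append(w)
    return GaussianMixtureFit(
        n_components=len(merged_m),
        means=np.array(merged_m),
        sds=np.array(merged_s),
        weights=np.array(merged_w) / np.sum(merged_w),
        bic=bic,
        bic_by_n=bic_by_n,
    )


def _build_model(
    n_states: int,
    means: np.ndarray,
    sds: np.ndarray,
    transmat: np.ndarray | None,
    startprob: np.ndarray | None,
) -> GaussianHMM:
    model = GaussianHMM(
        n_components=n_states,
        covariance_type="diag",
        init_params="",
        params="stmc",
        n_iter=0,
    )
    model.means_ = np.asarray(means, float).reshape(-1, 1)
    model.covars_ = np.asarray(sds, float).reshape(-1, 1) ** 2
    if transmat is None:
        transmat = np.full((n_states, n_states), 0.01 / max(n_states - 1, 1))
        np.fill_diagonal(transmat, 0.0)
        np.fill_diagonal(transmat, 1.0 - transmat.sum(axis=1))
    model.transmat_ = np.asarray(transmat, float)
    if startprob is None:
        startprob = np.full(n_states, 1.0 / n_states)
    model.startprob_ = np.asarray(startprob, float)
    return model


def fit_hmm(
    tr: Trajectory,
    n_states: int,
    init: GaussianMixtureFit | None = None,
    init_means: np.ndarray | None = None,
    seed: int = 0,
    max_iter: int = 500,
    tol_per_sample: float = 1e-8,
    decode: bool = True,
) -> HMMResult:
    """Fit a Gaussian-emission HMM to the (filtered) extension record by
    expectation–maximization and idealize with Viterbi.

    The log-likelihood is non-decreasing over EM iterations; convergence is
    declared when the per-sample improvement drops below
    ``tol_per_sample``.  Non-convergence returns the partial result with a
    warning flag rather than raising.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    X = tr.extension.reshape(-1, 1)
    if init_means is not None:
        means0 = np.sort(np.asarray(init_means, float))
        spread = np.std(tr.extension)
        sds0 = np.full(n_states, max(spread / max(n_states, 2), 0.3))
    elif init is not None and init.n_components == n_states:
        means0, sds0 = init.means, init.sds
    else:
        gm = GaussianMixture(
            n_components=n_states, n_init=3, random_state=seed, reg_covar=1e-4
        ).fit(X)
        order = np.argsort(gm.means_.ravel())
        means0 = gm.means_.ravel()[order]
        sds0 = np.sqrt(gm.covariances_.reshape(-1)[order])

    model = _build_model(n_states, means0, sds0, None, None)
    model.n_iter = max_iter
    model.tol = tol_per_sample * len(X)
    model.random_state = seed
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X)
    history = np.array(model.monitor_.history, float)
    converged = bool(model.monitor_.converged)
    if not converged:
        warnings.warn("HMM EM did not converge; returning partial result")

    order = np.argsort(model.means_.ravel())
    means = model.means_.ravel()[order]
    sds = np.sqrt(model.covars_.reshape(-1)[order])
    transmat = model.transmat_[np.ix_(order, order)]
    startprob = model.startprob_[order]
    logL = float(model.score(X))
    res = HMMResult(
        n_states=n_states,
        means=means,
        sds=sds,
        transmat=transmat,
        startprob=startprob,
        log_likelihood=logL,
        log_likelihood_history=history,
        converged=converged,
        sampling_rate=tr.sampling_rate,
    )
    if decode:
        res.viterbi_path = viterbi(tr, res)
        pops, dwells, rates, visited = dwell_and_rates(
            res.viterbi_path, tr.sampling_rate, n_states=n_states
        )
        res.populations = pops
        res.dwell_times = dwells
        res.mean_dwell = np.array(
            [np.mean(d) if len(d) else np.nan for d in dwells]
        )
        res.rate_matrix = rates
        res.visited = visited
    return res


def viterbi(tr: Trajectory, hmm: HMMResult) -> np.ndarray:
    """Most probable state path under the fitted model (Viterbi).

    Ties are broken toward the lower state index (states sorted by
    ascending emission mean).
    """
    model = _build_model(
        hmm.n_states, hmm.means, hmm.sds, hmm.transmat, hmm.startprob
    )
    _, path = model.decode(tr.extension.reshape(-1, 1), algorithm="viterbi")
    return path


def dwell_and_rates(
    path: np.ndarray, sampling_rate: float, n_states: int | None = None
):
    """Populations, dwell-time lists and the rate matrix of an idealized
    path.

    population_i = occupancy fraction; rate(i->j) = (number of i->j
    transitions) / (total time in i); mean lifetime = mean dwell.  Dwells
    censored by the trace ends are excluded from the dwell lists.  States
    never visited get NaN rates (flagged via the returned ``visited``
    mask), not zero.
    """
    path = np.asarray(path)
    if n_states is None:
        n_states = int(path.max()) + 1 if len(path) else 0
    dt = 1.0 / sampling_rate
    counts = np.bincount(path, minlength=n_states).astype(float)
    populations = counts / counts.sum()
    visited = counts > 0

    # run-length encode
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(path)]))
    run_states = path[starts]
    run_len = (ends - starts) * dt

    dwells = [
        run_len[1:-1][run_states[1:-1] == s] if len(run_states) > 2 else np.array([])
        for s in range(n_states)
    ]
    n_trans = np.zeros((n_states, n_states))
    for a, b in zip(run_states[:-1], run_states[1:]):
        n_trans[a, b] += 1
    time_in = counts * dt
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = n_trans / time_in[:, None]
    rates[~visited, :] = np.nan
    np.fill_diagonal(rates, 0.0)
    return populations, dwells, rates, visited


def detect_rare_bound_states(
    tr: Trajectory,
    hmm: HMMResult,
    z_threshold: float = 4.0,
    min_duration: float = 0.030,
) -> BoundStateReport:
    """Flag contiguous intervals whose extension is inconsistent with every
    baseline HMM state (|x - mu_k| > z_threshold * sd_k for all k) lasting
    at least ``min_duration`` seconds; report occurrence rate (events per
    total time) and mean dwell."""
    x = tr.extension
    z = np.abs(x[:, None] - hmm.means[None, :]) / hmm.sds[None, :]
    outlier = np.all(z > z_threshold, axis=1)
    dt = 1.0 / tr.sampling_rate
    # runs of consecutive outliers
    change = np.flatnonzero(np.diff(outlier.astype(int)))
    bounds = np.concatenate(([0], change + 1, [len(x)]))
    intervals = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if outlier[a] and (b - a) * dt >= min_duration:
            intervals.append((a * dt, b * dt))
    total_time = len(x) * dt
    rate = len(intervals) / total_time
    mean_dwell = (
        float(np.mean([b - a for a, b in intervals])) if intervals else np.nan
    )
    return BoundStateReport(
        intervals=intervals, occurrence_rate=rate, mean_dwell=mean_dwell
    )


# ---------------------------------------------------------------------------
# Trajectory I/O: tab-separated with a '#'-prefixed header block


def write_trajectory(tr: Trajectory, path) -> None:
    header = (
        f"# trap_sep_nm\t{tr.trap_separation}\n"
        f"# sampling_rate_hz\t{tr.sampling_rate}\n"
        f"# filter_window_s\t{tr.filter_window}\n"
    )
    df = pd.DataFrame(
        {
            "time_s": tr.time,
            "extension_nm": tr.extension,
            "force_pN": tr.force,
        }
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_trajectory(path) -> Trajectory:
    meta = {}
    with open(path) as fh:
        text = fh.read()
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("\t")
            meta[key] = float(val)
        else:
            body_lines.append(line)
    df = pd.read_csv(io.StringIO("\n".join(body_lines)), sep="\t")
    return Trajectory(
        time=df["time_s"].to_numpy(),
        extension=df["extension_nm"].to_numpy(),
        force=df["force_pN"].to_numpy(),
        trap_separation=meta.get("trap_sep_nm", np.nan),
        sampling_rate=meta["sampling_rate_hz"],
        filter_window=meta.get("filter_window_s", 0.0),
    )
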