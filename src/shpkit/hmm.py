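"""Two-state Gaussian-emission hidden Markov analysis of binding trajectories.

Segments per-molecule intensity time series into UNBOUND/BOUND states
(Baum-Welch fitting, Viterbi decoding), extracts dwell times with
censoring flags, and converts uncensored dwell means into kinetic rates.

State 0 is UNBOUND, state 1 is BOUND; the label convention
mu_bound > mu_unbound is enforced after fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import (
    DegenerateDataError,
    InsufficientDwellsError,
    InvalidParameterError,
)

UNBOUND, BOUND = 0, 1

#: frame interval at the 20 Hz acquisition rate
DEFAULT_FRAME_INTERVAL_S = 0.05

_VAR_FLOOR = 1e-10


@dataclass
class Trajectory:
    """Per-molecule intensity time series."""

    intensities: np.ndarray
    frame_interval: float = DEFAULT_FRAME_INTERVAL_S
    molecule_id: str = "mol0"

    def __post_init__(self):
        y = np.asarray(self.intensities, dtype=float)
        if y.size < 10:
            raise InvalidParameterError("trajectory needs >= 10 frames")
        if not np.all(np.isfinite(y)):
            raise InvalidParameterError("trajectory contains non-finite values")
        if self.frame_interval <= 0:
            raise InvalidParameterError("frame_interval must be positive")
        self.intensities = y

    def __len__(self) -> int:
        return self.intensities.size

    @property
    def duration_s(self) -> float:
        return len(self) * self.frame_interval

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self)) * self.frame_interval


@dataclass
class HMMParams:
    """Two-state Gaussian-emission HMM parameters (state 0 = UNBOUND)."""

    means: np.ndarray        # (2,)
    sds: np.ndarray          # (2,)
    transmat: np.ndarray     # (2, 2) row-stochastic
    startprob: np.ndarray    # (2,)

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.startprob = np.asarray(self.startprob, dtype=float)
        if self.means[BOUND] <= self.means[UNBOUND]:
            raise InvalidParameterError("label convention requires mu_bound > mu_unbound")
        if np.any(self.sds <= 0):
            raise InvalidParameterError("state s.d. must be positive")
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-12):
            raise InvalidParameterError("transition matrix rows must sum to 1")
        if not np.isclose(self.startprob.sum(), 1.0, atol=1e-12):
            raise InvalidParameterError("initial distribution must sum to 1")

    @property
    def mu_unbound(self) -> float:
        return float(self.means[UNBOUND])

    @property
    def mu_bound(self) -> float:
        return float(self.means[BOUND])


@dataclass
class HMMFit:
    """Baum-Welch result: parameters plus the EM log-likelihood trace."""

    params: HMMParams
    log_likelihoods: np.ndarray
    converged: bool
    n_iter: int


@dataclass
class StateSequence:
    """Decoded per-frame labels with the decoding log-likelihood."""

    states: np.ndarray
    log_likelihood: float
    frame_interval: float = DEFAULT_FRAME_INTERVAL_S

    def __len__(self) -> int:
        return self.states.size


@dataclass
class DwellTimes:
    """Dwell durations (s) per state with first/last censoring flags."""

    bound_s: np.ndarray
    unbound_s: np.ndarray
    bound_censored: np.ndarray     # bool, aligned with bound_s
    unbound_censored: np.ndarray

    def uncensored(self, state: int) -> np.ndarray:
        if state == BOUND:
            return self.bound_s[~self.bound_censored]
        return self.unbound_s[~self.unbound_censored]


@dataclass
class KineticRates:
    """Pseudo-first-order binding kinetics from uncensored dwell means."""

    k_off: float
    k_on_eff: float
    k_off_stderr: float
    k_on_stderr: float
    n_bound_dwells: int
    n_unbound_dwells: int


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _log_gauss(y: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """(T, 2) per-frame emission log densities."""
    y = y[:, None]
    return (
        -0.5 * np.log(2 * np.pi * sds**2)
        - 0.5 * (y - means) ** 2 / sds**2
    )


def _forward_backward(logb, log_a, log_pi):
    """Scaled-free log-space forward-backward; returns (gamma, xi_sum, loglik)."""
    T = logb.shape[0]
    la = np.empty((T, 2))
    la[0] = log_pi + logb[0]
    for t in range(1, T):
        la[t] = logb[t] + _logsumexp2(la[t - 1][:, None] + log_a)
    loglik = _logsumexp1(la[T - 1])

    lb = np.zeros((T, 2))
    for t in range(T - 2, -1, -1):
        lb[t] = _logsumexp_rows(log_a + (logb[t + 1] + lb[t + 1])[None, :])
    gamma = np.exp(la + lb - loglik)

    # expected transition counts summed over t
    xi_sum = np.zeros((2, 2))
    for t in range(T - 1):
        m = la[t][:, None] + log_a + (logb[t + 1] + lb[t + 1])[None, :] - loglik
        xi_sum += np.exp(m)
    return gamma, xi_sum, loglik


def _logsumexp1(v):
    m = np.max(v)
    return m + np.log(np.sum(np.exp(v - m)))


def _logsumexp2(m):
    mx = np.max(m, axis=0)
    return mx + np.log(np.sum(np.exp(m - mx), axis=0))


def _logsumexp_rows(m):
    mx = np.max(m, axis=1, keepdims=True)
    return (mx + np.log(np.sum(np.exp(m - mx), axis=1, keepdims=True))).ravel()


def _two_means_init(pooled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 2-means split of pooled intensities (Lloyd from the
    10th/90th percentiles). Returns (means, sds) in ascending-mean order."""
    lo, hi = np.percentile(pooled, [10.0, 90.0])
    if hi <= lo:
        raise DegenerateDataError("single-level data; cannot initialize two states")
    centers = np.array([lo, hi], dtype=float)
    for _ in range(100):
        assign = np.abs(pooled[:, None] - centers).argmin(axis=1)
        new = np.array([
            pooled[assign == k].mean() if np.any(assign == k) else centers[k]
            for k in range(2)
        ])
        if np.allclose(new, centers):
            break
        centers = new
    assign = np.abs(pooled[:, None] - centers).argmin(axis=1)
    sds = np.array([
        pooled[assign == k].std() if np.sum(assign == k) > 1 else 0.0
        for k in range(2)
    ])
    sds = np.maximum(sds, 1e-3 * max(centers[1] - centers[0], 1.0))
    order = np.argsort(centers)
    return centers[order], sds[order]


def fit_hmm(
    trajs: Sequence[Trajectory],
    init_strategy: str = "two_means",
    init_params: HMMParams | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> HMMFit:
    """Baum-Welch maximum likelihood for the two-state Gaussian HMM.

    Deterministic given the data: initialization is a 2-means split of the
    pooled intensities (no random restarts). The per-iteration total
    log-likelihood is non-decreasing; convergence is declared when its
    relative change drops below ``tol``.
    """
    ys = [np.asarray(t.intensities, dtype=float) for t in trajs]
    if sum(len(y) for y in ys) < 200:
        raise InvalidParameterError("need >= 200 pooled frames to fit")
    pooled = np.concatenate(ys)
    if pooled.std() == 0:
        raise DegenerateDataError("single-level data; degenerate fit")

    if init_strategy == "two_means":
        means, sds = _two_means_init(pooled)
        a = np.array([[0.95, 0.05], [0.05, 0.95]])
        pi = np.array([0.5, 0.5])
    elif init_strategy == "explicit":
        if init_params is None:
            raise InvalidParameterError("init_strategy='explicit' requires init_params")
        means = init_params.means.copy()
        sds = init_params.sds.copy()
        a = init_params.transmat.copy()
        pi = init_params.startprob.copy()
    else:
        raise InvalidParameterError(f"unknown init_strategy {init_strategy!r}")

    logliks = []
    converged = False
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        log_a = np.log(np.clip(a, 1e-300, None))
        log_pi = np.log(np.clip(pi, 1e-300, None))

        total_ll = 0.0
        g_sum = np.zeros(2)
        gy_sum = np.zeros(2)
        gyy_sum = np.zeros(2)
        xi_total = np.zeros((2, 2))
        pi_new = np.zeros(2)
        for y in ys:
            logb = _log_gauss(y, means, sds)
            gamma, xi_sum, ll = _forward_backward(logb, log_a, log_pi)
            total_ll += ll
            g_sum += gamma.sum(axis=0)
            gy_sum += gamma.T @ y
            gyy_sum += gamma.T @ (y**2)
            xi_total += xi_sum
            pi_new += gamma[0]

        logliks.append(total_ll)
        if it > 0:
            prev = logliks[-2]
            if abs(total_ll - prev) <= tol * max(abs(prev), 1.0):
                converged = True
                break

        # M step
        means = gy_sum / g_sum
        var = gyy_sum / g_sum - means**2
        sds = np.sqrt(np.maximum(var, _VAR_FLOOR))
        a = xi_total / xi_total.sum(axis=1, keepdims=True)
        pi = pi_new / pi_new.sum()

    if means[BOUND] < means[UNBOUND]:  # restore label convention
        means = means[::-1].copy()
        sds = sds[::-1].copy()
        a = a[::-1, ::-1].copy()
        pi = pi[::-1].copy()

    params = HMMParams(means=means, sds=sds, transmat=a, startprob=pi)
    return HMMFit(
        params=params,
        log_likelihoods=np.asarray(logliks),
        converged=converged,
        n_iter=n_iter,
    )


def viterbi_decode(traj: Trajectory, params: HMMParams) -> StateSequence:
    """Most-probable state path; ties broken toward UNBOUND."""
    y = traj.intensities
    logb = _log_gauss(y, params.means, params.sds)
    log_a = np.log(np.clip(params.transmat, 1e-300, None))
    log_pi = np.log(np.clip(params.startprob, 1e-300, None))

    T = len(y)
    delta = np.empty((T, 2))
    psi = np.zeros((T, 2), dtype=np.int8)
    delta[0] = log_pi + logb[0]
    for t in range(1, T):
        cand = delta[t - 1][:, None] + log_a          # cand[i, j]
        # argmax over i with ties toward UNBOUND (index 0)
        best = np.where(cand[1] > cand[0], 1, 0)
        psi[t] = best
        delta[t] = cand[best, [0, 1]] + logb[t]

    states = np.empty(T, dtype=np.int8)
    states[T - 1] = BOUND if delta[T - 1, BOUND] > delta[T - 1, UNBOUND] else UNBOUND
    for t in range(T - 2, -1, -1):
        states[t] = psi[t + 1][states[t + 1]]
    ll = float(delta[T - 1].max())
    return StateSequence(states=states, log_likelihood=ll,
                         frame_interval=traj.frame_interval)


def dwell_times(seq: StateSequence, frame_interval: float | None = None) -> DwellTimes:
    """Run-length encoding of a state sequence into dwell durations.

    The first and last dwells are flagged censored (their true extent is
    clipped by the acquisition window); the dwell sum equals the
    trajectory duration exactly.
    """
    dt = frame_interval if frame_interval is not None else seq.frame_interval
    s = np.asarray(seq.states)
    change = np.flatnonzero(np.diff(s)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [s.size]))
    runs = ends - starts
    run_states = s[starts]

    bound, unbound, bc, uc = [], [], [], []
    n_runs = len(runs)
    for i, (length, state) in enumerate(zip(runs, run_states)):
        censored = i == 0 or i == n_runs - 1
        if state == BOUND:
            bound.append(length * dt)
            bc.append(censored)
        else:
            unbound.append(length * dt)
            uc.append(censored)
    return DwellTimes(
        bound_s=np.asarray(bound, dtype=float),
        unbound_s=np.asarray(unbound, dtype=float),
        bound_censored=np.asarray(bc, dtype=bool),
        unbound_censored=np.asarray(uc, dtype=bool),
    )


def pool_dwells(dwell_list: Sequence[DwellTimes]) -> DwellTimes:
    """Concatenate dwell sets from many trajectories."""
    return DwellTimes(
        bound_s=np.concatenate([d.bound_s for d in dwell_list]),
        unbound_s=np.concatenate([d.unbound_s for d in dwell_list]),
        bound_censored=np.concatenate([d.bound_censored for d in dwell_list]),
        unbound_censored=np.concatenate([d.unbound_censored for d in dwell_list]),
    )


def estimate_rates(dwells: DwellTimes, min_dwells: int = 10) -> KineticRates:
    """Rates from uncensored exponential dwell means.

    k_off = 1/mean(bound dwells); k_on_eff = 1/mean(unbound dwells);
    standard errors follow the exponential-mean formula k/sqrt(n).
    Dwell-time discretization biases estimates when mean dwells approach
    ~2 frame intervals.
    """
    bound = dwells.uncensored(BOUND)
    unbound = dwells.uncensored(UNBOUND)
    if bound.size < min_dwells:
        raise InsufficientDwellsError(
            f"only {bound.size} uncensored BOUND dwells (need {min_dwells})")
    if unbound.size < min_dwells:
        raise InsufficientDwellsError(
            f"only {unbound.size} uncensored UNBOUND dwells (need {min_dwells})")
    k_off = 1.0 / bound.mean()
    k_on = 1.0 / unbound.mean()
    return KineticRates(
        k_off=float(k_off),
        k_on_eff=float(k_on),
        k_off_stderr=float(k_off / np.sqrt(bound.size)),
        k_on_stderr=float(k_on / np.sqrt(unbound.size)),
        n_bound_dwells=int(bound.size),
        n_unbound_dwells=int(unbound.size),
    )
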