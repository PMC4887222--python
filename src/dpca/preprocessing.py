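"""Spike-train preprocessing: smoothing, time warping, PSTHs, noise covariance.

Raw data are per-trial spike-time lists recorded under a factorial task design
(stimulus x decision).  This module turns them into trial-resolved firing-rate
tensors on a common time grid, trial-averaged PSTHs, and an estimate of the
trial-to-trial noise covariance -- the three ingredients the demixing
decomposition works with.

Conventions: time in seconds, rates in spikes/s, the time grid uses bin
centers with t=0 at the first alignment event.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = [
    "Trial",
    "SpikeTrainSet",
    "TrialTensor",
    "PsthTensor",
    "NoiseCovariance",
    "smooth_spike_trains",
    "warp_trial",
    "reference_events_from_medians",
    "compute_psths",
    "estimate_noise_covariance",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Trial:
    """A single trial of one neuron: spike times plus alignment events."""

    spike_times: np.ndarray          # seconds, within [start, end]
    start: float
    end: float
    event_times: np.ndarray          # alignment events, non-decreasing; NaN = absent
    correct: bool = True

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.event_times = np.asarray(self.event_times, dtype=float)
        if self.spike_times.size:
            lo, hi = self.spike_times.min(), self.spike_times.max()
            if lo < self.start - 1e-12 or hi > self.end + 1e-12:
                raise ValueError(
                    f"spike times outside trial window [{self.start}, {self.end}]"
                )
        ev = self.event_times[np.isfinite(self.event_times)]
        if ev.size and np.any(np.diff(ev) < -1e-12):
            raise ValueError("event times must be non-decreasing within a trial")


@dataclass
class SpikeTrainSet:
    """Spike trains of N sequentially recorded neurons under an S x Q design.

    ``trials[(n, s, d)]`` is the list of trials of neuron ``n`` under stimulus
    ``s`` and decision ``d``.  Every (neuron, condition) cell used for the
    demixing analysis must contain at least one trial.
    """

    trials: Dict[Tuple[int, int, int], List[Trial]]
    n_neurons: int
    n_stimuli: int
    n_decisions: int

    def get(self, n: int, s: int, d: int) -> List[Trial]:
        return self.trials.get((n, s, d), [])

    def validate(self) -> None:
        for n in range(self.n_neurons):
            for s in range(self.n_stimuli):
                for d in range(self.n_decisions):
                    if not self.get(n, s, d):
                        raise ValueError(
                            f"neuron {n} has no trial for condition (s={s}, d={d}); "
                            "all parameter combinations must be present"
                        )


@dataclass
class TrialTensor:
    """Trial-resolved rate tensor ``values[n, s, d, t, k]`` in spikes/s.

    Trial counts are unequal across conditions; slots with ``k >=
    trial_counts[n, s, d]`` are NaN-padded.  ``time`` holds the bin centers in
    seconds.
    """

    values: np.ndarray               # (N, S, Q, T, Kmax), NaN beyond counts
    trial_counts: np.ndarray         # (N, S, Q) ints >= 1
    time: np.ndarray                 # (T,)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.trial_counts = np.asarray(self.trial_counts, dtype=int)
        self.time = np.asarray(self.time, dtype=float)
        if self.values.ndim != 5:
            raise ValueError("values must be 5-dimensional (N, S, Q, T, Kmax)")
        N, S, Q, T, K = self.values.shape
        if self.trial_counts.shape != (N, S, Q):
            raise ValueError("trial_counts shape must match (N, S, Q)")
        if self.time.shape != (T,):
            raise ValueError("time grid length must match T")
        if np.any(self.trial_counts < 1):
            bad = np.argwhere(self.trial_counts < 1)[0]
            raise ValueError(
                f"condition (n={bad[0]}, s={bad[1]}, d={bad[2]}) has no trials; "
                "all parameter combinations must be present"
            )
        if np.any(self.trial_counts > K):
            raise ValueError("trial_counts exceed the trial axis length")
        mask = self.trial_mask()
        if not np.all(np.isfinite(self.values[mask])):
            raise ValueError("non-finite rate inside the valid trial range")

    @property
    def shape(self) -> Tuple[int, int, int, int, int]:
        return self.values.shape

    def trial_mask(self) -> np.ndarray:
        """Boolean mask of shape ``values.shape``: True where a trial exists."""
        K = self.values.shape[4]
        k = np.arange(K)
        mask = (k[None, None, None, None, :]
                < self.trial_counts[:, :, :, None, None])
        return np.broadcast_to(mask, self.values.shape)

    def is_balanced(self) -> bool:
        return bool(np.all(self.trial_counts == self.trial_counts.flat[0]))


@dataclass
class PsthTensor:
    """Trial-averaged rates ``values[n, s, d, t]`` (PSTHs).

    When ``centered`` each neuron's grand mean over (s, d, t) has been
    subtracted and is kept in ``means`` so single trials can be centered
    consistently.
    """

    values: np.ndarray               # (N, S, Q, T)
    time: np.ndarray
    centered: bool = False
    means: Optional[np.ndarray] = None   # (N,) row means if centered

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("values must be 4-dimensional (N, S, Q, T)")
        if self.centered:
            if self.means is None:
                raise ValueError("centered PSTH must store its row means")
            resid = self.values.mean(axis=(1, 2, 3))
            if np.max(np.abs(resid)) > 1e-8 * max(1.0, np.abs(self.values).max()):
                raise ValueError("centered flag set but per-neuron means are nonzero")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> Tuple[int, int, int, int]:
        return self.values.shape

    def matrix(self) -> np.ndarray:
        """The N x (S*Q*T) PSTH matrix."""
        return self.values.reshape(self.values.shape[0], -1)


@dataclass
class NoiseCovariance:
    """Trial-to-trial noise covariance across neurons.

    ``mode='diagonal'`` stores only per-neuron variances (the only option for
    sequentially recorded data, where cross-neuron noise correlations cannot
    be estimated); ``mode='full'`` stores the N x N matrix.  ``rebalanced``
    means the per-condition covariances were averaged with equal weight,
    irrespective of trial counts.
    """

    matrix: np.ndarray               # (N, N)
    mode: str                        # 'diagonal' | 'full'
    rebalanced: bool
    mean_trial_counts: np.ndarray    # (N,) average K_nsd over conditions

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.mode not in ("diagonal", "full"):
            raise ValueError("mode must be 'diagonal' or 'full'")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("covariance must be square")
        if np.max(np.abs(self.matrix - self.matrix.T)) > 1e-10 * max(
            1.0, np.abs(self.matrix).max()
        ):
            raise ValueError("covariance must be symmetric")
        if np.any(np.diag(self.matrix) < -1e-12):
            raise ValueError("negative noise variance")

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.matrix)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def smooth_spike_trains(
    spikes: SpikeTrainSet,
    sigma_ms: float = 50.0,
    rate_hz: float = 100.0,
    window: Optional[Tuple[float, float]] = None,
) -> TrialTensor:
    """Convolve each spike train with a Gaussian kernel, sampled on a grid.

    Each spike contributes a Gaussian density of SD ``sigma_ms`` (truncated at
    +/- 4 sigma, tails not renormalized), so the trace integrates to the spike
    count and is in spikes/s.  The grid runs at ``rate_hz`` over ``window``
    (default: the intersection of all trial windows), using bin centers.

    Trials are aligned on their first alignment event: spike and event times
    are shifted so the first event sits at t=0 before evaluation.
    """
    if sigma_ms <= 0:
        raise ValueError("sigma_ms must be positive")
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    spikes.validate()

    sigma = sigma_ms / 1000.0
    dt = 1.0 / rate_hz

    def _t0(tr: Trial) -> float:
        ev = tr.event_times[np.isfinite(tr.event_times)]
        return float(ev[0]) if ev.size else 0.0

    if window is None:
        starts, ends = [], []
        for trs in spikes.trials.values():
            for tr in trs:
                t0 = _t0(tr)
                starts.append(tr.start - t0)
                ends.append(tr.end - t0)
        lo, hi = max(starts), min(ends)
    else:
        lo, hi = window
    n_bins = int(np.floor((hi - lo) * rate_hz))
    if n_bins < 1:
        raise ValueError("empty time grid: trial windows do not overlap")
    time = lo + dt / 2 + dt * np.arange(n_bins)

    N, S, Q = spikes.n_neurons, spikes.n_stimuli, spikes.n_decisions
    counts = np.zeros((N, S, Q), dtype=int)
    for (n, s, d), trs in spikes.trials.items():
        counts[n, s, d] = len(trs)
    Kmax = int(counts.max())

    values = np.full((N, S, Q, n_bins, Kmax), np.nan)
    norm = 1.0 / (sigma * np.sqrt(2 * np.pi))
    for (n, s, d), trs in spikes.trials.items():
        for k, tr in enumerate(trs):
            t0 = _t0(tr)
            trace = np.zeros(n_bins)
            for ts in tr.spike_times - t0:
                u = (time - ts) / sigma
                sel = np.abs(u) <= 4.0
                trace[sel] += norm * np.exp(-0.5 * u[sel] ** 2)
            values[n, s, d, :, k] = trace
    return TrialTensor(values=values, trial_counts=counts, time=time)


# ---------------------------------------------------------------------------
# time warping
# ---------------------------------------------------------------------------

def warp_trial(
    trace: np.ndarray,
    times: np.ndarray,
    trial_events: np.ndarray,
    reference_events: np.ndarray,
    out_times: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Piecewise-linearly stretch a rate trace to align trial events.

    Time on each segment ``[t_i, t_{i+1}]`` is mapped linearly onto
    ``[T_i, T_{i+1}]`` and the trace resampled by linear interpolation, so the
    warped trace at each reference event equals the original trace at the
    corresponding trial event.  Returns ``(warped, out_times)`` defined on the
    reference grid (default: same sampling step as ``times``).
    """
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    te = np.asarray(trial_events, dtype=float)
    re = np.asarray(reference_events, dtype=float)
    if te.size != re.size or te.size < 2:
        raise ValueError("need the same number (>= 2) of trial and reference events")
    if np.any(np.diff(te) <= 0) or np.any(np.diff(re) <= 0):
        raise ValueError("alignment events must be strictly increasing "
                         "(degenerate or non-monotone segment)")
    if te[0] < times[0] - 1e-9 or te[-1] > times[-1] + 1e-9:
        raise ValueError("trace does not cover the trial's event span")
    if out_times is None:
        step = times[1] - times[0]
        out_times = re[0] + step * np.arange(int(np.floor((re[-1] - re[0]) / step)) + 1)
    # piecewise-linear inverse map: reference time -> trial time
    src = np.interp(out_times, re, te)
    warped = np.interp(src, times, trace)
    return warped, np.asarray(out_times, dtype=float)


def reference_events_from_medians(
    spikes: SpikeTrainSet,
    reward_wait_floor: float,
    reward_event_index: int = 3,
) -> Tuple[np.ndarray, SpikeTrainSet]:
    """Common reference events for warping, from per-trial event medians.

    All trials are first aligned on their first event (T_1 = 0).  Each later
    reference event is the median of that event's aligned time over trials;
    the reward event's median is taken over correct trials only.  Error trials
    that lack the reward event (NaN) get a synthetic one inserted at
    ``t_prev + reward_wait_floor`` (the minimal waiting time between reward-port
    entry and reward delivery).  Returns the reference events and a copy of the
    spike set with the synthetic events filled in.
    """
    all_trials = [tr for trs in spikes.trials.values() for tr in trs]
    if not all_trials:
        raise ValueError("no trials")
    E = all_trials[0].event_times.size
    if reward_event_index >= E:
        raise ValueError("reward_event_index out of range")

    filled: Dict[Tuple[int, int, int], List[Trial]] = {}
    aligned_rows = {"all": [], "correct": []}
    for key, trs in spikes.trials.items():
        new_list = []
        for tr in trs:
            ev = tr.event_times.copy()
            if not np.isfinite(ev[reward_event_index]):
                ev[reward_event_index] = ev[reward_event_index - 1] + reward_wait_floor
            new_list.append(replace(tr, event_times=ev))
            row = ev - ev[0]
            aligned_rows["all"].append(row)
            if tr.correct:
                aligned_rows["correct"].append(row)
        filled[key] = new_list
    if not aligned_rows["correct"]:
        raise ValueError("no correct trials: reward-event median undefined")

    allm = np.median(np.stack(aligned_rows["all"]), axis=0)
    corr = np.median(np.stack(aligned_rows["correct"]), axis=0)
    ref = allm.copy()
    ref[reward_event_index] = corr[reward_event_index]
    ref[0] = 0.0
    return ref, replace(spikes, trials=filled)


# ---------------------------------------------------------------------------
# PSTHs and noise covariance
# ---------------------------------------------------------------------------

def compute_psths(data: TrialTensor, center: bool = True) -> PsthTensor:
    """Average available trials per (neuron, stimulus, decision, time).

    With ``center`` (the default, required by the demixing decomposition) each
    neuron's grand mean over conditions and time is subtracted and stored.
    """
    mask = data.trial_mask()
    vals = np.where(mask, data.values, 0.0)
    psth = vals.sum(axis=4) / data.trial_counts[:, :, :, None]
    means = None
    if center:
        means = psth.mean(axis=(1, 2, 3))
        psth = psth - means[:, None, None, None]
    return PsthTensor(values=psth, time=data.time, centered=center, means=means)


def estimate_noise_covariance(
    data: TrialTensor,
    mode: str = "diagonal",
    rebalanced: bool = True,
) -> NoiseCovariance:
    """Estimate the trial-to-trial noise covariance.

    For each parameter combination (s, d, t) the covariance of trial residuals
    around the condition PSTH is computed with the population denominator
    K_nsd.  ``rebalanced`` averages these per-condition covariances with equal
    weight, which makes the estimate invariant to how often each condition was
    recorded; otherwise they are pooled weighted by trial counts.

    ``mode='full'`` requires simultaneously recorded trials, i.e. identical
    trial counts across neurons; for sequential recordings use the diagonal.
    """
    N, S, Q, T, K = data.values.shape
    mask = data.trial_mask()
    counts = data.trial_counts
    vals = np.where(mask, data.values, 0.0)
    psth = vals.sum(axis=4) / counts[:, :, :, None]
    resid = np.where(mask, data.values - psth[..., None], 0.0)
    mean_counts = counts.mean(axis=(1, 2))

    if mode == "diagonal":
        # per-(n,s,d,t) population variance, then average over (s,d,t)
        var_nsdt = (resid ** 2).sum(axis=4) / counts[:, :, :, None]
        if rebalanced:
            var = var_nsdt.mean(axis=(1, 2, 3))
        else:
            tot = (resid ** 2).sum(axis=(1, 2, 3, 4))
            var = tot / (counts.sum(axis=(1, 2)) * T)
        matrix = np.diag(var)
    elif mode == "full":
        if not np.all(counts == counts[:1, :, :]):
            raise ValueError(
                "full noise covariance needs shared (simultaneous) trials; "
                "trial counts differ across neurons -- use mode='diagonal'"
            )
        csd = counts[0]                      # (S, Q)
        acc = np.zeros((N, N))
        wsum = 0.0
        for s in range(S):
            for d in range(Q):
                k = csd[s, d]
                r = resid[:, s, d, :, :k]    # (N, T, k)
                for t in range(T):
                    c = r[:, t, :] @ r[:, t, :].T / k
                    if rebalanced:
                        acc += c
                        wsum += 1.0
                    else:
                        acc += c * k
                        wsum += k
        matrix = acc / wsum
    else:
        raise ValueError("mode must be 'diagonal' or 'full'")

    return NoiseCovariance(
        matrix=matrix, mode=mode, rebalanced=rebalanced,
        mean_trial_counts=mean_counts,
    )
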