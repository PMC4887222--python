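"""Synthetic neural populations with known demixed ground truth.

Emulates the structure of sequentially recorded multi-condition datasets:
N neurons, S stimuli x Q decisions, T time bins, unequal trial counts, with
the underlying rates built as sums of label-specific latent components

    x_n(t, s, d, k) = sum_j w_nj * z_j(t, s, d) + eps,   eps ~ N(0, noise_sd^2)

where each latent ``z_j`` lives entirely inside one marginalization
(condition-independent, stimulus, decision, or interaction) -- this is
enforced by projecting each raw latent onto its marginalization subspace, so
the decomposition recovers the latents exactly at zero noise.

Latent time courses default to Gaussian bumps and ramps, mimicking the
morphology of typical prefrontal PSTH components.  SNR is defined as total
latent variance over total noise variance in the PSTH after K-trial
averaging.

Two focused generators reproduce classic failure modes: an unbalanced 2x2
additive toy (pooled trial correlations appear with unequal trial counts even
though every condition is uncorrelated) and a time-jittered population
(temporal jitter across sequentially recorded neurons adds derivative-shaped
principal components).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np

from .marginalization import decompose, default_grouping
from .preprocessing import PsthTensor, TrialTensor

__all__ = [
    "SyntheticGroundTruth",
    "generate_population",
    "generate_unbalanced_toy",
    "generate_jittered_population",
    "pooled_correlation",
    "principal_time_courses",
    "recovery_correlations",
]

LABELS = ("t", "st", "dt", "sdt")


@dataclass
class SyntheticGroundTruth:
    """Everything needed to score recovery of a generated population."""

    latents: Dict[str, np.ndarray]      # label -> (n_latents, S, Q, T)
    weights: Dict[str, np.ndarray]      # label -> (n_latents, N), unit rows
    signal: np.ndarray                  # (N, S, Q, T) noiseless PSTH
    noise_sd: float
    snr: float
    trial_counts: np.ndarray            # (N, S, Q)
    seed: Optional[int]
    jitter_sd: float = 0.0
    extras: Optional[Dict[str, np.ndarray]] = None   # e.g. analytic z, z'


def _bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _raw_latent(label: str, S: int, Q: int, T: int,
                rng: np.random.Generator) -> np.ndarray:
    """A raw condition-dependent time course before projection onto its label."""
    t = np.linspace(0, 1, T)
    if rng.random() < 0.5:
        course = _bump(t, rng.uniform(0.2, 0.8), rng.uniform(0.1, 0.25))
    else:
        course = t * rng.choice([-1.0, 1.0])        # ramp
    if label == "t":
        mod = np.ones((S, Q))
    elif label == "st":
        mod = np.linspace(-1, 1, S)[:, None] * np.ones((1, Q))
    elif label == "dt":
        mod = np.ones((S, 1)) * np.linspace(-1, 1, max(Q, 2))[:Q][None, :]
    elif label == "sdt":
        mod = rng.standard_normal((S, Q))
    else:
        raise ValueError(f"unknown label '{label}'")
    return mod[:, :, None] * course[None, None, :]


def _project_to_label(z: np.ndarray, label: str) -> np.ndarray:
    """Keep only the part of a (S, Q, T) tensor inside one marginalization."""
    arr = z[None]                                   # fake neuron axis
    arr = arr - arr.mean(axis=(1, 2, 3), keepdims=True)
    mset = decompose(arr)
    return mset.tensors[label][0]


def generate_population(
    N: int = 100,
    S: int = 4,
    Q: int = 2,
    T: int = 50,
    K: Union[int, np.ndarray] = 10,
    n_latents_per_label: Union[int, Dict[str, int]] = 1,
    snr: float = 1.0,
    noise_sd: float = 1.0,
    seed: Optional[int] = None,
) -> Tuple[TrialTensor, SyntheticGroundTruth]:
    """Generate a trial-resolved population with known demixed structure.

    ``K`` may be a scalar (balanced design) or an (S, Q) / (N, S, Q) array of
    per-condition trial counts.  With ``noise_sd > 0`` latent amplitudes are
    rescaled so that total signal variance over expected PSTH noise variance
    equals ``snr``.
    """
    rng = np.random.default_rng(seed)
    if isinstance(n_latents_per_label, int):
        n_lat = {lab: n_latents_per_label for lab in LABELS}
    else:
        n_lat = dict(n_latents_per_label)

    latents: Dict[str, np.ndarray] = {}
    weights: Dict[str, np.ndarray] = {}
    signal = np.zeros((N, S, Q, T))
    for lab in LABELS:
        m = n_lat.get(lab, 0)
        zs = np.empty((m, S, Q, T))
        ws = np.empty((m, N))
        for j in range(m):
            z = _project_to_label(_raw_latent(lab, S, Q, T, rng), lab)
            w = rng.standard_normal(N)
            w /= np.linalg.norm(w)
            zs[j] = z
            ws[j] = w
            signal += w[:, None, None, None] * z[None]
        latents[lab] = zs
        weights[lab] = ws

    K_arr = np.asarray(K)
    if K_arr.ndim == 0:
        counts = np.full((N, S, Q), int(K_arr))
    elif K_arr.shape == (S, Q):
        counts = np.broadcast_to(K_arr.astype(int)[None], (N, S, Q)).copy()
    elif K_arr.shape == (N, S, Q):
        counts = K_arr.astype(int).copy()
    else:
        raise ValueError("K must be scalar, (S, Q) or (N, S, Q)")

    if noise_sd > 0:
        mean_k = counts.mean()
        noise_ss = N * S * Q * T * noise_sd ** 2 / mean_k
        sig_ss = float(np.sum(signal ** 2))
        if sig_ss > 0:
            alpha = np.sqrt(snr * noise_ss / sig_ss)
            signal *= alpha
            for lab in LABELS:
                latents[lab] = latents[lab] * alpha

    Kmax = int(counts.max())
    values = np.full((N, S, Q, T, Kmax), np.nan)
    for n in range(N):
        for s in range(S):
            for d in range(Q):
                k = counts[n, s, d]
                eps = noise_sd * rng.standard_normal((T, k))
                values[n, s, d, :, :k] = signal[n, s, d, :, None] + eps

    data = TrialTensor(values=values, trial_counts=counts,
                       time=np.linspace(0, 1, T))
    truth = SyntheticGroundTruth(latents=latents, weights=weights,
                                 signal=signal, noise_sd=noise_sd, snr=snr,
                                 trial_counts=counts, seed=seed)
    return data, truth


# ---------------------------------------------------------------------------
# unbalanced 2x2 toy
# ---------------------------------------------------------------------------

def generate_unbalanced_toy(
    K_small: int = 10,
    K_large: int = 100,
    effect: float = 1.0,
    noise_sd: float = 0.2,
    seed: Optional[int] = None,
) -> Tuple[TrialTensor, TrialTensor]:
    """Two neurons, 2x2 additive design: ``x_ij = a_i u + b_j v + noise``.

    Factor A drives neuron 1 (levels +/- ``effect``), factor B drives neuron 2;
    there is no interaction and the per-condition noise is uncorrelated.  The
    unbalanced design oversamples the two "diagonal" conditions (a and b of
    equal sign) ``K_large`` to ``K_small``, which induces a spurious positive
    pooled correlation between the neurons even though every condition and
    every additive term is uncorrelated.  Returns ``(balanced, unbalanced)``
    trial tensors (T = 1).
    """
    rng = np.random.default_rng(seed)
    levels = np.array([-effect, effect])

    def build(counts_sd: np.ndarray) -> TrialTensor:
        Kmax = int(counts_sd.max())
        values = np.full((2, 2, 2, 1, Kmax), np.nan)
        for i in range(2):
            for j in range(2):
                k = counts_sd[i, j]
                x1 = levels[i] + noise_sd * rng.standard_normal(k)
                x2 = levels[j] + noise_sd * rng.standard_normal(k)
                values[0, i, j, 0, :k] = x1
                values[1, i, j, 0, :k] = x2
        counts = np.broadcast_to(counts_sd[None], (2, 2, 2)).copy()
        return TrialTensor(values=values, trial_counts=counts,
                           time=np.zeros(1))

    balanced = build(np.full((2, 2), K_large))
    unbalanced = build(np.array([[K_large, K_small], [K_small, K_large]]))
    return balanced, unbalanced


def pooled_correlation(data: TrialTensor) -> float:
    """Correlation between the first two neurons over all pooled trials."""
    mask = data.trial_mask()
    x1 = data.values[0][mask[0]]
    x2 = data.values[1][mask[1]]
    return float(np.corrcoef(x1, x2)[0, 1])


# ---------------------------------------------------------------------------
# temporally jittered population
# ---------------------------------------------------------------------------

def generate_jittered_population(
    N: int = 100,
    jitter_sd: float = 0.03,
    T: int = 200,
    bump_width: float = 0.1,
    seed: Optional[int] = None,
) -> Tuple[TrialTensor, SyntheticGroundTruth]:
    """Population encoding one Gaussian bump with per-neuron time shifts.

    ``y_n(t) = a_n z(t + tau_n)`` with ``tau_n ~ N(0, jitter_sd^2)`` and
    ``z`` a Gaussian bump evaluated analytically (no grid shifting, so
    off-grid jitter needs no padding).  With zero jitter the covariance over
    time has rank one; small jitter adds a second principal component shaped
    like the temporal derivative ``z'(t)`` -- an artifact of pooling
    non-simultaneous recordings, not a feature of the signal.

    Ground-truth ``z`` and ``z'`` on the grid are returned in ``extras``.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, T)
    c = 0.5
    z = _bump(t, c, bump_width)
    zprime = -(t - c) / bump_width ** 2 * z
    a = 1.0 + 0.25 * rng.standard_normal(N)
    tau = jitter_sd * rng.standard_normal(N)
    y = a[:, None] * _bump(t[None, :] + tau[:, None], c, bump_width)

    values = y[:, None, None, :, None]
    data = TrialTensor(values=values,
                       trial_counts=np.ones((N, 1, 1), dtype=int),
                       time=t)
    truth = SyntheticGroundTruth(
        latents={"t": z[None, None, None, :]},
        weights={"t": (a / np.linalg.norm(a))[None, :]},
        signal=(a[:, None] * z[None, :])[:, None, None, :],
        noise_sd=0.0, snr=np.inf, trial_counts=data.trial_counts,
        seed=seed, jitter_sd=jitter_sd,
        extras={"z": z, "zprime": zprime, "tau": tau, "a": a},
    )
    return data, truth


def principal_time_courses(data: TrialTensor, n: int = 3) -> np.ndarray:
    """Leading PCA component time courses of a (N, 1, 1, T, 1) population."""
    y = data.values[:, 0, 0, :, 0]
    yc = y - y.mean(axis=1, keepdims=True)
    _, _, Vt = np.linalg.svd(yc, full_matrices=False)
    return Vt[:n]


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

def recovery_correlations(model, psth: PsthTensor,
                          truth: SyntheticGroundTruth) -> Dict[str, np.ndarray]:
    """Greedy |correlation| matching of fitted components to true latents.

    For each marginalization label, the fitted component time courses
    (decoder projections of the PSTH, reshaped per condition) are matched to
    that label's ground-truth latents by maximal absolute Pearson correlation
    over flattened condition x time, greedily without replacement.  Returns
    per-label arrays of matched |r| (one per true latent).
    """
    scores = model.transform(psth)
    out: Dict[str, np.ndarray] = {}
    for lab, zs in truth.latents.items():
        m = zs.shape[0]
        if m == 0 or lab not in scores:
            continue
        comp = scores[lab].reshape(scores[lab].shape[0], -1)
        zflat = zs.reshape(m, -1)
        cmat = np.zeros((m, comp.shape[0]))
        for i in range(m):
            for j in range(comp.shape[0]):
                cmat[i, j] = abs(np.corrcoef(zflat[i], comp[j])[0, 1])
        rs = np.full(m, np.nan)
        used: set = set()
        for _ in range(min(m, comp.shape[0])):
            best = np.unravel_index(np.nanargmax(cmat), cmat.shape)
            rs[best[0]] = cmat[best]
            cmat[best[0], :] = -np.inf
            cmat[:, best[1]] = -np.inf
        out[lab] = rs
    return out
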