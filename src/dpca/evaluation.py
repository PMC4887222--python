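"""Evaluation of fitted demixing models.

Covers the full accounting used to summarize a population analysis:

* explained variance (per component, cumulative, and split across
  marginalizations), for model components or arbitrary component matrices;
* signal variance: the PSTH variance remaining after subtracting the
  estimated finite-trial noise contribution Theta, with the per-
  marginalization degrees-of-freedom split and largest-remainder pie
  percentages;
* demixing indices of decoder axes;
* significance of non-orthogonality between encoder axes (dot-product
  threshold 3.3/sqrt(N) plus a robust Kendall-correlation check);
* time-resolved decoder-based classification accuracy with a shuffle null
  and the consecutive-bin significance rule;
* encoder-weight distributions and the density-peaks clustering diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from . import core, model_selection
from .marginalization import MarginalizationSet, decompose
from .preprocessing import NoiseCovariance, PsthTensor, TrialTensor

__all__ = [
    "VarianceReport",
    "SignificanceReport",
    "DensityPeaks",
    "largest_remainder_round",
    "explained_variance",
    "signal_variance",
    "demixing_index",
    "axis_significance",
    "classification_significance",
    "encoder_weight_diagnostics",
]


# ---------------------------------------------------------------------------
# rounding helper
# ---------------------------------------------------------------------------

def largest_remainder_round(fractions: np.ndarray, total: int = 100) -> np.ndarray:
    """Round non-negative fractions (summing to 1) to integers summing to ``total``.

    Each value gets its floor; remaining units go to the largest fractional
    remainders (ties broken by index)."""
    fractions = np.asarray(fractions, dtype=float)
    raw = fractions / fractions.sum() * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    remainders = raw - base
    order = np.argsort(-remainders, kind="stable")
    base[order[:short]] += 1
    return base


# ---------------------------------------------------------------------------
# explained variance
# ---------------------------------------------------------------------------

@dataclass
class VarianceReport:
    """Variance bookkeeping for a set of components."""

    component_r2: np.ndarray                     # (q,), individual components
    cumulative_r2: np.ndarray                    # (q,), stacked top-i
    label_split: Optional[Dict[str, np.ndarray]] = None   # label -> (q,)
    order: Optional[List[Tuple[str, int]]] = None
    total_r2: Optional[float] = None
    # signal-variance block (filled by signal_variance)
    theta: Optional[float] = None
    theta_per_label: Optional[Dict[str, float]] = None
    signal_fraction: Optional[float] = None
    pie_percent: Optional[Dict[str, int]] = None


def _r2(X: np.ndarray, resid: np.ndarray, total: float) -> float:
    return 1.0 - float(np.sum(resid ** 2)) / total


def explained_variance(
    components: Union[core.DpcaModel, np.ndarray],
    psth: PsthTensor,
    mset: Optional[MarginalizationSet] = None,
) -> VarianceReport:
    """Fraction of PSTH variance explained, R^2 = 1 - ||X - X_hat||^2 / ||X||^2.

    For a fitted model, reconstruction uses each component's encoder/decoder
    pair (individually and stacked cumulatively in global variance order), and
    the per-label split attributes each component's R^2 additively to the
    marginalizations.  For an arbitrary component matrix ``Z`` (q x S*Q*T),
    reconstruction weights are found by linear regression,
    ``B = X Z^T (Z Z^T)^{-1}``.
    """
    X = psth.matrix()
    total = float(np.sum(X ** 2))

    if isinstance(components, core.DpcaModel):
        model = components
        F, D, order = model.stacked()
        q = F.shape[1]
        comp_r2 = np.empty(q)
        cum_r2 = np.empty(q)
        for i in range(q):
            f, d = F[:, i:i + 1], D[i:i + 1]
            comp_r2[i] = _r2(X, X - f @ (d @ X), total)
            Fi, Di = F[:, :i + 1], D[:i + 1]
            cum_r2[i] = _r2(X, X - Fi @ (Di @ X), total)
        split = None
        if mset is not None:
            split = {}
            for lab in mset.tensors:
                Xphi = mset.matrix(lab)
                sq = float(np.sum(Xphi ** 2))
                vals = np.empty(q)
                for i in range(q):
                    f, d = F[:, i:i + 1], D[i:i + 1]
                    vals[i] = (sq - float(np.sum((Xphi - f @ (d @ Xphi)) ** 2))) / total
                split[lab] = vals
        return VarianceReport(component_r2=comp_r2, cumulative_r2=cum_r2,
                              label_split=split, order=order,
                              total_r2=float(cum_r2[-1]) if q else 0.0)

    Z = np.asarray(components, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != X.shape[1]:
        raise ValueError("component matrix must be q x (S*Q*T)")
    G = Z @ Z.T
    w, V = np.linalg.eigh(G)
    if w.min() <= 1e-12 * max(w.max(), 0.0):
        warnings.warn("singular component Gram matrix; using pseudo-inverse")
    B = X @ Z.T @ core._pinv_sym(G)
    q = Z.shape[0]
    comp_r2 = np.empty(q)
    cum_r2 = np.empty(q)
    for i in range(q):
        Bi = X @ Z[i:i + 1].T @ core._pinv_sym(Z[i:i + 1] @ Z[i:i + 1].T)
        comp_r2[i] = _r2(X, X - Bi @ Z[i:i + 1], total)
        Bc = X @ Z[:i + 1].T @ core._pinv_sym(Z[:i + 1] @ Z[:i + 1].T)
        cum_r2[i] = _r2(X, X - Bc @ Z[:i + 1], total)
    return VarianceReport(component_r2=comp_r2, cumulative_r2=cum_r2,
                          total_r2=_r2(X, X - B @ Z, total))


# ---------------------------------------------------------------------------
# signal variance
# ---------------------------------------------------------------------------

def _label_dof(label: str, mset: MarginalizationSet,
               level_counts: Dict[str, int]) -> int:
    """Degrees of freedom of a grouped marginalization: sum over its raw
    subsets of prod_{p in subset} (levels_p - 1)."""
    dof = 0
    for psi in mset.grouping[label]:
        term = 1
        for p in psi:
            term *= level_counts[p] - 1
        dof += term
    return dof


def signal_variance(
    noise: NoiseCovariance,
    psth: PsthTensor,
    mset: MarginalizationSet,
) -> VarianceReport:
    """Estimate how much PSTH variance is signal rather than finite-trial noise.

    The residual noise sum of squares is ``Theta = S*Q*T * sum_n C_nn /
    Kbar_n`` with ``Kbar_n`` the neuron's mean trial count.  Theta splits
    across marginalizations proportionally to their degrees of freedom
    ``K_phi`` (summing to S*Q*T - 1).  The per-marginalization signal pie is
    ``(||X_phi||^2 - Theta_phi) / (||X||^2 - Theta)``, shown as integer
    percentages via largest-remainder rounding.
    """
    N, *dims = psth.values.shape
    n_cols = int(np.prod(dims))
    level_counts = {p: psth.values.shape[i + 1] for i, p in enumerate(mset.params)}

    theta = n_cols * float(np.sum(noise.diagonal / noise.mean_trial_counts))
    total_dof = n_cols - 1
    dofs = {lab: _label_dof(lab, mset, level_counts) for lab in mset.tensors}
    theta_phi = {lab: dofs[lab] / total_dof * theta for lab in mset.tensors}

    total_sq = float(np.sum(psth.matrix() ** 2))
    signal_fraction = 1.0 - theta / total_sq
    if signal_fraction < 0:
        warnings.warn("estimated noise exceeds total variance; "
                      "signal fraction clipped at 0")
        signal_fraction = 0.0

    pie_raw = np.array([
        max(mset.sq_norm(lab) - theta_phi[lab], 0.0) for lab in mset.tensors
    ])
    if pie_raw.sum() > 0:
        pie = largest_remainder_round(pie_raw / pie_raw.sum())
    else:
        pie = np.zeros(len(pie_raw), dtype=int)
    pie_percent = {lab: int(p) for lab, p in zip(mset.tensors, pie)}

    return VarianceReport(
        component_r2=np.empty(0), cumulative_r2=np.empty(0),
        theta=theta, theta_per_label=theta_phi,
        signal_fraction=signal_fraction, pie_percent=pie_percent,
    )


# ---------------------------------------------------------------------------
# demixing index
# ---------------------------------------------------------------------------

def demixing_index(decoder: np.ndarray, mset: MarginalizationSet) -> float:
    """max_phi ||d X_phi||^2 / ||d X||^2; in [1/L, 1] for L marginalizations.

    1 means the component's variance falls entirely within a single
    marginalization (perfect demixing).  Returns NaN for a zero projection.
    """
    d = np.asarray(decoder, dtype=float).ravel()
    per_label = {lab: float(np.sum((d @ mset.matrix(lab)) ** 2))
                 for lab in mset.tensors}
    denom = float(np.sum((d @ mset.total_matrix()) ** 2))
    if denom <= 0:
        warnings.warn("zero projection: demixing index undefined")
        return float("nan")
    return max(per_label.values()) / denom


# ---------------------------------------------------------------------------
# axis angles
# ---------------------------------------------------------------------------

def axis_significance(
    encoders: np.ndarray,
    alpha_kendall: float = 0.001,
) -> Tuple[np.ndarray, np.ndarray]:
    """Flag significantly, robustly non-orthogonal pairs of encoder axes.

    Under the null of random directions on the N-sphere, dot products have SD
    ~ 1/sqrt(N); at p < 0.001 two axes are significantly non-orthogonal when
    ``|f1 . f2| > 3.3 / sqrt(N)``.  To guard against a few outlying neurons
    driving the dot product, a pair is only starred when the Kendall
    correlation between the two coordinate vectors is also significant.

    Returns ``(dots, starred)``: the q x q dot-product matrix and the boolean
    star matrix (diagonal False).
    """
    F = np.asarray(encoders, dtype=float)
    N, q = F.shape
    thr = 3.3 / np.sqrt(N)
    if thr > 0.95:
        warnings.warn(
            f"N={N} gives a dot-product threshold of {thr:.2f}; the "
            "non-orthogonality test is near-vacuous for so few neurons"
        )
    dots = F.T @ F
    starred = np.zeros((q, q), dtype=bool)
    for i in range(q):
        for j in range(i + 1, q):
            if abs(dots[i, j]) > thr:
                tau = stats.kendalltau(F[:, i], F[:, j])
                if tau.pvalue < alpha_kendall:
                    starred[i, j] = starred[j, i] = True
    return dots, starred


# ---------------------------------------------------------------------------
# decoder-based classification significance
# ---------------------------------------------------------------------------

@dataclass
class SignificanceReport:
    """Time-resolved classification accuracies with shuffle-null control."""

    accuracy: Dict[str, np.ndarray]          # label -> (n_comp, T)
    null_accuracy: Dict[str, np.ndarray]     # label -> (n_shuffles, n_comp, T)
    mask: Dict[str, np.ndarray]              # label -> bool (n_comp, T)
    chance: Dict[str, float]
    time: np.ndarray
    seed: Optional[int] = None


# which task parameter each condition-dependent label classifies
_CLASS_OF_LABEL = {"st": "stimulus", "dt": "decision", "sdt": "condition"}


def _class_ids(label: str, S: int, Q: int) -> np.ndarray:
    """True class index of each (s, d) pseudo-trial, flattened."""
    s_idx, d_idx = np.meshgrid(np.arange(S), np.arange(Q), indexing="ij")
    if _CLASS_OF_LABEL[label] == "stimulus":
        return s_idx.ravel()
    if _CLASS_OF_LABEL[label] == "decision":
        return d_idx.ravel()
    return (s_idx * Q + d_idx).ravel()


def _accuracy_one_cv(
    data: TrialTensor,
    rng: np.random.Generator,
    lam: float,
    n_comp_per_label: int,
    labels: Sequence[str],
) -> Dict[str, np.ndarray]:
    """One CV iteration: split, fit, nearest-class-mean classification."""
    psth_train, noise_train, x_test = model_selection.split_train_test(data, rng)
    mset = decompose(psth_train)
    model = core.fit(psth_train, mset, noise=noise_train,
                     q_per_label=n_comp_per_label, lam=lam,
                     keep_training_data=False)
    N, S, Q, T, _ = data.values.shape
    out: Dict[str, np.ndarray] = {}
    x_test_c = x_test - model.means[:, None, None, None]
    for lab in labels:
        D = model.decoders.get(lab, np.zeros((0, N)))
        nc = min(n_comp_per_label, D.shape[0])
        acc = np.zeros((n_comp_per_label, T))
        cls = _class_ids(lab, S, Q)
        n_classes = cls.max() + 1
        for i in range(nc):
            d = D[i]
            train_sc = (d @ psth_train.matrix()).reshape(S, Q, T)
            if _CLASS_OF_LABEL[lab] == "stimulus":
                means = train_sc.mean(axis=1)                       # (S, T)
            elif _CLASS_OF_LABEL[lab] == "decision":
                means = train_sc.mean(axis=0)                       # (Q, T)
            else:
                means = train_sc.reshape(S * Q, T)
            test_sc = np.einsum("n,nsqt->sqt", d, x_test_c).reshape(S * Q, T)
            # nearest class mean, per time point
            dist = np.abs(test_sc[:, None, :] - means[None, :, :])  # (SQ, C, T)
            assigned = np.argmin(dist, axis=1)                      # (SQ, T)
            acc[i] = (assigned == cls[:, None]).mean(axis=0)
        out[lab] = acc
    return out


def _shuffle_trials(data: TrialTensor, rng: np.random.Generator) -> TrialTensor:
    """Shuffle each neuron's trials across conditions, preserving counts."""
    N, S, Q, T, K = data.values.shape
    counts = data.trial_counts
    values = np.full_like(data.values, np.nan)
    for n in range(N):
        pool = []
        for s in range(S):
            for d in range(Q):
                for k in range(counts[n, s, d]):
                    pool.append(data.values[n, s, d, :, k])
        pool = np.array(pool)
        perm = rng.permutation(len(pool))
        idx = 0
        for s in range(S):
            for d in range(Q):
                for k in range(counts[n, s, d]):
                    values[n, s, d, :, k] = pool[perm[idx]]
                    idx += 1
        assert idx == len(pool)
    return TrialTensor(values=values, trial_counts=counts.copy(),
                       time=data.time)


def _significant_runs(above: np.ndarray, min_consecutive: int) -> np.ndarray:
    """Mask keeping only runs of True of length >= min_consecutive."""
    mask = np.zeros_like(above)
    T = above.size
    t = 0
    while t < T:
        if above[t]:
            t2 = t
            while t2 < T and above[t2]:
                t2 += 1
            if t2 - t >= min_consecutive:
                mask[t:t2] = True
            t = t2
        else:
            t += 1
    return mask


def classification_significance(
    data: TrialTensor,
    lam: float = 0.0,
    n_cv: int = 100,
    n_shuffles: int = 100,
    n_comp_per_label: int = 3,
    min_consecutive: int = 10,
    seed: Optional[int] = None,
    labels: Sequence[str] = ("st", "dt", "sdt"),
) -> SignificanceReport:
    """Decoder-axis classification accuracy with a trial-shuffle null.

    Stratified Monte Carlo leave-group-out CV: each iteration holds out one
    trial per neuron per condition as S*Q test pseudo-trials, fits the
    demixing model on the rest, and classifies each pseudo-trial at every
    time point by the closest class mean along each of the first
    ``n_comp_per_label`` decoder axes of the stimulus, decision and
    interaction marginalizations.  The chance distribution comes from
    ``n_shuffles`` within-neuron trial shuffles (trial counts preserved), each
    evaluated with the same CV procedure.  A time bin is flagged significant
    when the actual accuracy strictly exceeds every shuffle accuracy for at
    least ``min_consecutive`` consecutive bins.
    """
    if n_cv < 100 or n_shuffles < 100:
        warnings.warn(
            f"running with n_cv={n_cv}, n_shuffles={n_shuffles}; the standard "
            "setting is 100/100 -- the null band will be noisier"
        )
    rng = np.random.default_rng(seed)
    N, S, Q, T, _ = data.values.shape

    def mean_accuracy(d: TrialTensor) -> Dict[str, np.ndarray]:
        acc = {lab: np.zeros((n_comp_per_label, T)) for lab in labels}
        for _ in range(n_cv):
            one = _accuracy_one_cv(d, rng, lam, n_comp_per_label, labels)
            for lab in labels:
                acc[lab] += one[lab]
        return {lab: a / n_cv for lab, a in acc.items()}

    accuracy = mean_accuracy(data)
    null = {lab: np.zeros((n_shuffles, n_comp_per_label, T)) for lab in labels}
    for sh in range(n_shuffles):
        shuffled = _shuffle_trials(data, rng)
        acc_sh = mean_accuracy(shuffled)
        for lab in labels:
            null[lab][sh] = acc_sh[lab]

    mask = {}
    for lab in labels:
        null_max = null[lab].max(axis=0)          # (n_comp, T)
        above = accuracy[lab] > null_max
        mask[lab] = np.vstack([
            _significant_runs(above[i], min_consecutive)
            for i in range(n_comp_per_label)
        ])

    chance = {
        lab: 1.0 / {"stimulus": S, "decision": Q, "condition": S * Q}[
            _CLASS_OF_LABEL[lab]]
        for lab in labels
    }
    return SignificanceReport(accuracy=accuracy, null_accuracy=null,
                              mask=mask, chance=chance, time=data.time,
                              seed=seed)


# ---------------------------------------------------------------------------
# encoder-weight diagnostics (density peaks)
# ---------------------------------------------------------------------------

@dataclass
class DensityPeaks:
    """Per-neuron density-peaks statistics in encoder-weight space."""

    weights: np.ndarray                # (N, m) encoder weights used
    density: np.ndarray                # (N,) Gaussian-kernel local density
    delta: np.ndarray                  # (N,) distance to nearest denser point
    histograms: Dict[int, Tuple[np.ndarray, np.ndarray]]  # comp -> (counts, edges)

    @property
    def gamma(self) -> np.ndarray:
        """density * delta; cluster centres stand out as large values."""
        return self.density * self.delta


def encoder_weight_diagnostics(
    model_or_weights: Union[core.DpcaModel, np.ndarray],
    kernel_var: float = 0.01,
    n_components: int = 15,
    hist_bin_width: float = 0.005,
) -> DensityPeaks:
    """Encoder-weight distributions and the density-peaks clustering statistic.

    Neurons are points in the space of encoder weights of the leading
    ``n_components`` components.  For each point a local density is computed
    with a Gaussian kernel of variance ``kernel_var``; ``delta`` is the
    minimal distance to a point of higher density (for the global density
    maximum: the distance to the furthest point).  Cluster centres appear as
    joint outliers in (density, delta); a single outlier indicates one
    cluster, i.e. no distinct sub-populations.
    """
    if isinstance(model_or_weights, core.DpcaModel):
        F, _, _ = model_or_weights.stacked()
        W = F[:, :n_components]
    else:
        W = np.asarray(model_or_weights, dtype=float)
    N = W.shape[0]
    if N < 2:
        raise ValueError("need at least 2 neurons")

    dist = squareform(pdist(W))
    density = np.exp(-dist ** 2 / (2.0 * kernel_var)).sum(axis=1) - 1.0

    delta = np.empty(N)
    for i in range(N):
        # ties in density broken by index: earlier index counts as denser
        higher = (density > density[i]) | ((density == density[i])
                                           & (np.arange(N) < i))
        if higher.any():
            delta[i] = dist[i, higher].min()
        else:
            delta[i] = dist[i].max()

    hists = {}
    for j in range(W.shape[1]):
        lo, hi = W[:, j].min(), W[:, j].max()
        nb = max(int(np.ceil((hi - lo) / hist_bin_width)), 1)
        hists[j] = np.histogram(W[:, j], bins=nb)
    return DensityPeaks(weights=W, density=density, delta=delta,
                        histograms=hists)


# ---------------------------------------------------------------------------
# generic component plotting
# ---------------------------------------------------------------------------

def plot_components(model: "core.DpcaModel", psth: PsthTensor,
                    n_per_label: int = 2):
    """Plot component time courses, one condition per line, per label.

    Returns the matplotlib figure (Agg-safe; matplotlib is imported lazily
    and only needed for this function)."""
    import matplotlib
    import matplotlib.pyplot as plt

    scores = {lab: model.transform(psth, labels=[lab])[lab]
              for lab in model.decoders}
    labels = [lab for lab in model.decoders if scores[lab].shape[0]]
    ncols = max(min(n_per_label, max(scores[lab].shape[0]
                                     for lab in labels)), 1)
    fig, axes = plt.subplots(len(labels), ncols, squeeze=False,
                             figsize=(4 * ncols, 2.2 * len(labels)))
    t = psth.time
    for r, lab in enumerate(labels):
        sc = scores[lab]
        for c in range(ncols):
            ax = axes[r, c]
            if c >= sc.shape[0]:
                ax.axis("off")
                continue
            comp = sc[c]                     # (S, Q, T)
            for s in range(comp.shape[0]):
                for d in range(comp.shape[1]):
                    ax.plot(t, comp[s, d], lw=1)
            ax.set_title(f"{lab} #{c + 1}", fontsize=9)
            if r == len(labels) - 1:
                ax.set_xlabel("time (s)")
    fig.tight_layout()
    return fig
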