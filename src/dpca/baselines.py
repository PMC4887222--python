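"""Comparison methods: PCA, per-marginalization PCA with pseudo-inverse,
targeted dimensionality reduction (TDR), factorial LDA, difference of
covariances (DOC), and classical per-neuron ANOVA tuning.

These are the methods the demixing approach is usually benchmarked against.
They share the decoder/encoder vocabulary of the core model where it applies,
so demixing indices and explained variance can be computed uniformly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import linalg, stats

from . import core
from .marginalization import CovarianceSet, MarginalizationSet
from .preprocessing import PsthTensor, TrialTensor

__all__ = [
    "BaselineModel",
    "pca_baseline",
    "marg_pca_pinv",
    "tdr",
    "factorial_lda",
    "doc_axes",
    "classical_tuning",
    "ClassicalTuningResult",
]


@dataclass
class BaselineModel:
    """Axes produced by a comparison method.

    ``decoders``/``encoders`` are stacked (q x N) / (N x q); ``axis_labels``
    tags each axis with the marginalization or parameter it targets when the
    method defines one.
    """

    method: str
    decoders: np.ndarray
    encoders: Optional[np.ndarray] = None
    axis_labels: Optional[List[str]] = None
    meta: Dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_baseline(psth: PsthTensor, q: int) -> BaselineModel:
    """Top-q principal axes of the centered PSTH matrix; F = D^T = U_pca."""
    X = psth.matrix()
    N = X.shape[0]
    if q > N:
        q = N
    U, sv, _ = np.linalg.svd(X, full_matrices=False)
    Uq = U[:, :q]
    return BaselineModel(method="pca", decoders=Uq.T, encoders=Uq,
                         meta={"singular_values": sv[:q]})


# ---------------------------------------------------------------------------
# PCA in each marginalization + pseudo-inverse decoders
# ---------------------------------------------------------------------------

def marg_pca_pinv(mset: MarginalizationSet, k: int = 10) -> BaselineModel:
    """Per-marginalization principal axes as encoders, pseudo-inverse decoders.

    The top-k principal axes of every marginalization are stacked into a
    single N x (L*k) matrix U; encoders are its columns and decoders the rows
    of its pseudo-inverse, which approximates the demixing solution when the
    principal subspaces of different marginalizations do not overlap.
    """
    blocks = []
    labels = []
    for lab in mset.tensors:
        Xphi = mset.matrix(lab)
        U, _, _ = np.linalg.svd(Xphi, full_matrices=False)
        kk = min(k, U.shape[1])
        blocks.append(U[:, :kk])
        labels += [lab] * kk
    U = np.column_stack(blocks)
    N = U.shape[0]
    if U.shape[1] > N:
        warnings.warn(
            f"{U.shape[1]} stacked axes exceed N={N}; the pseudo-inverse "
            "decoders are underdetermined"
        )
    D = np.linalg.pinv(U)
    return BaselineModel(method="marg-pca-pinv", decoders=D, encoders=U,
                         axis_labels=labels, meta={"k": k})


# ---------------------------------------------------------------------------
# targeted dimensionality reduction
# ---------------------------------------------------------------------------

def tdr(
    psth: PsthTensor,
    stimulus_values: Sequence[float],
    decision_values: Sequence[float],
    order: Sequence[str] = ("st", "dt", "sdt"),
    n_pcs: int = 20,
) -> BaselineModel:
    """Targeted dimensionality reduction: regression axes, denoised and QR'd.

    Per neuron and time point, the rate is regressed on stimulus, decision
    and their product (in the supplied task units).  The resulting
    coefficient vectors ``beta_phi(t)`` are denoised by projecting onto the
    top ``n_pcs`` PCA axes; for each parameter the time point maximizing
    ``||K beta_phi(t)||`` is selected (first maximum on ties).  The chosen
    vectors are stacked in the given order -- the condition-independent
    vector always last -- and orthogonalized by QR; the resulting orthonormal
    axes both decode and encode.

    The stacking order matters whenever the beta vectors are non-orthogonal,
    which is why it is a required, dataset-specific argument.
    """
    N, S, Q, T = psth.values.shape
    s_vals = np.asarray(stimulus_values, float)
    d_vals = np.asarray(decision_values, float)
    if s_vals.size != S or d_vals.size != Q:
        raise ValueError("parametrization lengths must match (S, Q)")

    ss, dd = np.meshgrid(s_vals, d_vals, indexing="ij")
    design = np.column_stack([
        np.ones(S * Q), ss.ravel(), dd.ravel(), (ss * dd).ravel()
    ])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "collinear regressors: the stimulus/decision parametrization "
            "does not span an identifiable two-factor design"
        )

    Y = psth.values.transpose(1, 2, 0, 3).reshape(S * Q, N * T)
    B = np.linalg.lstsq(design, Y, rcond=None)[0].reshape(4, N, T)
    betas = {"t": B[0], "st": B[1], "dt": B[2], "sdt": B[3]}   # each (N, T)

    X = psth.matrix()
    U, _, _ = np.linalg.svd(X, full_matrices=False)
    Un = U[:, :min(n_pcs, U.shape[1])]
    Kproj = Un @ Un.T

    chosen = []
    labels = []
    stack_order = list(order) + ["t"]       # condition-independent axis last
    degenerate = []
    for lab in stack_order:
        kb = Kproj @ betas[lab]             # (N, T)
        norms = np.linalg.norm(kb, axis=0)
        t_star = int(np.argmax(norms))
        v = kb[:, t_star]
        if norms[t_star] <= 1e-12 * max(1.0, np.abs(X).max()):
            degenerate.append(lab)
        chosen.append(v)
        labels.append(lab)
    if degenerate:
        warnings.warn(
            f"absent effect(s) {degenerate}: their axes are arbitrary within "
            "the orthocomplement of the preceding axes"
        )
    Bmat = np.column_stack(chosen)
    Qmat, _ = np.linalg.qr(Bmat)
    return BaselineModel(method="tdr", decoders=Qmat.T, encoders=Qmat,
                         axis_labels=labels,
                         meta={"order": list(order), "n_pcs": n_pcs,
                               "degenerate": degenerate})


# ---------------------------------------------------------------------------
# factorial LDA
# ---------------------------------------------------------------------------

def factorial_lda(
    cset: CovarianceSet,
    label: str,
    q: int,
    ridge: float = 0.0,
) -> BaselineModel:
    """LDA run per marginalization: between-class C_phi, within-class C_-phi.

    Decoders are the top-q eigenvectors of ``C_-phi^{-1} C_phi`` (solved as a
    generalized symmetric eigenproblem).  ``ridge`` adds an isotropic
    stabilizer to the within-class matrix when it is singular.
    """
    Cphi = cset.per_label[label]
    C = cset.total
    Cm = C - Cphi
    for M, name in ((Cphi, "C_phi"), (Cm, "C_-phi")):
        w = np.linalg.eigvalsh(M)
        if w.min() < -1e-8 * max(abs(w).max(), 1.0):
            raise ValueError(f"{name} is not positive semidefinite")
    N = C.shape[0]
    Cm_reg = Cm + ridge * np.eye(N)
    if np.linalg.eigvalsh(Cm_reg).min() <= 1e-12 * np.abs(Cm_reg).max():
        raise ValueError(
            "within-class covariance is singular; pass a positive ridge"
        )
    w, V = linalg.eigh(Cphi, Cm_reg)
    idx = np.argsort(w)[::-1][:q]
    D = V[:, idx].T
    D = D / np.linalg.norm(D, axis=1, keepdims=True)
    return BaselineModel(method="flda", decoders=D,
                         axis_labels=[label] * len(idx),
                         meta={"eigenvalues": w[idx], "ridge": ridge})


# ---------------------------------------------------------------------------
# difference of covariances
# ---------------------------------------------------------------------------

def doc_axes(cset: CovarianceSet, label_pair: Tuple[str, str]) -> BaselineModel:
    """Axes of the difference of two marginalized covariances.

    ``S = C_phi1 - C_phi2``; eigenvectors with positive eigenvalues point
    along directions of dominant phi1 variance (tagged phi1), negative ones
    along phi2.  Imposing a single orthogonal set of axes for both
    marginalizations is the key restriction relaxed by the demixing model.
    """
    lab1, lab2 = label_pair
    Smat = cset.per_label[lab1] - cset.per_label[lab2]
    w, V = np.linalg.eigh(Smat)
    idx = np.argsort(w)[::-1]
    w, V = w[idx], V[:, idx]
    labels = [lab1 if wi > 0 else lab2 for wi in w]
    return BaselineModel(method="doc", decoders=V.T, encoders=V,
                         axis_labels=labels, meta={"eigenvalues": w})


# ---------------------------------------------------------------------------
# classical per-neuron ANOVA tuning
# ---------------------------------------------------------------------------

_EFFECTS = ("stimulus", "decision", "interaction")


@dataclass
class ClassicalTuningResult:
    """Per-neuron, per-timepoint two-way ANOVA summary of tuning."""

    p_values: Dict[str, np.ndarray]        # effect -> (N, T)
    effect_sizes: Dict[str, np.ndarray]    # effect -> (N, T), signed partial omega^2
    alpha: float
    time: np.ndarray

    def fraction_significant(self, effect: str) -> np.ndarray:
        return (self.p_values[effect] < self.alpha).mean(axis=0)

    def population_average(self, psth: PsthTensor, effect: str,
                           time_index: int) -> np.ndarray:
        """Population-average component over significant cells at one time.

        Cells significant for the effect at ``time_index`` get weight
        ``+/- 1 / N_sig`` with the sign of their effect size (PSTHs of
        negatively tuned cells are flipped); others get zero.  Returns the
        component reshaped (S, Q, T).
        """
        sig = self.p_values[effect][:, time_index] < self.alpha
        n_sig = int(sig.sum())
        if n_sig == 0:
            raise ValueError(f"no cells significant for '{effect}' at "
                             f"time index {time_index}")
        w = np.zeros(psth.n_neurons)
        signs = np.sign(self.effect_sizes[effect][:, time_index])
        signs[signs == 0] = 1.0
        w[sig] = signs[sig] / n_sig
        comp = w @ psth.matrix()
        return comp.reshape(psth.values.shape[1:])


def _effect_columns(S: int, Q: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sum-to-zero (effect) coded columns for the cell grid, one row per cell."""
    def contrasts(L: int) -> np.ndarray:
        C = np.zeros((L, L - 1))
        C[:L - 1, :] = np.eye(L - 1)
        C[L - 1, :] = -1.0
        return C
    Ca, Cb = contrasts(S), contrasts(Q)
    s_idx, d_idx = np.meshgrid(np.arange(S), np.arange(Q), indexing="ij")
    A = Ca[s_idx.ravel()]
    Bc = Cb[d_idx.ravel()]
    AB = np.einsum("ni,nj->nij", A, Bc).reshape(S * Q, -1)
    return A, Bc, AB


def classical_tuning(data: TrialTensor, alpha: float = 0.05) -> ClassicalTuningResult:
    """Two-way ANOVA (stimulus x decision, with interaction) per neuron and time.

    Balanced cells use the direct sums-of-squares decomposition; unbalanced
    designs use Type-II sums of squares from nested effect-coded regressions.
    Effect size is partial omega squared, signed by the correlation between
    firing rate and the (centered) parameter value -- for the interaction,
    the product of centered stimulus and decision indices.
    """
    N, S, Q, T, _ = data.values.shape
    counts = data.trial_counts
    if np.any(counts < 2):
        raise ValueError("ANOVA needs at least 2 trials per condition")

    A_cells, B_cells, AB_cells = _effect_columns(S, Q)
    dfs = {"stimulus": S - 1, "decision": Q - 1,
           "interaction": (S - 1) * (Q - 1)}

    p_values = {e: np.ones((N, T)) for e in _EFFECTS}
    omega = {e: np.zeros((N, T)) for e in _EFFECTS}

    s_centered = np.arange(S) - (S - 1) / 2
    d_centered = np.arange(Q) - (Q - 1) / 2

    for n in range(N):
        cnt = counts[n]                                   # (S, Q)
        n_tot = int(cnt.sum())
        cell_of_trial = np.repeat(np.arange(S * Q), cnt.ravel())
        # gather trials: (n_tot, T)
        ys = []
        regs = {"stimulus": [], "decision": [], "interaction": []}
        for s in range(S):
            for d in range(Q):
                k = cnt[s, d]
                ys.append(data.values[n, s, d, :, :k].T)  # (k, T)
                regs["stimulus"] += [s_centered[s]] * k
                regs["decision"] += [d_centered[d]] * k
                regs["interaction"] += [s_centered[s] * d_centered[d]] * k
        Yn = np.vstack(ys)                                # (n_tot, T)
        df_err = n_tot - S * Q
        if df_err <= 0:
            raise ValueError("not enough trials for the error term")

        ones = np.ones((n_tot, 1))
        A = A_cells[cell_of_trial]
        B = B_cells[cell_of_trial]
        AB = AB_cells[cell_of_trial]

        def rss(M: np.ndarray) -> np.ndarray:
            Qm, _ = np.linalg.qr(M)
            resid = Yn - Qm @ (Qm.T @ Yn)
            return np.sum(resid ** 2, axis=0)

        rss_full = rss(np.hstack([ones, A, B, AB]))
        rss_ab = rss(np.hstack([ones, A, B]))
        ss = {
            "stimulus": rss(np.hstack([ones, B])) - rss_ab,
            "decision": rss(np.hstack([ones, A])) - rss_ab,
            "interaction": rss_ab - rss_full,
        }
        ms_err = rss_full / df_err
        for eff in _EFFECTS:
            ss_e = np.maximum(ss[eff], 0.0)
            F = (ss_e / dfs[eff]) / np.where(ms_err > 0, ms_err, np.inf)
            p_values[eff][n] = stats.f.sf(F, dfs[eff], df_err)
            om = (ss_e - dfs[eff] * ms_err) / (ss_e + (n_tot - dfs[eff]) * ms_err)
            reg = np.asarray(regs[eff], float)
            regc = reg - reg.mean()
            denom = np.sqrt(np.sum(regc ** 2) * np.sum(
                (Yn - Yn.mean(axis=0)) ** 2, axis=0))
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = (regc @ (Yn - Yn.mean(axis=0))) / denom
            sign = np.where(np.nan_to_num(corr) < 0, -1.0, 1.0)
            omega[eff][n] = sign * np.abs(om)

    return ClassicalTuningResult(p_values=p_values, effect_sizes=omega,
                                 alpha=alpha, time=data.time)
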