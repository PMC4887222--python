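"""Core demixing fit: per-marginalization regularized reduced-rank regression.

For each marginalization ``phi`` the method minimizes

    L_phi = || X_phi - F_phi D_phi X ||^2
            + S*Q*T * || F_phi D_phi C_noise^{1/2} ||^2
            + mu * || F_phi D_phi ||^2

over an encoder ``F_phi`` (N x q, orthonormal columns) and a decoder
``D_phi`` (q x N).  The full-rank ridge solution is

    A = X_phi X^T (X X^T + S*Q*T * C_noise + mu I)^{-1},

and the rank-q solution follows from the Eckart-Young theorem: with ``U_q``
the leading left singular vectors of ``A X``, set ``F = U_q`` and
``D = U_q^T A``.  Successive encoder/decoder pairs are nested: pair i does
not depend on how many pairs are extracted.

The ridge strength is parametrized as ``mu = (lambda * ||X||)^2`` so that
``lambda`` is comparable across datasets; the noise term re-balances
unequal trial counts and handles sequential recordings via a diagonal
noise covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .marginalization import MarginalizationSet
from .preprocessing import NoiseCovariance, PsthTensor

__all__ = ["DpcaModel", "rrr_solve", "fit", "transform", "reconstruct"]

# relative eigenvalue cutoff for the symmetric pseudo-inverse
_PINV_RTOL = 1e-12


def _pinv_sym(G: np.ndarray, warn_singular: bool = False) -> np.ndarray:
    """Pseudo-inverse of a symmetric PSD matrix via eigen-decomposition."""
    w, V = np.linalg.eigh(G)
    cutoff = _PINV_RTOL * max(w.max(), 0.0)
    keep = w > cutoff
    if warn_singular and not keep.all():
        warnings.warn(
            "singular normal matrix: using pseudo-inverse "
            f"(rank {keep.sum()} of {len(w)})"
        )
    inv = np.zeros_like(w)
    inv[keep] = 1.0 / w[keep]
    return (V * inv) @ V.T


def _fix_signs(F: np.ndarray, D: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Flip each pair so the encoder coefficient of largest magnitude is > 0."""
    for i in range(F.shape[1]):
        j = int(np.argmax(np.abs(F[:, i])))
        if F[j, i] < 0:
            F[:, i] = -F[:, i]
            D[i, :] = -D[i, :]
    return F, D


def rrr_solve(
    target: np.ndarray,
    predictor: np.ndarray,
    q: int,
    ridge_mu: float = 0.0,
    noise_term: Optional[np.ndarray] = None,
    noise_weight: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Solve one regularized reduced-rank regression, ``target ~ predictor``.

    Returns ``(F, D, loss)`` where ``loss = ||target - F D predictor||^2``
    (the data term only).  ``noise_term`` adds ``noise_weight * noise_term``
    to the normal matrix; ``ridge_mu`` adds an isotropic ridge.
    """
    target = np.asarray(target, dtype=float)
    predictor = np.asarray(predictor, dtype=float)
    N = predictor.shape[0]
    if target.shape[1] != predictor.shape[1]:
        raise ValueError("target and predictor must have the same columns")
    if q > target.shape[0]:
        raise ValueError("rank q exceeds the number of rows")
    if ridge_mu < 0:
        raise ValueError("ridge_mu must be non-negative")

    G = predictor @ predictor.T
    if noise_term is not None:
        G = G + noise_weight * np.asarray(noise_term, dtype=float)
    if ridge_mu > 0:
        G = G + ridge_mu * np.eye(N)
    A = target @ predictor.T @ _pinv_sym(
        G, warn_singular=(ridge_mu == 0 and noise_term is None)
    )

    M = A @ predictor
    U, sv, _ = np.linalg.svd(M, full_matrices=False)
    rank = int(np.sum(sv > _PINV_RTOL * sv[0])) if sv.size and sv[0] > 0 else 0
    if q > rank:
        warnings.warn(
            f"requested rank {q} exceeds the rank {rank} of the solution; "
            "trailing components have zero variance"
        )
    F = U[:, :q].copy()
    D = F.T @ A
    F, D = _fix_signs(F, D)
    loss = float(np.sum((target - F @ (D @ predictor)) ** 2))
    return F, D, loss


@dataclass
class DpcaModel:
    """Fitted demixing model: per-marginalization decoders and encoders.

    Components are indexed globally in order of decreasing explained variance
    of the decoder projection, but each keeps its marginalization label
    (``order`` maps global rank -> (label, index within label)).
    """

    encoders: Dict[str, np.ndarray]          # label -> (N, q_phi)
    decoders: Dict[str, np.ndarray]          # label -> (q_phi, N)
    order: List[Tuple[str, int]]
    means: np.ndarray                        # (N,) centering means
    shape: Tuple[int, ...]                   # (N, S, Q, T)
    lam: float
    mu: float
    component_variance: Dict[str, np.ndarray]  # label -> (q_phi,), ||d X||^2
    training_matrix: Optional[np.ndarray] = None   # centered N x SQT PSTH

    @property
    def labels(self) -> List[str]:
        return list(self.decoders)

    @property
    def n_components(self) -> int:
        return sum(D.shape[0] for D in self.decoders.values())

    def decoder(self, label: str, i: int) -> np.ndarray:
        return self.decoders[label][i]

    def encoder(self, label: str, i: int) -> np.ndarray:
        return self.encoders[label][:, i]

    def stacked(self) -> Tuple[np.ndarray, np.ndarray, List[Tuple[str, int]]]:
        """Global-variance-ordered stacked encoders (N x q) and decoders (q x N)."""
        F = np.column_stack([self.encoders[lab][:, i] for lab, i in self.order])
        D = np.vstack([self.decoders[lab][i] for lab, i in self.order])
        return F, D, list(self.order)

    def transform(self, data, labels: Optional[Sequence[str]] = None):
        return transform(self, data, labels)

    def reconstruct(self, labels: Optional[Sequence[str]] = None,
                    q: Optional[int] = None) -> PsthTensor:
        return reconstruct(self, labels, q)


def fit(
    psth: PsthTensor,
    mset: MarginalizationSet,
    noise: Optional[NoiseCovariance] = None,
    q_per_label: Union[int, Dict[str, int]] = 10,
    lam: float = 0.0,
    keep_training_data: bool = True,
) -> DpcaModel:
    """Fit the demixing model on trial-averaged data.

    One reduced-rank regression per marginalization label, with target the
    label tensor and predictor the full centered PSTH matrix.  The noise
    covariance enters the normal matrix with weight S*Q*T (the re-balanced
    loss); the ridge is ``mu = (lam * ||X||_F)^2``.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if not psth.centered:
        raise ValueError("PSTH must be centered (compute_psths(center=True))")
    X = psth.matrix()
    N = X.shape[0]
    n_cond_cols = X.shape[1]                 # S*Q*T
    mu = (lam * np.linalg.norm(X)) ** 2

    noise_matrix = None
    if noise is not None:
        if noise.matrix.shape[0] != N:
            raise ValueError("noise covariance does not match neuron count")
        noise_matrix = noise.matrix

    if isinstance(q_per_label, int):
        q_map = {lab: q_per_label for lab in mset.tensors}
    else:
        q_map = dict(q_per_label)

    encoders: Dict[str, np.ndarray] = {}
    decoders: Dict[str, np.ndarray] = {}
    comp_var: Dict[str, np.ndarray] = {}
    for lab in mset.tensors:
        Xphi = mset.matrix(lab)
        q = min(q_map.get(lab, 0), N)
        if q == 0:
            continue
        if mset.sq_norm(lab) <= 1e-30 * max(1.0, float(np.sum(X ** 2))):
            warnings.warn(f"marginalization '{lab}' has zero variance; "
                          "no components extracted for it")
            encoders[lab] = np.zeros((N, 0))
            decoders[lab] = np.zeros((0, N))
            comp_var[lab] = np.zeros(0)
            continue
        F, D, _ = rrr_solve(
            Xphi, X, q, ridge_mu=mu,
            noise_term=noise_matrix,
            noise_weight=float(n_cond_cols) if noise_matrix is not None else 0.0,
        )
        encoders[lab] = F
        decoders[lab] = D
        comp_var[lab] = np.sum((D @ X) ** 2, axis=1)

    pairs = [(lab, i) for lab in decoders for i in range(decoders[lab].shape[0])]
    pairs.sort(key=lambda li: -comp_var[li[0]][li[1]])

    return DpcaModel(
        encoders=encoders, decoders=decoders, order=pairs,
        means=psth.means.copy(), shape=psth.values.shape,
        lam=lam, mu=mu, component_variance=comp_var,
        training_matrix=X.copy() if keep_training_data else None,
    )


def _center_input(model: DpcaModel, data) -> Tuple[np.ndarray, Tuple[int, ...]]:
    """Center arbitrary (N, ...)-shaped input with the model's stored means."""
    if isinstance(data, PsthTensor):
        arr = data.values
        if data.centered:
            return arr.reshape(arr.shape[0], -1), arr.shape[1:]
    else:
        arr = np.asarray(data, dtype=float)
    if arr.shape[0] != model.means.shape[0]:
        raise ValueError("data neuron count does not match the model")
    shape_rest = arr.shape[1:]
    flat = arr.reshape(arr.shape[0], -1) - model.means[:, None]
    return flat, shape_rest


def transform(
    model: DpcaModel, data, labels: Optional[Sequence[str]] = None
) -> Dict[str, np.ndarray]:
    """Project data onto the decoder axes: scores ``d . x`` per component.

    Works on PSTHs and on single (pseudo-)trials alike; output per label has
    shape ``(q_phi, *data.shape[1:])``.
    """
    flat, rest = _center_input(model, data)
    labels = list(model.decoders) if labels is None else list(labels)
    out = {}
    for lab in labels:
        if lab not in model.decoders:
            raise KeyError(f"unknown marginalization label '{lab}'")
        sc = model.decoders[lab] @ flat
        out[lab] = sc.reshape((sc.shape[0],) + rest)
    return out


def reconstruct(
    model: DpcaModel,
    labels: Optional[Sequence[str]] = None,
    q: Optional[int] = None,
) -> PsthTensor:
    """Low-rank reconstruction of the training PSTH from chosen components.

    Sums ``f (d X)`` over the first ``q`` components (in each label's own
    ordering) of the chosen labels, then adds back the stored means.
    """
    if model.training_matrix is None:
        raise ValueError("model was fitted without keeping the training data")
    labels = list(model.decoders) if labels is None else list(labels)
    X = model.training_matrix
    acc = np.zeros_like(X)
    for lab in labels:
        if lab not in model.decoders:
            raise KeyError(f"unknown marginalization label '{lab}'")
        qq = model.decoders[lab].shape[0] if q is None else min(q, model.decoders[lab].shape[0])
        if qq:
            F = model.encoders[lab][:, :qq]
            D = model.decoders[lab][:qq]
            acc += F @ (D @ X)
    vals = acc.reshape(model.shape) + model.means[:, None, None, None]
    T = model.shape[-1]
    return PsthTensor(values=vals, time=np.arange(T, dtype=float),
                      centered=False, means=None)
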