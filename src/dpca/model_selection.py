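"""Cross-validated selection of the ridge strength lambda.

Because neurons are recorded sequentially, ordinary trial-level CV is not
available.  Instead, one random trial per neuron per condition is held out and
assembled into S*Q test "pseudo-trials"; the remaining trials form the
training PSTHs and noise covariance.  The criterion is the residual
training-set variance not explained by the decoded test data,

    L_CV(lambda) = sum_phi ||X_train,phi - F_phi D_phi X_test||^2
                   / ||X_train||^2,

averaged over repetitions; the argmin over a logarithmic lambda grid is
selected (ties broken toward smaller lambda, i.e. the weaker prior).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple, Union

import numpy as np

from . import core
from .marginalization import MarginalizationSet, decompose
from .preprocessing import NoiseCovariance, PsthTensor, TrialTensor

__all__ = ["CvResult", "split_train_test", "cv_error", "select_lambda"]

DEFAULT_GRID = np.logspace(-7, -3, 30)


@dataclass
class CvResult:
    """Cross-validation curves over the lambda grid."""

    grid: np.ndarray                   # (G,) ascending
    curves: np.ndarray                 # (n_reps, G) per-repetition L_CV
    mean_curve: np.ndarray             # (G,)
    lambda_opt: float
    per_label_curves: Optional[Dict[str, np.ndarray]] = None
    seed: Optional[int] = None


def split_train_test(
    data: TrialTensor,
    rng: Union[int, np.random.Generator, None] = None,
) -> Tuple[PsthTensor, NoiseCovariance, np.ndarray]:
    """Hold out one random trial per neuron per condition.

    Returns ``(psth_train, noise_train, x_test)`` where ``x_test`` is the
    (N, S, Q, T) array of held-out pseudo-trials (neurons drawn
    independently), ``psth_train`` the centered average of the remaining
    trials, and ``noise_train`` the diagonal noise covariance re-estimated
    from training trials only.
    """
    rng = np.random.default_rng(rng)
    N, S, Q, T, K = data.values.shape
    counts = data.trial_counts
    if np.any(counts < 2):
        bad = np.argwhere(counts < 2)[0]
        raise ValueError(
            f"cannot split: condition (n={bad[0]}, s={bad[1]}, d={bad[2]}) "
            "has a single trial"
        )
    held = (rng.random(counts.shape) * counts).astype(int)   # uniform index

    x_test = np.take_along_axis(
        data.values, held[:, :, :, None, None], axis=4
    )[..., 0]

    train_vals = data.values.copy()
    # overwrite the held-out slot with the last valid trial, then shrink counts
    last = np.take_along_axis(
        data.values, (counts - 1)[:, :, :, None, None], axis=4
    )[..., 0]
    np.put_along_axis(train_vals, held[:, :, :, None, None],
                      last[..., None], axis=4)
    new_counts = counts - 1
    k = np.arange(K)
    invalid = k[None, None, None, None, :] >= new_counts[:, :, :, None, None]
    train_vals = np.where(invalid, np.nan, train_vals)

    train = TrialTensor(values=train_vals, trial_counts=new_counts,
                        time=data.time)
    from .preprocessing import compute_psths, estimate_noise_covariance
    psth_train = compute_psths(train, center=True)
    noise_train = estimate_noise_covariance(train, mode="diagonal",
                                            rebalanced=True)
    return psth_train, noise_train, x_test


def cv_error(
    model: core.DpcaModel,
    x_test: np.ndarray,
    train_mset: MarginalizationSet,
) -> float:
    """Normalized reconstruction error of training marginalizations from test data.

    The direction is asymmetric by design: decoders and encoders are fitted on
    the training set and applied to the held-out pseudo-trials, while the
    targets are the training-set marginalizations.
    """
    flat_test = x_test.reshape(x_test.shape[0], -1) - model.means[:, None]
    total = train_mset.total_sq_norm()
    err = 0.0
    for lab in train_mset.tensors:
        Xphi = train_mset.matrix(lab)
        if lab in model.decoders and model.decoders[lab].shape[0]:
            pred = model.encoders[lab] @ (model.decoders[lab] @ flat_test)
        else:
            pred = np.zeros_like(Xphi)
        if pred.shape != Xphi.shape:
            raise ValueError("test pseudo-trials do not match the training shape")
        err += float(np.sum((Xphi - pred) ** 2))
    return err / total


def select_lambda(
    data: TrialTensor,
    grid: Optional[np.ndarray] = None,
    n_reps: int = 10,
    q_per_label: int = 10,
    seed: Optional[int] = None,
    per_label: bool = False,
) -> CvResult:
    """Select the regularization strength by repeated pseudo-trial CV.

    Defaults follow the method's standard setup: 10 components per
    marginalization, 10 train/test repetitions, and a logarithmic grid over
    [1e-7, 1e-3].
    """
    grid = DEFAULT_GRID if grid is None else np.sort(np.asarray(grid, float))
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)

    curves = np.empty((n_reps, grid.size))
    label_curves: Dict[str, np.ndarray] = {}
    for rep in range(n_reps):
        psth_train, noise_train, x_test = split_train_test(data, rng)
        mset_train = decompose(psth_train)
        total = mset_train.total_sq_norm()
        for gi, lam in enumerate(grid):
            model = core.fit(psth_train, mset_train, noise=noise_train,
                             q_per_label=q_per_label, lam=float(lam),
                             keep_training_data=False)
            curves[rep, gi] = cv_error(model, x_test, mset_train)
            if per_label:
                flat_test = (x_test.reshape(x_test.shape[0], -1)
                             - model.means[:, None])
                for lab in mset_train.tensors:
                    pred = model.encoders[lab] @ (model.decoders[lab] @ flat_test)
                    e = float(np.sum((mset_train.matrix(lab) - pred) ** 2)) / total
                    label_curves.setdefault(
                        lab, np.empty((n_reps, grid.size)))[rep, gi] = e

    mean_curve = curves.mean(axis=0)
    if np.all(np.isnan(mean_curve)):
        raise ValueError("cross-validation produced no finite errors")
    lambda_opt = float(grid[int(np.nanargmin(mean_curve))])
    return CvResult(grid=grid, curves=curves, mean_curve=mean_curve,
                    lambda_opt=lambda_opt,
                    per_label_curves=label_curves if per_label else None,
                    seed=seed)
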