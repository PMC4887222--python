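"""ANOVA-style marginalization: split data into parameter-specific averages.

Centered population data ``x(t, s, d, ...)`` decompose additively into terms
that each depend on one subset of the task parameters (the *marginalizations*)
plus trial-to-trial noise.  The terms are built from alternating-sign sums of
averages, which makes them pairwise uncorrelated, so the population covariance
splits additively as well -- the backbone of the demixing method.

The decomposition is implemented for an arbitrary ordered parameter set; the
standard neuroscience grouping folds each purely-condition term into its
condition x time interaction, yielding the four labels
``t`` (condition-independent), ``st`` (stimulus), ``dt`` (decision) and
``sdt`` (interaction).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .preprocessing import PsthTensor, TrialTensor

__all__ = [
    "MarginalizationSet",
    "CovarianceSet",
    "default_grouping",
    "decompose",
    "marginalized_covariances",
]

Subset = frozenset
Grouping = Dict[str, List[Subset]]


def _all_subsets(params: Sequence[str]) -> List[Subset]:
    return [frozenset(c) for r in range(1, len(params) + 1)
            for c in combinations(params, r)]


def default_grouping(params: Sequence[str] = ("s", "d", "t")) -> Grouping:
    """Default grouping for (stimulus, decision, time) designs.

    Every term gains an explicit time dependence: the pure-stimulus term is
    grouped with the stimulus x time interaction, etc., because all neural
    components are expected to vary with time.
    """
    if set(params) != {"s", "d", "t"}:
        raise ValueError(
            "default grouping is defined for parameters {'s','d','t'}; "
            "supply an explicit grouping for other parameter sets"
        )
    f = frozenset
    return {
        "t": [f("t")],
        "st": [f("s"), f("st")],
        "dt": [f("d"), f("dt")],
        "sdt": [f("sd"), f("sdt")],
    }


def _validate_grouping(grouping: Grouping, params: Sequence[str]) -> None:
    wanted = _all_subsets(params)
    seen: List[Subset] = list(chain.from_iterable(grouping.values()))
    if len(seen) != len(set(seen)):
        raise ValueError("grouping assigns some parameter subset twice")
    if set(seen) != set(wanted):
        missing = set(wanted) - set(seen)
        extra = set(seen) - set(wanted)
        raise ValueError(
            f"grouping must cover every non-empty parameter subset exactly once "
            f"(missing: {sorted(map(set, missing), key=str)}, "
            f"unknown: {sorted(map(set, extra), key=str)})"
        )


@dataclass
class MarginalizationSet:
    """The additive decomposition of a centered data tensor.

    ``tensors[label]`` has PSTH shape (N, *param_dims); the label tensors sum
    to the centered source exactly.  When the source was trial-resolved,
    ``noise`` holds the per-trial residuals around the condition means.
    """

    tensors: Dict[str, np.ndarray]
    params: Tuple[str, ...]
    grouping: Grouping
    noise: Optional[np.ndarray] = None        # (N, *dims, Kmax), NaN-padded
    n_trials: Optional[np.ndarray] = None     # (N, *condition dims)

    @property
    def labels(self) -> List[str]:
        return list(self.tensors)

    def matrix(self, label: str) -> np.ndarray:
        """Label tensor flattened to N x (prod of parameter dims)."""
        t = self.tensors[label]
        return t.reshape(t.shape[0], -1)

    def total_matrix(self) -> np.ndarray:
        return sum(self.matrix(lab) for lab in self.tensors)

    def sq_norm(self, label: str) -> float:
        return float(np.sum(self.tensors[label] ** 2))

    def total_sq_norm(self) -> float:
        return float(sum(self.sq_norm(lab) for lab in self.tensors))


@dataclass
class CovarianceSet:
    """Covariance split induced by a marginalization, common denominator."""

    total: np.ndarray
    per_label: Dict[str, np.ndarray]
    noise: Optional[np.ndarray] = None


def _raw_terms(
    arr: np.ndarray, params: Sequence[str], trial_axis: Optional[int]
) -> Dict[Subset, np.ndarray]:
    """Iterative nested-average terms for every non-empty parameter subset.

    ``term(psi) = <x - sum_{tau subset psi} term(tau)>`` averaged over the
    parameters outside ``psi`` (and over trials), equivalent to the
    alternating-sign closed form.  Terms keep broadcastable singleton axes.
    """
    axes_of = {p: i + 1 for i, p in enumerate(params)}  # axis 0 = neurons
    if trial_axis is not None:
        mean_full = np.nanmean(arr, axis=trial_axis, keepdims=False)
    else:
        mean_full = arr

    terms: Dict[Subset, np.ndarray] = {}
    grand = mean_full.mean(axis=tuple(axes_of.values()), keepdims=True)
    subsets = sorted(_all_subsets(params), key=len)
    for psi in subsets:
        out_axes = tuple(axes_of[p] for p in params if p not in psi)
        term = mean_full.mean(axis=out_axes, keepdims=True) - grand
        for tau in subsets:
            if tau < psi:
                term = term - terms[tau]
        terms[psi] = term
    return terms


def decompose(
    data,
    params: Sequence[str] = ("s", "d", "t"),
    grouping: Optional[Grouping] = None,
    center_tol: float = 1e-8,
) -> MarginalizationSet:
    """Decompose centered data into grouped, pairwise-uncorrelated averages.

    ``data`` may be a centered :class:`PsthTensor`, a :class:`TrialTensor`
    (averaged to PSTHs internally; per-trial residuals are returned as the
    noise term), or a bare ndarray of shape (N, *param_dims).

    Raises if the input is not centered per neuron (tolerance ``center_tol``
    relative to the data scale).
    """
    noise = None
    n_trials = None
    if isinstance(data, TrialTensor):
        mask = data.trial_mask()
        vals = np.where(mask, data.values, np.nan)
        psth = np.nanmean(vals, axis=4)
        means = psth.mean(axis=(1, 2, 3), keepdims=True)
        psth = psth - means
        noise = vals - psth[..., None] - means[..., None]
        n_trials = data.trial_counts
        arr = psth
    elif isinstance(data, PsthTensor):
        if not data.centered:
            raise ValueError("PSTH must be centered before decomposition")
        arr = data.values
    else:
        arr = np.asarray(data, dtype=float)

    if arr.ndim != len(params) + 1:
        raise ValueError(
            f"data has {arr.ndim - 1} parameter axes but {len(params)} "
            "parameters were named"
        )
    scale = max(1.0, float(np.abs(arr).max()))
    rowmean = arr.mean(axis=tuple(range(1, arr.ndim)))
    if np.max(np.abs(rowmean)) > center_tol * scale:
        raise ValueError("data must be centered per neuron (grand mean != 0)")

    if grouping is None:
        grouping = default_grouping(params)
    else:
        _validate_grouping(grouping, params)

    single_levels = [p for i, p in enumerate(params) if arr.shape[i + 1] == 1]
    if single_levels:
        import warnings
        warnings.warn(
            f"parameter(s) {single_levels} have a single level; the "
            "corresponding marginalizations are identically zero"
        )

    terms = _raw_terms(arr, params, trial_axis=None)
    tensors: Dict[str, np.ndarray] = {}
    for label, subsets in grouping.items():
        acc = np.zeros_like(arr)
        for psi in subsets:
            acc = acc + np.broadcast_to(terms[psi], arr.shape)
        tensors[label] = acc

    return MarginalizationSet(
        tensors=tensors, params=tuple(params), grouping=grouping,
        noise=noise, n_trials=n_trials,
    )


def marginalized_covariances(mset: MarginalizationSet) -> CovarianceSet:
    """Per-label covariances ``C_phi = X_phi X_phi^T / n`` plus the total.

    All covariances share the common denominator ``n`` = number of columns of
    the source data matrix (trial-resolved columns when a noise term is
    present), so that for balanced data ``C = sum_phi C_phi + C_noise``
    holds entrywise.  The total is computed directly from the source data,
    making the additivity a genuine property rather than a bookkeeping
    identity.
    """
    psth = sum(mset.tensors.values())          # equals the centered source
    N = psth.shape[0]
    n_cols_psth = int(np.prod(psth.shape[1:]))

    if mset.noise is not None:
        counts = mset.n_trials
        K = int(counts.flat[0])
        if not np.all(counts == K):
            raise ValueError(
                "trial-resolved covariance split requires balanced trial "
                "counts; route unbalanced data through the PSTH formulation"
            )
        n = n_cols_psth * K
        # label tensors are implicitly replicated K times along trials
        per_label = {lab: mset.matrix(lab) @ mset.matrix(lab).T * K / n
                     for lab in mset.tensors}
        valid = np.isfinite(mset.noise)
        noise = np.where(valid, mset.noise, 0.0)
        Xn = noise.reshape(N, -1)
        noise_cov = Xn @ Xn.T / n
        full = np.where(valid, psth[..., None] + noise, 0.0)
        Xfull = full.reshape(N, -1)
        total = Xfull @ Xfull.T / n
    else:
        n = n_cols_psth
        per_label = {lab: mset.matrix(lab) @ mset.matrix(lab).T / n
                     for lab in mset.tensors}
        noise_cov = None
        X = psth.reshape(N, -1)
        total = X @ X.T / n
    return CovarianceSet(total=total, per_label=per_label, noise=noise_cov)
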