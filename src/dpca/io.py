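"""File formats, run configuration, and the end-to-end pipeline.

HDF5 is the canonical container for tensors and fitted models; CSV and JSON
serve the human-readable reports.  Layouts:

* trial tensor:   datasets ``values`` (N,S,Q,T,Kmax; NaN-padded),
                  ``trial_counts`` (N,S,Q), ``time`` (T,)
* spike trains:   groups ``/neurons/<id>/trials/<k>`` with ``spike_times``,
                  ``event_times`` and attrs ``stimulus``, ``decision``,
                  ``start``, ``end``, ``correct``
* fitted model:   one group per marginalization label with ``decoder``,
                  ``encoder``, ``variance``; scalar metadata in a JSON
                  sidecar (same path + ``.json``)
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import h5py
import numpy as np
import pandas as pd

from . import core, evaluation, model_selection, synthetic
from .marginalization import decompose
from .preprocessing import (NoiseCovariance, PsthTensor, SpikeTrainSet, Trial,
                            TrialTensor, compute_psths,
                            estimate_noise_covariance)

__all__ = [
    "RunConfig",
    "read_dataset",
    "write_trial_tensor",
    "read_trial_tensor",
    "write_spike_trains",
    "read_spike_trains",
    "read_long_csv",
    "write_model",
    "read_model",
    "run_pipeline",
]

log = logging.getLogger("dpca")


# ---------------------------------------------------------------------------
# trial tensors
# ---------------------------------------------------------------------------

def write_trial_tensor(path: Union[str, Path], data: TrialTensor) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=data.values)
        f.create_dataset("trial_counts", data=data.trial_counts)
        f.create_dataset("time", data=data.time)
        f.attrs["kind"] = "trial_tensor"


def read_trial_tensor(path: Union[str, Path]) -> TrialTensor:
    with h5py.File(path, "r") as f:
        try:
            return TrialTensor(values=f["values"][...],
                               trial_counts=f["trial_counts"][...],
                               time=f["time"][...])
        except KeyError as e:
            raise ValueError(f"{path}: malformed trial tensor file ({e})")


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

def write_spike_trains(path: Union[str, Path], spikes: SpikeTrainSet) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "spike_trains"
        f.attrs["n_neurons"] = spikes.n_neurons
        f.attrs["n_stimuli"] = spikes.n_stimuli
        f.attrs["n_decisions"] = spikes.n_decisions
        root = f.create_group("neurons")
        for (n, s, d), trials in spikes.trials.items():
            for k, tr in enumerate(trials):
                g = root.create_group(f"{n}/trials/{s}_{d}_{k}")
                g.create_dataset("spike_times", data=tr.spike_times)
                g.create_dataset("event_times", data=tr.event_times)
                g.attrs.update({"stimulus": s, "decision": d,
                                "start": tr.start, "end": tr.end,
                                "correct": tr.correct})


def read_spike_trains(path: Union[str, Path]) -> SpikeTrainSet:
    trials: Dict[Tuple[int, int, int], List[Trial]] = {}
    with h5py.File(path, "r") as f:
        meta = (int(f.attrs["n_neurons"]), int(f.attrs["n_stimuli"]),
                int(f.attrs["n_decisions"]))
        for nid, ng in f["neurons"].items():
            for _, g in sorted(ng["trials"].items()):
                s, d = int(g.attrs["stimulus"]), int(g.attrs["decision"])
                tr = Trial(spike_times=g["spike_times"][...],
                           start=float(g.attrs["start"]),
                           end=float(g.attrs["end"]),
                           event_times=g["event_times"][...],
                           correct=bool(g.attrs["correct"]))
                trials.setdefault((int(nid), s, d), []).append(tr)
    return SpikeTrainSet(trials=trials, n_neurons=meta[0],
                         n_stimuli=meta[1], n_decisions=meta[2])


def read_dataset(path: Union[str, Path]) -> Union[TrialTensor, SpikeTrainSet]:
    """Load a dataset, dispatching on the file's declared kind."""
    path = Path(path)
    if path.suffix == ".csv":
        return read_long_csv(path)
    with h5py.File(path, "r") as f:
        kind = f.attrs.get("kind", "trial_tensor")
    if kind == "spike_trains":
        spikes = read_spike_trains(path)
        spikes.validate()
        return spikes
    return read_trial_tensor(path)


def read_long_csv(path: Union[str, Path]) -> TrialTensor:
    """Long-format table with columns (neuron, s, d, t, k, rate).

    ``t`` may be a bin index or a time stamp; the sorted unique values define
    the grid.
    """
    df = pd.read_csv(path)
    required = {"neuron", "s", "d", "t", "k", "rate"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must have columns {sorted(required)}")
    t_vals = np.sort(df["t"].unique())
    t_index = {v: i for i, v in enumerate(t_vals)}
    N = int(df["neuron"].max()) + 1
    S = int(df["s"].max()) + 1
    Q = int(df["d"].max()) + 1
    T = len(t_vals)
    Kmax = int(df["k"].max()) + 1
    values = np.full((N, S, Q, T, Kmax), np.nan)
    values[df["neuron"], df["s"], df["d"],
           df["t"].map(t_index), df["k"]] = df["rate"]
    counts = np.zeros((N, S, Q), dtype=int)
    grp = df.groupby(["neuron", "s", "d"])["k"].max() + 1
    for (n, s, d), c in grp.items():
        counts[int(n), int(s), int(d)] = int(c)
    return TrialTensor(values=values, trial_counts=counts,
                       time=t_vals.astype(float))


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------

def write_marginalization_set(path: Union[str, Path], mset) -> None:
    """Export marginalization tensors to HDF5, one group per label."""
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "marginalization_set"
        f.attrs["params"] = list(mset.params)
        for lab, tensor in mset.tensors.items():
            g = f.create_group(lab)
            g.create_dataset("values", data=tensor)
        if mset.noise is not None:
            f.create_dataset("noise", data=mset.noise)


def read_marginalization_set(path: Union[str, Path]):
    from .marginalization import MarginalizationSet, default_grouping
    with h5py.File(path, "r") as f:
        params = tuple(p if isinstance(p, str) else p.decode()
                       for p in f.attrs["params"])
        tensors = {lab: f[lab]["values"][...] for lab in f
                   if lab != "noise"}
        noise = f["noise"][...] if "noise" in f else None
    return MarginalizationSet(tensors=tensors, params=params,
                              grouping=default_grouping(params),
                              noise=noise)


def write_model(path: Union[str, Path], model: core.DpcaModel) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "dpca_model"
        for lab in model.decoders:
            g = f.create_group(lab)
            g.create_dataset("decoder", data=model.decoders[lab])
            g.create_dataset("encoder", data=model.encoders[lab])
            g.create_dataset("variance", data=model.component_variance[lab])
        f.create_dataset("means", data=model.means)
        if model.training_matrix is not None:
            f.create_dataset("training_matrix", data=model.training_matrix)
    sidecar = {
        "lambda": model.lam, "mu": model.mu,
        "shape": list(model.shape),
        "order": [[lab, int(i)] for lab, i in model.order],
        "labels": model.labels,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_model(path: Union[str, Path]) -> core.DpcaModel:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    enc, dec, var = {}, {}, {}
    with h5py.File(path, "r") as f:
        for lab in meta["labels"]:
            dec[lab] = f[lab]["decoder"][...]
            enc[lab] = f[lab]["encoder"][...]
            var[lab] = f[lab]["variance"][...]
        means = f["means"][...]
        training = (f["training_matrix"][...]
                    if "training_matrix" in f else None)
    return core.DpcaModel(
        encoders=enc, decoders=dec,
        order=[(lab, int(i)) for lab, i in meta["order"]],
        means=means, shape=tuple(meta["shape"]),
        lam=float(meta["lambda"]), mu=float(meta["mu"]),
        component_variance=var, training_matrix=training,
    )


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Fully serializable description of one analysis run.

    ``input_path`` may be an HDF5/CSV dataset or ``simulate:<preset>`` with
    preset in {basic, unbalanced, jitter}.  ``lam=None`` triggers
    cross-validated selection.
    """

    input_path: str
    output_dir: str
    q_per_label: int = 10
    lam: Optional[float] = None
    cv_reps: int = 10
    cv_grid: Optional[List[float]] = None
    seed: int = 0
    smoothing_sigma_ms: float = 50.0
    rate_hz: float = 100.0
    classification: bool = False
    n_cv: int = 100
    n_shuffles: int = 100
    verbosity: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _load_input(config: RunConfig) -> TrialTensor:
    from .preprocessing import smooth_spike_trains
    if config.input_path.startswith("simulate:"):
        preset = config.input_path.split(":", 1)[1]
        if preset == "basic":
            data, _ = synthetic.generate_population(seed=config.seed)
        elif preset == "unbalanced":
            _, data = synthetic.generate_unbalanced_toy(seed=config.seed)
        elif preset == "jitter":
            data, _ = synthetic.generate_jittered_population(seed=config.seed)
        else:
            raise ValueError(f"unknown simulate preset '{preset}'")
        return data
    loaded = read_dataset(config.input_path)
    if isinstance(loaded, SpikeTrainSet):
        return smooth_spike_trains(loaded, sigma_ms=config.smoothing_sigma_ms,
                                   rate_hz=config.rate_hz)
    return loaded


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute the full analysis described by a config; write artifacts.

    Stages: load/simulate -> PSTH + noise covariance -> marginalization ->
    (optional) CV for lambda -> fit -> variance / demixing / angle reports
    (-> optional classification significance).  Every artifact records the
    config hash.  Returns the summary dict.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr,
                        level=getattr(logging, config.verbosity.upper(), 20))
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    chash = config.config_hash()
    (out / "config.json").write_text(config.to_json())

    current_stage = {"name": "init"}

    def stage(name):
        current_stage["name"] = name
        log.info("stage: %s", name)

    try:
        stage("load")
        data = _load_input(config)
        stage("preprocess")
        psth = compute_psths(data, center=True)
        noise = estimate_noise_covariance(data, mode="diagonal",
                                          rebalanced=True)
        stage("marginalize")
        mset = decompose(psth)

        lam = config.lam
        cv_summary = None
        if lam is None:
            stage("crossval")
            grid = (np.asarray(config.cv_grid)
                    if config.cv_grid else None)
            cv = model_selection.select_lambda(
                data, grid=grid, n_reps=config.cv_reps,
                q_per_label=config.q_per_label, seed=config.seed)
            lam = cv.lambda_opt
            pd.DataFrame(cv.curves, columns=[f"{l:.3e}" for l in cv.grid]
                         ).to_csv(out / "cv_curves.csv", index=False)
            cv_summary = {"lambda_opt": cv.lambda_opt,
                          "grid": cv.grid.tolist(),
                          "mean_curve": cv.mean_curve.tolist()}

        stage("fit")
        model = core.fit(psth, mset, noise=noise,
                         q_per_label=config.q_per_label, lam=lam)
        write_model(out / "model.h5", model)

        stage("evaluate")
        var = evaluation.explained_variance(model, psth, mset)
        sig = evaluation.signal_variance(noise, psth, mset)
        F, D, order = model.stacked()
        dmx = [evaluation.demixing_index(D[i], mset) for i in range(D.shape[0])]
        dots, starred = evaluation.axis_significance(F)

        table = pd.DataFrame({
            "rank": np.arange(1, len(order) + 1),
            "label": [lab for lab, _ in order],
            "within_label_index": [i for _, i in order],
            "r2": var.component_r2,
            "cumulative_r2": var.cumulative_r2,
            "demixing_index": dmx,
        })
        for lab, vals in (var.label_split or {}).items():
            table[f"r2_{lab}"] = vals
        table.to_csv(out / "variance.csv", index=False)

        summary = {
            "config_hash": chash,
            "lambda": lam,
            "cv": cv_summary,
            "n_components": model.n_components,
            "total_r2": var.total_r2,
            "signal_fraction": sig.signal_fraction,
            "pie_percent": sig.pie_percent,
            "mean_demixing_index": float(np.nanmean(dmx)),
            "n_significant_axis_pairs": int(starred.sum() // 2),
        }

        if config.classification:
            stage("classification")
            rep = evaluation.classification_significance(
                data, lam=lam, n_cv=config.n_cv,
                n_shuffles=config.n_shuffles, seed=config.seed)
            rows = []
            for lab, m in rep.mask.items():
                for i in range(m.shape[0]):
                    for t in range(m.shape[1]):
                        rows.append((lab, i, t, rep.accuracy[lab][i, t],
                                     bool(m[i, t])))
            pd.DataFrame(rows, columns=["label", "component", "time_bin",
                                        "accuracy", "significant"]
                         ).to_csv(out / "significance.csv", index=False)
            summary["significant_bins"] = {
                lab: int(m.sum()) for lab, m in rep.mask.items()}

        (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                     sort_keys=True))
        return summary
    except Exception as e:
        raise RuntimeError(
            f"pipeline failed at stage '{current_stage['name']}': {e}"
        ) from e
    finally:
        log.removeHandler(fh)
        fh.close()
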