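"""Readers, writers and run configuration.

CSV is the canonical tabular interchange (epochs, condition summaries,
evidence matrices, parameter tables); JSON holds manifests and diagnostics;
force traces can go to CSV or HDF5.  Deposited MAT-format source-data files
(payoff per participant-visit, fitted parameter values, regression weights)
are ingested read-only into tidy long tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ConditionSummary
from .model import ParameterSet
from .simulate import SyntheticDataset

__all__ = [
    "RunConfig",
    "read_source_data",
    "save_dataset",
    "load_dataset",
    "save_trace_csv",
    "load_trace_csv",
]

# Expected variable content per source-data file kind.
_SOURCE_VARIABLES = {
    "fig1": ["payoff"],
    "fig2": ["Ai", "Sem", "Sed", "Srm", "Sri"],
    "fig3": [
        "effort_mean", "effort_incentive", "effort_difficulty",
        "rest_mean", "rest_incentive", "rest_difficulty",
    ],
}

# Name heuristics: lowercase substring -> canonical variable label.
_NAME_HEURISTICS = {
    "payoff": "payoff", "gain": "payoff",
    "sem": "Sem", "se_m": "Sem", "srm": "Srm", "sr_m": "Srm",
    "sed": "Sed", "se_d": "Sed", "sri": "Sri", "sr_i": "Sri",
    "ai": "Ai", "a_i": "Ai",
}


@dataclass
class RunConfig:
    """Serializable settings of one pipeline run."""

    seed: int = 0
    output_dir: str = "."
    fs: float = 100.0
    trial_length: float = 30.0
    n_blocks: int = 8
    noise_frac: float = 0.03
    n_perm: int = 10000
    inflation: float = 0.20
    n_reps: int = 100
    extras: dict = field(default_factory=dict)

    def to_json(self, path):
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _load_mat(path):
    """Load MAT v5 via scipy or v7.3 via h5py into {name: ndarray}."""
    path = Path(path)
    try:
        from scipy.io import loadmat

        raw = loadmat(path, squeeze_me=True)
        return {
            k: np.asarray(v)
            for k, v in raw.items()
            if not k.startswith("__") and np.asarray(v).dtype.kind in "fiu"
        }
    except Exception:
        pass
    try:
        import h5py

        out = {}
        with h5py.File(path, "r") as h:
            def visit(name, obj):
                if isinstance(obj, h5py.Dataset) and obj.dtype.kind in "fiu":
                    out[name.split("/")[-1]] = np.asarray(obj)

            h.visititems(visit)
        return out
    except Exception as exc:
        raise ValueError(f"cannot read MAT file {path}: {exc}") from exc


def read_source_data(path, which: str, mapping: dict | None = None) -> pd.DataFrame:
    """Read a deposited source-data MAT file into a tidy long table.

    Parameters
    ----------
    path
        MAT-format file (v5 or v7.3).
    which
        ``"fig1"`` (payoff per participant-visit), ``"fig2"`` (fitted
        parameter values) or ``"fig3"`` (duration-regression weights).
    mapping
        Optional override mapping MAT variable name -> canonical variable
        label, for files whose internal naming defeats the heuristics.

    Returns a DataFrame with columns (subject, visit, group, variable,
    value).  Group assignment expects either separate per-group variables
    (names containing "placebo"/"escitalopram") or a grouping vector named
    like "group"; otherwise group is labelled "unknown".  An unrecognizable
    layout raises an error listing the discovered variables.
    """
    if which not in _SOURCE_VARIABLES:
        raise ValueError(f"which must be one of {sorted(_SOURCE_VARIABLES)}")
    arrays = _load_mat(path)
    if not arrays:
        raise ValueError(f"no numeric variables found in {path}")
    wanted = _SOURCE_VARIABLES[which]
    resolved: dict[tuple[str, str], np.ndarray] = {}

    def classify(name: str):
        low = name.lower()
        group = "unknown"
        if "placebo" in low:
            group = "placebo"
        elif "escit" in low or "ssri" in low:
            group = "escitalopram"
        label = (mapping or {}).get(name)
        if label is None:
            for key, lab in sorted(_NAME_HEURISTICS.items(), key=lambda kv: -len(kv[0])):
                if key in low and lab in wanted:
                    label = lab
                    break
        if label is None and len(wanted) == 1:
            label = wanted[0]
        return label, group

    for name, arr in arrays.items():
        label, group = classify(name)
        if label is not None:
            resolved[(label, group, name)] = np.atleast_2d(np.asarray(arr, float))
    if not resolved:
        raise ValueError(
            f"could not map any variable in {path} to {wanted}; discovered "
            f"variables: {sorted(arrays)}; pass an explicit `mapping`"
        )
    records = []
    for (label, group, name), arr in resolved.items():
        if arr.shape[0] < arr.shape[1]:
            arr = arr.T           # subjects in rows, visits in columns
        for s in range(arr.shape[0]):
            for v in range(arr.shape[1]):
                val = arr[s, v]
                if np.isfinite(val):
                    records.append(
                        {"subject": s, "visit": v, "group": group,
                         "variable": label, "value": float(val),
                         "source_name": name}
                    )
    return pd.DataFrame.from_records(records)


def save_dataset(dataset: SyntheticDataset, directory):
    """Write a synthetic cohort as CSVs + a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s, visits in dataset.summaries.items():
        for v, summ in enumerate(visits):
            df = summ.to_frame()
            df.insert(0, "subject", s)
            df.insert(1, "visit", v)
            rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(
        directory / "summaries.csv", index=False
    )
    manifest = {
        "group": dataset.spec.group,
        "n_subjects": dataset.spec.n_subjects,
        "n_visits": dataset.spec.n_visits,
        "seed": dataset.spec.seed,
        "duration_noise_frac": dataset.spec.duration_noise_frac,
        "duration_noise_sd": dataset.spec.duration_noise_sd,
        "population": {k: list(v) for k, v in dataset.spec.population.items()},
        "true_parameters": [p.as_dict() for p in dataset.parameters],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_dataset(directory) -> SyntheticDataset:
    """Round-trip loader for :func:`save_dataset` output."""
    from .simulate import CohortSpec

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    spec = CohortSpec(
        group=manifest["group"],
        n_subjects=manifest["n_subjects"],
        n_visits=manifest["n_visits"],
        seed=manifest["seed"],
        duration_noise_frac=manifest["duration_noise_frac"],
        duration_noise_sd=manifest["duration_noise_sd"],
        population={k: tuple(v) for k, v in manifest["population"].items()},
    )
    params = [
        ParameterSet(**{k: v for k, v in d.items()})
        for d in manifest["true_parameters"]
    ]
    df = pd.read_csv(directory / "summaries.csv")
    summaries = {}
    for (s, v), sub in df.groupby(["subject", "visit"]):
        summaries.setdefault(int(s), {})[int(v)] = ConditionSummary.from_frame(sub)
    summaries = {s: [d[v] for v in sorted(d)] for s, d in summaries.items()}
    return SyntheticDataset(spec=spec, parameters=params, summaries=summaries)


def save_trace_csv(trace, path):
    pd.DataFrame({"t": trace.t, "f": trace.f}).to_csv(path, index=False)


def load_trace_csv(path, cond, fs=None):
    from .simulate import ForceTrace

    df = pd.read_csv(path)
    t = df["t"].to_numpy(float)
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    return ForceTrace(t=t, f=df["f"].to_numpy(float), fs=fs, cond=cond)
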