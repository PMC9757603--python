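"""Neutral on-disk interchange format for kinematic trials.

A trial is a directory with three tabular files and a JSON sidecar::

    trial/
      joint_velocities.csv         K rows x n columns
      endeffector_velocities.csv   K rows x m columns
      jacobians.csv                K rows x (m*n) columns, row-major per step
      meta.json                    {"n", "m", "dt", "labels", ...}

Optionally ``joint_positions.csv`` (K x n).  The format is language-neutral,
diff-able and round-trips losslessly (floats written with full precision),
so generated and recorded data are interchangeable everywhere in the
package.  A cohort is a directory tree ``participant/condition/target/
trial-XXX/`` with a ``cohort.json`` manifest at the root.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .estimation import KinematicDataset

__all__ = ["write_trial", "read_trial", "MissingTrialFileError"]

_FILES = {
    "joint_velocities": "joint_velocities.csv",
    "endeffector_velocities": "endeffector_velocities.csv",
    "jacobians": "jacobians.csv",
    "meta": "meta.json",
}


class MissingTrialFileError(FileNotFoundError):
    """A trial directory lacks one of the required interchange files."""

    def __init__(self, path: Path, missing: str):
        super().__init__(f"trial directory {path} is missing required file '{missing}'")
        self.missing = missing


def write_trial(dataset: KinematicDataset, directory) -> Path:
    """Write a dataset as one interchange trial directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    K, n, m = dataset.n_samples, dataset.n, dataset.m

    def _write(arr: np.ndarray, name: str, prefix: str):
        cols = [f"{prefix}{i + 1}" for i in range(arr.shape[1])]
        # default float formatting is shortest round-trip repr: lossless
        pd.DataFrame(arr, columns=cols).to_csv(directory / name, index=False)

    _write(dataset.joint_velocities.T, _FILES["joint_velocities"], "q_dot_")
    _write(dataset.endeffector_velocities.T, _FILES["endeffector_velocities"], "x_dot_")
    _write(dataset.jacobians.reshape(K, m * n), _FILES["jacobians"], "J_")
    if dataset.joint_positions is not None:
        _write(dataset.joint_positions.T, "joint_positions.csv", "q_")
    meta = {
        "n": n,
        "m": m,
        "n_samples": K,
        "dt": dataset.dt,
        "labels": dataset.labels,
    }
    (directory / _FILES["meta"]).write_text(json.dumps(meta, indent=2))
    return directory


def read_trial(directory) -> KinematicDataset:
    """Load one interchange trial directory back into a dataset."""
    directory = Path(directory)
    for key in ("joint_velocities", "endeffector_velocities", "jacobians", "meta"):
        if not (directory / _FILES[key]).exists():
            raise MissingTrialFileError(directory, _FILES[key])
    meta = json.loads((directory / _FILES["meta"]).read_text())
    n, m = int(meta["n"]), int(meta["m"])

    def _read(name):
        # round_trip parsing keeps the stored shortest-repr floats bit-exact
        return pd.read_csv(directory / name, float_precision="round_trip").to_numpy(float)

    Q = _read(_FILES["joint_velocities"])
    X = _read(_FILES["endeffector_velocities"])
    Jflat = _read(_FILES["jacobians"])
    K = Q.shape[0]
    if Q.shape[1] != n or X.shape[1] != m or Jflat.shape != (K, m * n):
        raise ValueError(
            f"inconsistent interchange shapes in {directory}: "
            f"q_dot {Q.shape}, x_dot {X.shape}, J {Jflat.shape} for n={n}, m={m}"
        )
    pos_path = directory / "joint_positions.csv"
    positions: Optional[np.ndarray] = None
    if pos_path.exists():
        positions = _read("joint_positions.csv").T
    return KinematicDataset(
        joint_velocities=Q.T,
        endeffector_velocities=X.T,
        jacobians=Jflat.reshape(K, m, n),
        joint_positions=positions,
        dt=meta.get("dt"),
        labels=meta.get("labels") or {},
    )
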