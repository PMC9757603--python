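"""Cohort-level workflows: per-participant weight estimation and contrasts.

Wraps the single-dataset estimator for study designs of the form
participant x condition (x target x trial): loading recordings from
MAT-files or the neutral interchange tree, estimating one weight vector
per (participant, condition), extracting null-space velocity profiles
under the estimated weights versus the conventional identity weights, and
testing a paired condition contrast with Hotelling's T-squared.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.io import loadmat

from .estimation import (
    EstimationConfig,
    KinematicDataset,
    contribution_coefficients,
    estimate_weights,
)
from .kinematics import WeightVector, decompose_velocity
from .interchange import read_trial, write_trial

__all__ = [
    "CohortRecordings",
    "ConditionContrast",
    "DatasetLayoutError",
    "load_paper_dataset",
    "load_cohort",
    "save_cohort",
    "estimate_cohort_weights",
    "nullspace_utilization",
    "aggregate_null_profiles",
    "paired_hotelling_contrast",
    "group_contribution_coefficients",
    "EXPERIMENT1_CONDITIONS",
    "EXPERIMENT2_CONDITIONS",
]

EXPERIMENT1_CONDITIONS = ("Natural", "Viscous")
EXPERIMENT2_CONDITIONS = ("Natural", "Locked", "Coupled", "Assistive")

#: Target key used when a study has no target structure (one trial/condition).
_NO_TARGET = "all"


class DatasetLayoutError(ValueError):
    """A recordings file does not follow the expected cohort layout."""


@dataclass
class CohortRecordings:
    """Recordings of a cohort: participant -> condition -> target -> trials.

    ``trials[participant][condition][target]`` is an ordered list of
    :class:`~ikweights.estimation.KinematicDataset`.  All trials of a
    participant share joint count n and task dimension m.  Missing trials
    are tolerated (lists may have different lengths across targets).
    """

    trials: Dict[str, Dict[str, Dict[str, List[KinematicDataset]]]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for pid, conditions in self.trials.items():
            dims = set()
            for cond, targets in conditions.items():
                for target, tlist in targets.items():
                    for i, trial in enumerate(tlist):
                        dims.add((trial.n, trial.m))
            if len(dims) > 1:
                raise DatasetLayoutError(
                    f"participant {pid!r} mixes chain dimensions {sorted(dims)}"
                )

    @property
    def participants(self) -> List[str]:
        return list(self.trials)

    @property
    def conditions(self) -> List[str]:
        conds: List[str] = []
        for p in self.trials.values():
            for c in p:
                if c not in conds:
                    conds.append(c)
        return conds

    def condition_dataset(self, participant: str, condition: str) -> KinematicDataset:
        """All trials of one participant/condition concatenated column-wise."""
        targets = self.trials[participant][condition]
        datasets = [t for tlist in targets.values() for t in tlist]
        if not datasets:
            raise DatasetLayoutError(
                f"no trials for participant {participant!r}, condition {condition!r}"
            )
        return KinematicDataset.concatenate(
            datasets, labels={"participant": participant, "condition": condition}
        )

    def iter_trials(self):
        """Yield ``(participant, condition, target, trial_index, dataset)``."""
        for pid, conditions in self.trials.items():
            for cond, targets in conditions.items():
                for target, tlist in targets.items():
                    for i, trial in enumerate(tlist):
                        yield pid, cond, target, i, trial


def _trial_from_mat(entry, pid, cond, target, index) -> KinematicDataset:
    """Build a dataset from one MAT trial struct.

    Expected fields: ``dq`` (K x n joint velocities), ``dx`` (K x m
    end-effector velocities), ``J`` (K x (m*n) row-major, or m x n x K),
    optional ``q`` (K x n) and scalar ``dt``.
    """
    where = f"participant {pid!r}, condition {cond!r}, target {target!r}, trial {index}"
    fields = {f: getattr(entry, f) for f in getattr(entry, "_fieldnames", []) if hasattr(entry, f)}
    for name in ("dq", "dx", "J"):
        if name not in fields:
            raise DatasetLayoutError(f"missing field '{name}' in {where}")
    dq = np.atleast_2d(np.asarray(fields["dq"], dtype=float))
    dx = np.atleast_2d(np.asarray(fields["dx"], dtype=float))
    K, n = dq.shape
    if dx.shape[0] != K:
        raise DatasetLayoutError(f"dq has {K} steps but dx has {dx.shape[0]} in {where}")
    m = dx.shape[1]
    J = np.asarray(fields["J"], dtype=float)
    if J.shape == (K, m * n):
        J = J.reshape(K, m, n)
    elif J.shape == (m, n, K):
        J = np.moveaxis(J, -1, 0)
    elif J.shape != (K, m, n):
        raise DatasetLayoutError(f"jacobian shape {J.shape} unrecognized in {where}")
    q = fields.get("q")
    positions = None if q is None else np.atleast_2d(np.asarray(q, dtype=float)).T
    dt = fields.get("dt")
    return KinematicDataset(
        joint_velocities=dq.T,
        endeffector_velocities=dx.T,
        jacobians=J,
        joint_positions=positions,
        dt=None if dt is None else float(np.asarray(dt).ravel()[0]),
        labels={"participant": pid, "condition": cond, "target": target, "trial": index},
    )


def _as_list(obj) -> list:
    if obj is None:
        return []
    arr = np.asarray(obj, dtype=object)
    if arr.ndim == 0:
        return [arr.item()]
    return list(arr.ravel())


def load_paper_dataset(path, experiment: int) -> CohortRecordings:
    """Load a supplementary-style MAT-file cohort.

    ``experiment=1`` expects the viscous-field layout: one struct per
    participant with fields ``Natural``/``Viscous``, each holding target
    structs (``target1``..``target3`` or a cell array) whose elements are
    trial structs (see :func:`_trial_from_mat` for trial fields).
    ``experiment=2`` expects fields ``Natural``/``Locked``/``Coupled``/
    ``Assistive``, each a single trial struct.  Directories are dispatched
    to the neutral interchange reader instead.
    """
    path = Path(path)
    if path.is_dir():
        return load_cohort(path)
    if experiment not in (1, 2):
        raise ValueError("experiment must be 1 or 2")
    conditions = EXPERIMENT1_CONDITIONS if experiment == 1 else EXPERIMENT2_CONDITIONS
    mat = loadmat(path, squeeze_me=True, struct_as_record=False)
    payload = {k: v for k, v in mat.items() if not k.startswith("__")}
    if "participants" in payload:
        participants = _as_list(payload["participants"])
    elif len(payload) == 1:
        participants = _as_list(next(iter(payload.values())))
    else:
        raise DatasetLayoutError(
            f"expected a single 'participants' variable; found {sorted(payload)}"
        )

    trials: Dict[str, Dict[str, Dict[str, List[KinematicDataset]]]] = {}
    for p_idx, pstruct in enumerate(participants):
        pid = f"P{p_idx + 1:02d}"
        trials[pid] = {}
        for cond in conditions:
            if not hasattr(pstruct, cond):
                raise DatasetLayoutError(
                    f"participant {pid!r} is missing condition field '{cond}'"
                )
            cond_obj = getattr(pstruct, cond)
            trials[pid][cond] = {}
            if experiment == 2:
                trials[pid][cond][_NO_TARGET] = [
                    _trial_from_mat(cond_obj, pid, cond, _NO_TARGET, 0)
                ]
                continue
            target_fields = [f for f in getattr(cond_obj, "_fieldnames", []) if f.lower().startswith("target")]
            if not target_fields:
                raise DatasetLayoutError(
                    f"participant {pid!r}, condition '{cond}' has no target fields"
                )
            for target in target_fields:
                tlist = _as_list(getattr(cond_obj, target))
                trials[pid][cond][target] = [
                    _trial_from_mat(t, pid, cond, target, i) for i, t in enumerate(tlist)
                ]
    return CohortRecordings(trials=trials, metadata={"experiment": experiment, "source": str(path)})


def save_cohort(recordings: CohortRecordings, directory) -> Path:
    """Write a cohort as a neutral interchange directory tree."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"metadata": recordings.metadata, "participants": {}}
    for pid, cond, target, i, trial in recordings.iter_trials():
        rel = Path(pid) / cond / str(target) / f"trial-{i:03d}"
        write_trial(trial, directory / rel)
        manifest["participants"].setdefault(pid, {}).setdefault(cond, {}).setdefault(
            str(target), []
        ).append(str(rel))
    (directory / "cohort.json").write_text(json.dumps(manifest, indent=2))
    return directory


def load_cohort(directory) -> CohortRecordings:
    """Read a cohort written by :func:`save_cohort`."""
    directory = Path(directory)
    manifest_path = directory / "cohort.json"
    if not manifest_path.exists():
        raise DatasetLayoutError(f"no cohort.json manifest in {directory}")
    manifest = json.loads(manifest_path.read_text())
    trials: Dict[str, Dict[str, Dict[str, List[KinematicDataset]]]] = {}
    for pid, conditions in manifest["participants"].items():
        trials[pid] = {}
        for cond, targets in conditions.items():
            trials[pid][cond] = {}
            for target, rels in targets.items():
                trials[pid][cond][target] = [read_trial(directory / rel) for rel in rels]
    return CohortRecordings(trials=trials, metadata=manifest.get("metadata", {}))


def estimate_cohort_weights(
    recordings: CohortRecordings,
    config: Optional[EstimationConfig] = None,
    grouping: str = "per-condition-concatenated",
) -> pd.DataFrame:
    """Estimate one weight vector per key and tabulate weights and betas.

    ``grouping='per-condition-concatenated'`` concatenates all targets and
    trials of a condition into one dataset per (participant, condition) —
    the default, mirroring how recorded cohorts ship their per-condition
    data.  ``grouping='per-trial'`` estimates every trial separately and
    keys rows by (participant, condition, target, trial).

    Estimation failures are re-raised with the offending key in the
    message.
    """
    config = config or EstimationConfig()
    if grouping not in ("per-condition-concatenated", "per-trial"):
        raise ValueError(f"unknown grouping {grouping!r}")
    rows = []
    if grouping == "per-condition-concatenated":
        jobs = [
            ((pid, cond), recordings.condition_dataset(pid, cond))
            for pid in recordings.trials
            for cond in recordings.trials[pid]
        ]
        index_names = ["participant", "condition"]
    else:
        jobs = [
            ((pid, cond, target, i), trial)
            for pid, cond, target, i, trial in recordings.iter_trials()
        ]
        index_names = ["participant", "condition", "target", "trial"]

    for key, dataset in jobs:
        try:
            result = estimate_weights(dataset, config)
        except Exception as exc:
            raise type(exc)(f"estimation failed for {key}: {exc}") from exc
        w = np.asarray(result.weights)
        beta = contribution_coefficients(w)
        row = dict(zip(index_names, key))
        row.update({f"w{j + 1}": w[j] for j in range(w.size)})
        row.update({f"beta{j + 1}": beta[j] for j in range(w.size)})
        row["converged"] = result.converged
        row["iterations"] = result.iterations_used
        rows.append(row)
    return pd.DataFrame(rows).set_index(index_names)


def _weights_from_row(row: pd.Series) -> np.ndarray:
    cols = sorted((c for c in row.index if c.startswith("w") and c[1:].isdigit()),
                  key=lambda c: int(c[1:]))
    return row[cols].to_numpy(float)


def nullspace_utilization(
    recordings: CohortRecordings,
    weights: pd.DataFrame,
) -> pd.DataFrame:
    """Null-space velocity profiles under estimated versus identity weights.

    For every trial and time step, decomposes the recorded joint velocity
    twice — once with the (participant, condition) weight estimate, once
    with identity weights — and returns a long-format table with columns
    ``participant, condition, target, trial, time_index, joint,
    null_estimated, null_identity``.  Both decompositions conserve the
    recorded velocity (task + null = q_dot) by construction.
    """
    records = []
    for pid, cond, target, i, trial in recordings.iter_trials():
        w = _weights_from_row(weights.loc[(pid, cond)])
        wv = WeightVector.from_values(w)
        identity = WeightVector(np.ones(trial.n))
        for k in range(trial.n_samples):
            sample = trial.sample(k)
            d_est = decompose_velocity(sample, wv)
            d_eye = decompose_velocity(sample, identity)
            for j in range(trial.n):
                records.append(
                    {
                        "participant": pid,
                        "condition": cond,
                        "target": target,
                        "trial": i,
                        "time_index": k,
                        "joint": j + 1,
                        "null_estimated": d_est.null_velocity[j],
                        "null_identity": d_eye.null_velocity[j],
                    }
                )
    return pd.DataFrame(records)


def aggregate_null_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of null-space velocity across trials/participants per step."""
    return (
        profiles.groupby(["condition", "time_index", "joint"])[
            ["null_estimated", "null_identity"]
        ]
        .agg(["mean", "std"])
        .reset_index()
    )


@dataclass(frozen=True)
class ConditionContrast:
    """Paired multivariate contrast between two conditions.

    ``t_squared`` is Hotelling's T² on the paired differences,
    ``f_statistic`` its exact F transform with ``df = (p, N - p)`` and
    ``p_value`` the upper tail of that F distribution.
    """

    t_squared: float
    f_statistic: float
    df: tuple
    p_value: float
    differences: np.ndarray

    def formatted_p(self, floor: float = 1e-3) -> str:
        return f"< {floor:g}" if self.p_value < floor else f"{self.p_value:.4g}"

    def to_dict(self) -> dict:
        return {
            "t_squared": self.t_squared,
            "f_statistic": self.f_statistic,
            "df": list(self.df),
            "p_value": self.p_value,
            "p_display": self.formatted_p(),
            "n_pairs": int(self.differences.shape[0]),
        }


def paired_hotelling_contrast(weights_a, weights_b) -> ConditionContrast:
    """Paired Hotelling T² test on per-participant weight components.

    Rows are participants (paired across the two inputs), columns the
    compared weight components (components pinned by convention, e.g. the
    max-normalized anchor or an over-specified joint, must be excluded —
    their paired differences are degenerate).  With N pairs and p
    components, ``T² = N d_bar' S^-1 d_bar`` on the differences and
    ``F = (N - p) / (p (N - 1)) T²`` with df ``(p, N - p)``.
    """
    A = np.atleast_2d(np.asarray(weights_a, dtype=float))
    B = np.atleast_2d(np.asarray(weights_b, dtype=float))
    if A.shape != B.shape:
        raise ValueError("paired weight tables must have identical shape")
    N, p = A.shape
    if N <= p:
        raise ValueError(f"need more participants ({N}) than components ({p})")
    D = A - B
    if np.all(D == 0):
        # identical conditions: no effect, by convention T2 = 0 and p = 1
        return ConditionContrast(
            t_squared=0.0, f_statistic=0.0, df=(p, N - p), p_value=1.0, differences=D
        )
    d_bar = D.mean(axis=0)
    S = np.cov(D, rowvar=False, ddof=1).reshape(p, p)
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "singular covariance of paired differences; drop degenerate "
            "(pinned or constant) weight components before the contrast"
        )
    t2 = float(N * d_bar @ np.linalg.solve(S, d_bar))
    f_stat = float((N - p) / (p * (N - 1)) * t2)
    p_value = float(stats.f.sf(f_stat, p, N - p))
    return ConditionContrast(
        t_squared=t2, f_statistic=f_stat, df=(p, N - p), p_value=p_value, differences=D
    )


def group_contribution_coefficients(
    weights: pd.DataFrame, condition: str, method: str = "median"
) -> np.ndarray:
    """Group-level contribution coefficients for one condition.

    ``method='median'``/``'mean'`` aggregates the per-participant weights
    first and transforms the aggregate; ``'transform-then-aggregate'``
    transforms each participant's weights and takes the median of the
    coefficients (renormalized to sum to 1).
    """
    sub = weights.xs(condition, level="condition")
    W = np.vstack([_weights_from_row(row) for _, row in sub.iterrows()])
    if method == "median":
        return contribution_coefficients(np.median(W, axis=0))
    if method == "mean":
        return contribution_coefficients(W.mean(axis=0))
    if method == "transform-then-aggregate":
        betas = np.vstack([contribution_coefficients(w) for w in W])
        agg = np.median(betas, axis=0)
        return agg / agg.sum()
    raise ValueError(f"unknown aggregation method {method!r}")
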