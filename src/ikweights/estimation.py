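"""Identification of inverse-kinematics weights from observed motion.

Observed joint velocities are modeled as ``q_dot_k = J#_k x_dot_k + v_k``
where ``J#_k`` is the weighted pseudo-inverse at sample ``k`` and ``v_k``
is a null-space velocity.  The diagonal weight matrix ``W`` is unknown;
because ``J#`` depends on ``W`` nonlinearly, it is identified iteratively:

1. *Evaluation* — with the current estimate ``W_bar``, attribute a fraction
   ``gamma`` of the projected velocity to the null space,
   ``v_bar_k = gamma (I - J#_bar J_k) q_dot_k``, and record the mean
   per-sample residual ``e``.
2. *Update* — rewrite the model as the linear system
   ``W_bar (Q_dot - V_bar) = U_bar`` with the auxiliary variable
   ``u_bar_k = J_k^T (J_k W_bar^{-1} J_k^T)^{-1} x_dot_k``, multiply both
   sides by ``Q_dot^T`` and solve for the diagonal of ``W`` by
   box-constrained quadratic programming (weights in ``(0, 1]``), then
   max-normalize.

The loop is quasi-static: ``U_bar`` is held at the current estimate while
``W`` is updated, and repeats until the residual drops below a threshold
or an iteration budget is exhausted.  ``gamma = 1`` makes any weight
matrix fit perfectly, so no update ever occurs; small ``gamma`` risks
explaining genuine null-space motion through the task-space model.  A
scheduled ``gamma`` ramping toward 1 trades early convergence speed for
late optimality.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize

from .kinematics import (
    RCOND_THRESHOLD,
    WEIGHT_FLOOR,
    KinematicSample,
    SingularJacobianError,
    WeightVector,
)

__all__ = [
    "KinematicDataset",
    "GammaSchedule",
    "EstimationConfig",
    "QPProblem",
    "QPSolverError",
    "EstimationResult",
    "assemble_linear_system",
    "solve_weight_qp",
    "estimate_weights",
    "contribution_coefficients",
    "detect_overspecified_joints",
]

logger = logging.getLogger(__name__)


class QPSolverError(RuntimeError):
    """Raised when the box-constrained QP solver fails; carries its status."""

    def __init__(self, message: str, status: object = None):
        super().__init__(message)
        self.status = status


@dataclass(frozen=True)
class KinematicDataset:
    """Ordered collection of K samples sharing joint count n and task dim m.

    Stored columnwise: ``joint_velocities`` is n x K, ``endeffector_velocities``
    m x K, ``jacobians`` K x m x n.  ``labels`` carries provenance metadata
    (participant, condition, target, trial) and ``dt`` the sample period when
    known.
    """

    joint_velocities: np.ndarray
    endeffector_velocities: np.ndarray
    jacobians: np.ndarray
    joint_positions: Optional[np.ndarray] = None
    dt: Optional[float] = None
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        Q = np.atleast_2d(np.asarray(self.joint_velocities, dtype=float))
        X = np.atleast_2d(np.asarray(self.endeffector_velocities, dtype=float))
        J = np.asarray(self.jacobians, dtype=float)
        if J.ndim == 2:
            J = J[None]
        n, K = Q.shape
        m = X.shape[0]
        if X.shape[1] != K:
            raise ValueError("joint and end-effector velocity sample counts differ")
        if J.shape != (K, m, n):
            raise ValueError(f"jacobians shape {J.shape} != expected {(K, m, n)}")
        if K < 1:
            raise ValueError("dataset must contain at least one sample")
        object.__setattr__(self, "joint_velocities", Q)
        object.__setattr__(self, "endeffector_velocities", X)
        object.__setattr__(self, "jacobians", J)
        if self.joint_positions is not None:
            P = np.atleast_2d(np.asarray(self.joint_positions, dtype=float))
            if P.shape != (n, K):
                raise ValueError("joint_positions shape mismatch")
            object.__setattr__(self, "joint_positions", P)

    @property
    def n(self) -> int:
        return self.joint_velocities.shape[0]

    @property
    def m(self) -> int:
        return self.endeffector_velocities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.joint_velocities.shape[1]

    def sample(self, k: int) -> KinematicSample:
        return KinematicSample(
            joint_velocity=self.joint_velocities[:, k],
            endeffector_velocity=self.endeffector_velocities[:, k],
            jacobian=self.jacobians[k],
            joint_position=None if self.joint_positions is None else self.joint_positions[:, k],
        )

    def __len__(self) -> int:
        return self.n_samples

    def __iter__(self):
        return (self.sample(k) for k in range(self.n_samples))

    @classmethod
    def from_samples(cls, samples: Sequence[KinematicSample], **kwargs) -> "KinematicDataset":
        if len(samples) == 0:
            raise ValueError("need at least one sample")
        n, m = samples[0].n, samples[0].m
        if any(s.n != n or s.m != m for s in samples):
            raise ValueError("all samples must share joint and task dimensions")
        pos = None
        if all(s.joint_position is not None for s in samples):
            pos = np.column_stack([s.joint_position for s in samples])
        return cls(
            joint_velocities=np.column_stack([s.joint_velocity for s in samples]),
            endeffector_velocities=np.column_stack([s.endeffector_velocity for s in samples]),
            jacobians=np.stack([s.jacobian for s in samples]),
            joint_positions=pos,
            **kwargs,
        )

    @classmethod
    def concatenate(cls, datasets: Sequence["KinematicDataset"], **kwargs) -> "KinematicDataset":
        """Column-wise concatenation of trials into one estimation dataset."""
        if len(datasets) == 0:
            raise ValueError("need at least one dataset")
        n, m = datasets[0].n, datasets[0].m
        if any(d.n != n or d.m != m for d in datasets):
            raise ValueError("datasets must share joint and task dimensions")
        pos = None
        if all(d.joint_positions is not None for d in datasets):
            pos = np.hstack([d.joint_positions for d in datasets])
        return cls(
            joint_velocities=np.hstack([d.joint_velocities for d in datasets]),
            endeffector_velocities=np.hstack([d.endeffector_velocities for d in datasets]),
            jacobians=np.concatenate([d.jacobians for d in datasets]),
            joint_positions=pos,
            dt=kwargs.pop("dt", datasets[0].dt),
            **kwargs,
        )


@dataclass(frozen=True)
class GammaSchedule:
    """Geometric ramp ``gamma_{t+1} = gamma_t + rate * (1 - gamma_t)``.

    Starts fast (small gamma updates weights aggressively) and approaches
    ``gamma = 1`` (no modeling error, no further update pressure).
    """

    initial: float = 0.6
    rate: float = 0.6

    def __post_init__(self):
        if not 0.0 <= self.initial <= 1.0:
            raise ValueError("initial gamma must lie in [0, 1]")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must lie in [0, 1]")

    def value(self, iteration: int) -> float:
        return 1.0 - (1.0 - self.initial) * (1.0 - self.rate) ** iteration


@dataclass(frozen=True)
class EstimationConfig:
    """Parameters of the weight-identification loop.

    gamma : float or GammaSchedule
        Null-space projection ratio in [0, 1].  Default 0.9: a conservative
        fixed choice sacrificing convergence speed for optimality.
    error_threshold : float
        Stop when the mean per-sample residual norm falls below this.
    max_iterations : int
        Update budget; exhausting it flags the result as non-converged.
    qp_tolerances : dict
        ``{"optimality", "constraint", "step"}`` forwarded to the QP solver.
    weight_lower_bound : float
        Strictly positive lower box bound (W must stay invertible).
    overspecified_joints : tuple of int
        Joints whose Jacobian column is outside the span of the others; their
        weight is unidentifiable, pinned back to 1 after each QP solve and
        excluded from max-normalization.
    min_task_speed : float
        Samples with ``||x_dot||`` below this floor are dropped from the
        linear-system assembly (rest periods carry no task information and
        destabilize the auxiliary variable).
    """

    gamma: Union[float, GammaSchedule] = 0.9
    error_threshold: float = 1e-3
    max_iterations: int = 100
    qp_tolerances: dict = field(
        default_factory=lambda: {"optimality": 1e-9, "constraint": 1e-9, "step": 1e-12}
    )
    weight_lower_bound: float = WEIGHT_FLOOR
    overspecified_joints: tuple = ()
    min_task_speed: float = 1e-8
    seed: Optional[int] = None

    def __post_init__(self):
        if isinstance(self.gamma, (int, float)):
            if not 0.0 <= float(self.gamma) <= 1.0:
                raise ValueError("gamma must lie in [0, 1]")
            object.__setattr__(self, "gamma", float(self.gamma))
        if self.error_threshold <= 0:
            raise ValueError("error_threshold must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")
        if not 0.0 < self.weight_lower_bound <= 1.0:
            raise ValueError("weight_lower_bound must lie in (0, 1]")
        object.__setattr__(self, "overspecified_joints", tuple(self.overspecified_joints))

    def gamma_at(self, iteration: int) -> float:
        if isinstance(self.gamma, GammaSchedule):
            return self.gamma.value(iteration)
        return float(self.gamma)

    @classmethod
    def from_file(cls, path) -> "EstimationConfig":
        """Load a config from a YAML or JSON file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yml", ".yaml"}:
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "EstimationConfig":
        raw = dict(raw or {})
        gamma = raw.get("gamma", 0.9)
        if isinstance(gamma, dict):
            gamma = GammaSchedule(
                initial=float(gamma.get("initial", 0.6)),
                rate=float(gamma.get("rate", 0.6)),
            )
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known and k != "gamma"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "overspecified_joints" in kwargs:
            kwargs["overspecified_joints"] = tuple(kwargs["overspecified_joints"])
        return cls(gamma=gamma, **kwargs)


@dataclass(frozen=True)
class QPProblem:
    """Box-constrained QP ``min 1/2 w^T H w + F^T w, lb <= w_i <= ub``.

    ``H = Psi_tilde^T Psi_tilde`` is PSD by construction.
    """

    hessian: np.ndarray
    linear_term: np.ndarray
    lower_bound: float = WEIGHT_FLOOR
    upper_bound: float = 1.0

    def __post_init__(self):
        H = np.asarray(self.hessian, dtype=float)
        F = np.asarray(self.linear_term, dtype=float).reshape(-1)
        if H.shape != (F.size, F.size):
            raise ValueError("hessian/linear-term dimension mismatch")
        if not np.allclose(H, H.T, atol=1e-8 * (1 + np.abs(H).max())):
            raise ValueError("hessian must be symmetric")
        object.__setattr__(self, "hessian", H)
        object.__setattr__(self, "linear_term", F)
        if not 0 < self.lower_bound <= self.upper_bound:
            raise ValueError("bounds must satisfy 0 < lower <= upper")

    @property
    def n(self) -> int:
        return self.linear_term.size


@dataclass(frozen=True)
class EstimationResult:
    """Outcome of the identification loop.

    ``error_trace[0]`` is the residual of the initial guess ``W = I`` —
    evaluation precedes update, so the identity-weight fit used throughout
    the literature is always reported for comparison.  ``null_velocities``
    holds ``V_bar`` (n x K) from the final evaluation.
    """

    weights: WeightVector
    error_trace: np.ndarray
    iterations_used: int
    null_velocities: np.ndarray
    converged: bool
    gamma_trace: np.ndarray = field(default=None, compare=False)
    weight_trace: np.ndarray = field(default=None, compare=False)

    def to_dict(self) -> dict:
        return {
            "weights": np.asarray(self.weights).tolist(),
            "contribution_coefficients": contribution_coefficients(self.weights).tolist(),
            "error_trace": np.asarray(self.error_trace).tolist(),
            "iterations_used": int(self.iterations_used),
            "converged": bool(self.converged),
        }


def _batched_core(jacobians: np.ndarray, w: np.ndarray):
    """Per-sample ``W^{-1} J^T`` and ``J W^{-1} J^T`` with conditioning check."""
    WJt = jacobians.transpose(0, 2, 1) / w[None, :, None]  # (K, n, m)
    core = jacobians @ WJt  # (K, m, m) symmetric
    eigs = np.linalg.eigvalsh(core)
    ratio = eigs[:, 0] / np.maximum(eigs[:, -1], np.finfo(float).tiny)
    bad = np.where((eigs[:, -1] <= 0) | (ratio < RCOND_THRESHOLD))[0]
    if bad.size:
        raise SingularJacobianError(
            "J W^-1 J^T is singular or near-singular", sample_index=int(bad[0])
        )
    return WJt, core


def assemble_linear_system(
    dataset: KinematicDataset,
    current_weights,
    null_velocities: np.ndarray,
    lower_bound: float = WEIGHT_FLOOR,
    min_task_speed: float = 1e-8,
) -> QPProblem:
    """Build the QP whose solution updates the weight estimate.

    With ``u_bar_k = J_k^T (J_k W_bar^{-1} J_k^T)^{-1} x_dot_k`` the model
    reads ``W_bar (Q_dot - V_bar) = U_bar``; multiplying by ``Q_dot^T``
    gives ``W_bar Psi_bar = Omega_bar`` with ``Psi_bar = (Q_dot - V_bar)
    Q_dot^T`` and ``Omega_bar = U_bar Q_dot^T``.  Because ``W`` is diagonal
    the matrix equation is rearranged columnwise into ``Psi_tilde w =
    Omega_tilde`` (``Psi_tilde`` of shape n^2 x n stacking ``diag`` of each
    column of ``Psi_bar``), yielding ``H = Psi_tilde^T Psi_tilde`` and
    ``F = -Psi_tilde^T Omega_tilde``.
    """
    w = np.asarray(WeightVector.from_values(np.asarray(current_weights, dtype=float)))
    n, K = dataset.n, dataset.n_samples
    V = np.asarray(null_velocities, dtype=float)
    if V.shape != (n, K):
        raise ValueError(f"null_velocities shape {V.shape} != {(n, K)}")

    keep = np.linalg.norm(dataset.endeffector_velocities, axis=0) >= min_task_speed
    dropped = int(np.sum(~keep))
    if dropped:
        logger.info("dropped %d near-rest samples (||x_dot|| below floor) from assembly", dropped)
    if not np.any(keep):
        raise ValueError("no samples with non-negligible end-effector velocity")

    Jk = dataset.jacobians[keep]
    Xk = dataset.endeffector_velocities[:, keep]
    Qk = dataset.joint_velocities[:, keep]
    Vk = V[:, keep]

    _, core = _batched_core(Jk, w)
    Z = np.linalg.solve(core, Xk.T[:, :, None])  # (K', m, 1)
    U = (Jk.transpose(0, 2, 1) @ Z)[:, :, 0].T  # (n, K'), u_k = J^T core^-1 x

    Psi = (Qk - Vk) @ Qk.T  # (n, n)
    Omega = U @ Qk.T  # (n, n)

    Psi_tilde = np.zeros((n * n, n))
    for j in range(n):
        Psi_tilde[j * n : (j + 1) * n, :] = np.diag(Psi[:, j])
    Omega_tilde = Omega.flatten(order="F")

    H = Psi_tilde.T @ Psi_tilde
    F = -(Psi_tilde.T @ Omega_tilde)
    return QPProblem(hessian=H, linear_term=F, lower_bound=lower_bound, upper_bound=1.0)


def solve_weight_qp(problem: QPProblem, config: Optional[EstimationConfig] = None) -> np.ndarray:
    """Minimize the box-constrained quadratic cost; returns un-normalized weights.

    Uses projected quasi-Newton iterations (L-BFGS-B) with the analytic
    gradient ``H w + F``; the problem is convex, so any local solution is
    global.  Tolerances map from ``config.qp_tolerances`` (``optimality`` to
    the projected-gradient tolerance, ``step`` to the relative cost
    decrease).
    """
    config = config or EstimationConfig()
    H, F = problem.hessian, problem.linear_term
    n = problem.n
    lb, ub = problem.lower_bound, problem.upper_bound
    tols = {"optimality": 1e-9, "step": 1e-12}
    tols.update({k: v for k, v in (config.qp_tolerances or {}).items() if k in tols})

    # Warm start from the clipped unconstrained minimizer.
    x0 = np.clip(np.linalg.lstsq(H, -F, rcond=None)[0], lb, ub)

    res = minimize(
        lambda x: 0.5 * x @ H @ x + F @ x,
        x0,
        jac=lambda x: H @ x + F,
        method="L-BFGS-B",
        bounds=[(lb, ub)] * n,
        options={
            "gtol": float(tols["optimality"]),
            "ftol": float(tols["step"]),
            "maxiter": 500,
        },
    )
    if not res.success and "ROUNDING" not in str(res.message).upper():
        raise QPSolverError(f"QP solver failed: {res.message}", status=res.status)
    return np.clip(res.x, lb, ub)


def estimate_weights(dataset: KinematicDataset, config: Optional[EstimationConfig] = None) -> EstimationResult:
    """Identify the IK weight vector of a dataset.

    Alternates evaluation and update until the mean residual drops below
    ``config.error_threshold`` or ``config.max_iterations`` updates have
    run.  Deterministic given its inputs.  Non-convergence is reported via
    ``EstimationResult.converged``, not an exception; singular samples
    raise :class:`~ikweights.kinematics.SingularJacobianError`.
    """
    config = config or EstimationConfig()
    n, m, K = dataset.n, dataset.m, dataset.n_samples
    if K < n * n:
        warnings.warn(
            f"only K={K} samples for n={n} joints (fewer than n^2={n * n}); "
            "the weight fit may be poorly posed",
            stacklevel=2,
        )
    bad_over = [j for j in config.overspecified_joints if not 0 <= j < n]
    if bad_over:
        raise ValueError(f"overspecified joint indices out of range: {bad_over}")
    free = np.ones(n, dtype=bool)
    free[list(config.overspecified_joints)] = False
    if not free.any():
        raise ValueError("cannot declare every joint over-specified")

    Q = dataset.joint_velocities  # (n, K)
    X = dataset.endeffector_velocities  # (m, K)
    Jarr = dataset.jacobians  # (K, m, n)

    w = np.ones(n)
    error_trace: list[float] = []
    gamma_trace: list[float] = []
    weight_trace: list[np.ndarray] = [w.copy()]
    V = np.zeros((n, K))
    converged = False
    updates = 0

    for it in range(config.max_iterations + 1):
        gamma = config.gamma_at(it)
        gamma_trace.append(gamma)

        # Evaluation: current null-space attribution and prediction residual.
        # v_bar = gamma (q_dot - J#_bar x_dot): the projected-velocity form
        # (I - J#_bar J) q_dot of the update rule, written through x_dot so
        # that gamma = 1 is a bit-exact fixed point even for measured
        # recordings whose forward consistency only holds approximately.
        WJt, core = _batched_core(Jarr, w)
        Z = np.linalg.solve(core, X.T[:, :, None])
        task = (WJt @ Z)[:, :, 0].T  # J#_bar x_dot
        V = gamma * (Q - task)  # v_bar per sample
        # residual q_dot - (task + v_bar), written in closed form
        e = float(np.mean(np.linalg.norm((1.0 - gamma) * (Q - task), axis=0)))
        error_trace.append(e)

        if e < config.error_threshold:
            converged = True
            break
        if it == config.max_iterations:
            break

        # Update: assemble the linearized system and solve the box QP.
        problem = assemble_linear_system(
            dataset, w, V,
            lower_bound=config.weight_lower_bound,
            min_task_speed=config.min_task_speed,
        )
        w_new = solve_weight_qp(problem, config)
        w_new[~free] = 1.0
        w_new[free] = np.clip(
            w_new[free] / w_new[free].max(), config.weight_lower_bound, 1.0
        )
        w = w_new
        weight_trace.append(w.copy())
        updates = it + 1

    return EstimationResult(
        weights=WeightVector(w),
        error_trace=np.asarray(error_trace),
        iterations_used=updates,
        null_velocities=V,
        converged=converged,
        gamma_trace=np.asarray(gamma_trace),
        weight_trace=np.asarray(weight_trace),
    )


def contribution_coefficients(weights) -> np.ndarray:
    """Reciprocal-normalized weights ``beta_i = w_i^{-1} / sum_k w_k^{-1}``.

    Weights quantify joint *cost*; these coefficients re-express them as each
    joint's share of the task contribution.  They sum to 1 and order
    opposite to the weights, which eases comparison across conditions where
    the max-normalization anchor differs.
    """
    w = np.asarray(weights, dtype=float).reshape(-1)
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("contribution coefficients require strictly positive weights")
    inv = 1.0 / w
    return inv / inv.sum()


def detect_overspecified_joints(dataset: KinematicDataset, tol: float = 1e-8) -> list[int]:
    """Opt-in detector: joints whose Jacobian column leaves the span of the others.

    Stacks each joint's Jacobian column across all samples and measures the
    least-squares residual of projecting it onto the stacked columns of the
    remaining joints.  A relative residual above ``tol`` means no linear
    combination of the other joints reproduces that joint's task effect
    anywhere in the dataset, leaving its weight unidentifiable.
    """
    n = dataset.n
    # (K*m, n): column j stacks joint j's Jacobian column over all samples.
    A = dataset.jacobians.reshape(-1, n)
    flagged = []
    for j in range(n):
        others = np.delete(A, j, axis=1)
        target = A[:, j]
        coef, *_ = np.linalg.lstsq(others, target, rcond=None)
        resid = np.linalg.norm(others @ coef - target)
        scale = max(np.linalg.norm(target), 1.0)
        if resid / scale > tol:
            flagged.append(j)
    return flagged


def save_result_json(result: EstimationResult, path) -> None:
    """Write weights, contribution coefficients and the trace as JSON."""
    Path(path).write_text(json.dumps(result.to_dict(), indent=2))


def save_trace_csv(result: EstimationResult, path) -> None:
    """Write the per-iteration residual trace as a two-column CSV."""
    import pandas as pd

    frame = {"iteration": np.arange(len(result.error_trace)), "mean_residual": result.error_trace}
    if result.gamma_trace is not None:
        frame["gamma"] = result.gamma_trace
    pd.DataFrame(frame).to_csv(path, index=False)
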