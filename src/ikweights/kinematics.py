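"""Weighted inverse-kinematics algebra for redundant chains.

A kinematic chain with ``n`` joints and an ``m``-dimensional task
(``n >= m``) maps joint velocities to end-effector velocities through the
Jacobian, ``x_dot = J(q) q_dot``.  When the chain is redundant the inverse
map is under-determined; the weighted pseudo-inverse

    J# = W^{-1} J^T (J W^{-1} J^T)^{-1}

selects, among all joint velocities reproducing ``x_dot``, the one
minimizing the quadratic cost ``q_dot^T W q_dot``.  The diagonal of ``W``
assigns a relative cost to each joint: a heavily weighted joint
contributes less to the task.  Every choice of ``W`` induces a unique
decomposition of an observed joint velocity into a task-space part
``J# x_dot`` and a null-space part ``N q_dot`` with ``N = I - J# J``.

This module provides that algebra; the weights themselves are estimated
from data by :mod:`ikweights.estimation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SingularJacobianError",
    "WeightVector",
    "KinematicSample",
    "VelocityDecomposition",
    "weighted_pseudo_inverse",
    "null_space_projector",
    "decompose_velocity",
    "modeling_error",
]

#: Smallest admissible IK weight.  The paper-level convention allows weights
#: in [0, 1], but W must remain invertible; values at this floor are
#: indistinguishable from zero at reporting precision.
WEIGHT_FLOOR = 1e-6

#: Reciprocal-condition-number threshold below which J W^{-1} J^T is treated
#: as singular.  We raise instead of damping: a damped inverse would silently
#: bias downstream weight estimates.
RCOND_THRESHOLD = 1e-10


class SingularJacobianError(np.linalg.LinAlgError):
    """Raised when J W^{-1} J^T is rank deficient or numerically singular.

    Carries the offending sample index when raised while sweeping a dataset.
    """

    def __init__(self, message: str, sample_index: Optional[int] = None):
        if sample_index is not None:
            message = f"{message} (sample index {sample_index})"
        super().__init__(message)
        self.sample_index = sample_index


@dataclass(frozen=True)
class WeightVector:
    """Diagonal IK weights ``w`` with every element in ``(0, 1]``.

    By convention the vector is max-normalized: dividing by the largest
    element leaves the induced pseudo-inverse unchanged (scaling ``W`` by a
    positive scalar cancels in ``J#``), so at least one weight equals 1.
    Construct via :meth:`from_values` to apply the normalization, or
    directly when the values already satisfy the convention.
    """

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float).reshape(-1)
        if w.size == 0:
            raise ValueError("weight vector must be non-empty")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
        if np.any(w > 1 + 1e-12):
            raise ValueError("weights must not exceed 1; use from_values() to normalize")
        object.__setattr__(self, "weights", w)

    @classmethod
    def from_values(cls, values, floor: float = WEIGHT_FLOOR) -> "WeightVector":
        """Build a max-normalized weight vector from arbitrary positive values."""
        w = np.asarray(values, dtype=float).reshape(-1)
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("weights must be finite and strictly positive")
        w = w / w.max()
        return cls(np.maximum(w, floor))

    @property
    def n(self) -> int:
        return self.weights.size

    def matrix(self) -> np.ndarray:
        """The diagonal weight matrix W."""
        return np.diag(self.weights)

    def __array__(self, dtype=None, copy=None):
        return np.array(self.weights, dtype=dtype)

    def __len__(self) -> int:
        return self.weights.size


def _as_weights(weights, n: int) -> np.ndarray:
    """Coerce a WeightVector or array-like into a validated n-vector."""
    if isinstance(weights, WeightVector):
        w = weights.weights
    else:
        w = np.asarray(weights, dtype=float).reshape(-1)
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("weights must be finite and strictly positive")
    if w.size != n:
        raise ValueError(f"expected {n} weights, got {w.size}")
    return w


@dataclass(frozen=True)
class KinematicSample:
    """One time-step of recorded motion: ``(q_dot, x_dot, J)`` and optionally ``q``.

    Parameters
    ----------
    joint_velocity : (n,) array
        Joint velocities (rad/s for revolute, m/s for prismatic joints).
    endeffector_velocity : (m,) array
        End-effector velocity (m/s).
    jacobian : (m, n) array
        Maps joint to end-effector velocities at the current posture.
    joint_position : (n,) array, optional
        Joint configuration (rad or m).
    strict : bool
        When True, reject samples whose forward-kinematics residual
        ``||x_dot - J q_dot||`` exceeds ``consistency_tol`` (relative).
        Measured recordings carry differentiation noise, so the default is
        lenient.
    """

    joint_velocity: np.ndarray
    endeffector_velocity: np.ndarray
    jacobian: np.ndarray
    joint_position: Optional[np.ndarray] = None
    strict: bool = field(default=False, compare=False)
    consistency_tol: float = field(default=1e-6, compare=False)

    def __post_init__(self):
        qd = np.asarray(self.joint_velocity, dtype=float).reshape(-1)
        xd = np.asarray(self.endeffector_velocity, dtype=float).reshape(-1)
        J = np.atleast_2d(np.asarray(self.jacobian, dtype=float))
        if J.shape != (xd.size, qd.size):
            raise ValueError(
                f"jacobian shape {J.shape} inconsistent with "
                f"m={xd.size} task dims and n={qd.size} joints"
            )
        if not (np.all(np.isfinite(qd)) and np.all(np.isfinite(xd)) and np.all(np.isfinite(J))):
            raise ValueError("sample contains non-finite entries")
        object.__setattr__(self, "joint_velocity", qd)
        object.__setattr__(self, "endeffector_velocity", xd)
        object.__setattr__(self, "jacobian", J)
        if self.joint_position is not None:
            q = np.asarray(self.joint_position, dtype=float).reshape(-1)
            if q.size != qd.size:
                raise ValueError("joint_position length does not match joint_velocity")
            object.__setattr__(self, "joint_position", q)
        if self.strict:
            resid = self.consistency_residual()
            scale = max(np.linalg.norm(xd), 1.0)
            if resid > self.consistency_tol * scale:
                raise ValueError(
                    f"forward-kinematics residual {resid:.3e} exceeds strict tolerance"
                )

    @property
    def n(self) -> int:
        return self.joint_velocity.size

    @property
    def m(self) -> int:
        return self.endeffector_velocity.size

    def consistency_residual(self) -> float:
        """``||x_dot - J q_dot||`` — zero for exactly consistent samples."""
        return float(np.linalg.norm(self.endeffector_velocity - self.jacobian @ self.joint_velocity))


@dataclass(frozen=True)
class VelocityDecomposition:
    """Task/null split of a joint velocity under a given weight matrix.

    ``task_velocity + null_velocity`` reconstructs the observed joint
    velocity, and the null component produces no end-effector motion
    (``J @ null_velocity = 0``).
    """

    task_velocity: np.ndarray
    null_velocity: np.ndarray
    pseudo_inverse: np.ndarray
    projector: np.ndarray


def _check_conditioning(core: np.ndarray, sample_index: Optional[int] = None) -> None:
    # core = J W^{-1} J^T is symmetric PSD; its eigenvalue ratio is its rcond.
    eigs = np.linalg.eigvalsh(core)
    if eigs[-1] <= 0 or eigs[0] / eigs[-1] < RCOND_THRESHOLD:
        raise SingularJacobianError(
            "J W^-1 J^T is singular or near-singular "
            f"(rcond ~ {max(eigs[0], 0.0) / max(eigs[-1], np.finfo(float).tiny):.2e})",
            sample_index,
        )


def weighted_pseudo_inverse(jacobian, weights, sample_index: Optional[int] = None) -> np.ndarray:
    """Weighted pseudo-inverse ``J# = W^{-1} J^T (J W^{-1} J^T)^{-1}``.

    For full-row-rank ``J`` this is a right inverse (``J J# = I_m``) and
    ``J# x_dot`` is the joint velocity of minimum cost ``q_dot^T W q_dot``
    among all solutions of ``J q_dot = x_dot``.  Scaling the weights by a
    positive constant leaves the result unchanged.

    Raises
    ------
    SingularJacobianError
        If ``J W^{-1} J^T`` is (near-)singular.  No damping is applied.
    """
    J = np.atleast_2d(np.asarray(jacobian, dtype=float))
    m, n = J.shape
    w = _as_weights(weights, n)
    winv_jt = J.T / w[:, None]          # W^{-1} J^T, (n, m)
    core = J @ winv_jt                  # J W^{-1} J^T, (m, m), symmetric
    _check_conditioning(core, sample_index)
    # J# = (W^{-1} J^T) core^{-1}; solve on the symmetric core.
    return np.linalg.solve(core, winv_jt.T).T


def null_space_projector(jacobian, weights, sample_index: Optional[int] = None) -> np.ndarray:
    """Null-space projector ``N = I - J# J`` of the weighted pseudo-inverse.

    ``N`` is idempotent and satisfies ``J N = 0``; it is the zero matrix for
    a square full-rank Jacobian (no redundancy).
    """
    J = np.atleast_2d(np.asarray(jacobian, dtype=float))
    J_sharp = weighted_pseudo_inverse(J, weights, sample_index)
    return np.eye(J.shape[1]) - J_sharp @ J


def decompose_velocity(sample: KinematicSample, weights) -> VelocityDecomposition:
    """Split an observed joint velocity into task and null components.

    ``q_dot_task = J# x_dot`` and ``q_dot_null = q_dot - q_dot_task``, so the
    two parts always sum back to the observation.  For forward-consistent
    samples the null part equals ``N q_dot``.
    """
    J_sharp = weighted_pseudo_inverse(sample.jacobian, weights)
    task = J_sharp @ sample.endeffector_velocity
    null = sample.joint_velocity - task
    projector = np.eye(sample.n) - J_sharp @ sample.jacobian
    return VelocityDecomposition(
        task_velocity=task,
        null_velocity=null,
        pseudo_inverse=J_sharp,
        projector=projector,
    )


def modeling_error(sample: KinematicSample, weights, gamma: float) -> np.ndarray:
    """Residual of the IK model when a fraction ``gamma`` of the projected
    velocity is attributed to the null space.

    Returns ``(1 - gamma) * N q_dot``: for ``gamma = 1`` the model explains
    any observation perfectly (zero error regardless of the weights), while
    for ``gamma = 0`` the error is the full null-space velocity.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    N = null_space_projector(sample.jacobian, weights)
    return (1.0 - gamma) * (N @ sample.joint_velocity)
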