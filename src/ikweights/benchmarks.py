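"""Synthetic benchmarks with known ground-truth IK weights.

Three generators produce :class:`~ikweights.estimation.KinematicDataset`
objects whose joint velocities follow the weighted-IK model
``q_dot = J#(w*) x_dot + v`` for a *known* nominal weight vector ``w*``,
so estimator accuracy can be measured exactly:

* :func:`generate_random_benchmark` — fully random chains: each sample has
  an iid standard-normal Jacobian and task velocity, with null-space noise
  of scale ``sigma`` projected through the nominal projector.  Task and
  null velocities are uncorrelated by construction.
* :func:`simulate_two_joint_chain` — two serial prismatic joints tracking
  a switching 1-D goal, with a null-space policy driving the first joint
  toward zero.  Here null and task motion are correlated, which is what
  makes the null-space projection ratio ``gamma`` matter.
* :func:`simulate_assistive_elbow` — a 3-link planar chain (hip, shoulder,
  virtual prosthetic elbow) where the distal joint is driven by an
  assistive controller amplifying the user's end-point velocity while
  discouraging proximal compensation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .estimation import EstimationConfig, KinematicDataset, estimate_weights
from .kinematics import (
    WeightVector,
    null_space_projector,
    weighted_pseudo_inverse,
)

__all__ = [
    "RandomBenchmarkSpec",
    "TwoJointSimSpec",
    "AssistiveElbowSpec",
    "generate_random_benchmark",
    "simulate_two_joint_chain",
    "simulate_assistive_elbow",
    "random_benchmark_recovery_errors",
    "planar_jacobian",
    "planar_forward_kinematics",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RandomBenchmarkSpec:
    """Fully random redundant-chain benchmark.

    Defaults match the reference study conditions: n = 5 joints, m = 3 task
    dimensions, K = 500 samples, nominal weights [1, 0.8, 0.6, 0.4, 0.2]
    and null-space noise sigma = 0.2.
    """

    joint_count: int = 5
    task_dim: int = 3
    sample_count: int = 500
    nominal_weights: Tuple[float, ...] = (1.0, 0.8, 0.6, 0.4, 0.2)
    null_noise_sigma: float = 0.2
    seed: int = 0
    repetitions: int = 1

    def __post_init__(self):
        if not self.joint_count > self.task_dim >= 1:
            raise ValueError("need joint_count > task_dim >= 1")
        if self.sample_count < 1:
            raise ValueError("sample_count must be >= 1")
        if self.null_noise_sigma < 0:
            raise ValueError("null_noise_sigma must be non-negative")
        if len(self.nominal_weights) != self.joint_count:
            raise ValueError("nominal_weights length must equal joint_count")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


def generate_random_benchmark(spec: RandomBenchmarkSpec) -> KinematicDataset:
    """Draw one dataset from the random-chain generative model.

    Per sample: Jacobian entries iid N(0, 1) (resampled in the
    measure-zero event of near rank deficiency); a latent task velocity iid
    N(0, 1); raw noise iid N(0, sigma) projected onto the sample's null
    space through the nominal projector; the emitted joint velocity is
    ``J#(w*) x_dot + v`` and the end-effector velocity is ``J q_dot``
    (exactly consistent, since ``J v = 0``).
    """
    n, m, K = spec.joint_count, spec.task_dim, spec.sample_count
    w_star = WeightVector.from_values(spec.nominal_weights)
    rng = np.random.default_rng(spec.seed)

    Q = np.empty((n, K))
    X = np.empty((m, K))
    Jarr = np.empty((K, m, n))
    resampled = 0
    for k in range(K):
        while True:
            J = rng.standard_normal((m, n))
            try:
                J_sharp = weighted_pseudo_inverse(J, w_star)
            except np.linalg.LinAlgError:
                resampled += 1
                continue
            break
        x_lat = rng.standard_normal(m)
        z = rng.normal(0.0, spec.null_noise_sigma, n) if spec.null_noise_sigma > 0 else np.zeros(n)
        N = np.eye(n) - J_sharp @ J
        v = N @ z
        qd = J_sharp @ x_lat + v
        Jarr[k] = J
        Q[:, k] = qd
        X[:, k] = J @ qd
    if resampled:
        logger.info("resampled %d rank-deficient random Jacobians", resampled)
    return KinematicDataset(
        joint_velocities=Q,
        endeffector_velocities=X,
        jacobians=Jarr,
        labels={"generator": "random_benchmark", "seed": spec.seed},
    )


def random_benchmark_recovery_errors(
    spec: RandomBenchmarkSpec,
    config: Optional[EstimationConfig] = None,
) -> np.ndarray:
    """Weight-recovery error over ``spec.repetitions`` independent datasets.

    Returns the Euclidean norm of (estimated - nominal) weights per
    repetition; repetition ``r`` uses seed ``spec.seed + r``.
    """
    config = config or EstimationConfig(gamma=0.6)
    w_star = np.asarray(WeightVector.from_values(spec.nominal_weights))
    errors = np.empty(spec.repetitions)
    for r in range(spec.repetitions):
        rep_spec = RandomBenchmarkSpec(
            joint_count=spec.joint_count,
            task_dim=spec.task_dim,
            sample_count=spec.sample_count,
            nominal_weights=spec.nominal_weights,
            null_noise_sigma=spec.null_noise_sigma,
            seed=spec.seed + r,
            repetitions=1,
        )
        dataset = generate_random_benchmark(rep_spec)
        result = estimate_weights(dataset, config)
        errors[r] = np.linalg.norm(np.asarray(result.weights) - w_star)
    return errors


@dataclass(frozen=True)
class TwoJointSimSpec:
    """Two serial prismatic joints, 1-D task (J = [1, 1] everywhere).

    The nominal strategy ``w* = [1, 0.01]`` makes the second joint do
    almost all task work, while the null-space policy ``[-null_gain * q1, 0]``
    (projected through the nominal projector) drives the first joint to
    zero over the run.  A proportional controller tracks a goal position
    that switches twice.  The defaults make the null motion of joint 1
    comparable to its (tiny) task motion — the regime in which ignoring
    null-space velocities (``gamma = 0``) misattributes the task to the
    first joint, while ``gamma >= 0.6`` recovers the nominal ordering.
    """

    nominal_weights: Tuple[float, float] = (1.0, 0.01)
    dt: float = 0.1
    duration: float = 6.0
    initial_position: Tuple[float, float] = (0.5, 0.5)
    goal_schedule: Tuple[Tuple[float, float], ...] = ((0.0, 1.0), (2.0, 1.5), (3.0, 0.5))
    tracking_gain: float = 1.5
    null_gain: float = 1.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        steps = self.duration / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("duration must be an integer multiple of dt")
        if self.tracking_gain <= 0:
            raise ValueError("tracking_gain must be positive")
        if len(self.goal_schedule) < 1 or self.goal_schedule[0][0] > 0:
            raise ValueError("goal_schedule must start at time 0")

    @property
    def n_steps(self) -> int:
        return round(self.duration / self.dt)


def simulate_two_joint_chain(spec: TwoJointSimSpec) -> KinematicDataset:
    """Euler-integrate the two-joint chain and emit its K = duration/dt samples."""
    J = np.array([[1.0, 1.0]])
    w_star = WeightVector.from_values(spec.nominal_weights)
    J_sharp = weighted_pseudo_inverse(J, w_star)  # (2, 1)
    N = null_space_projector(J, w_star)

    q = np.array(spec.initial_position, dtype=float)
    K = spec.n_steps
    Q = np.empty((2, K))
    X = np.empty((1, K))
    P = np.empty((2, K))
    Jarr = np.broadcast_to(J, (K, 1, 2)).copy()
    schedule = sorted(spec.goal_schedule)

    for k in range(K):
        t = k * spec.dt
        goal = [g for ts, g in schedule if ts <= t + 1e-12][-1]
        x = float(q[0] + q[1])
        xd_des = spec.tracking_gain * (goal - x)
        null_drive = np.array([-spec.null_gain * q[0], 0.0])
        qd = J_sharp[:, 0] * xd_des + N @ null_drive
        P[:, k] = q
        Q[:, k] = qd
        X[:, k] = J @ qd
        q = q + spec.dt * qd

    return KinematicDataset(
        joint_velocities=Q,
        endeffector_velocities=X,
        jacobians=Jarr,
        joint_positions=P,
        dt=spec.dt,
        labels={"generator": "two_joint_chain"},
    )


def planar_forward_kinematics(q: np.ndarray, link_lengths: Sequence[float]) -> np.ndarray:
    """End-point position of a planar revolute chain with cumulative angles."""
    c = np.cumsum(np.asarray(q, dtype=float))
    l = np.asarray(link_lengths, dtype=float)
    return np.array([np.sum(l * np.cos(c)), np.sum(l * np.sin(c))])


def planar_jacobian(q: np.ndarray, link_lengths: Sequence[float]) -> np.ndarray:
    """Standard 2 x n Jacobian of the planar revolute chain."""
    c = np.cumsum(np.asarray(q, dtype=float))
    l = np.asarray(link_lengths, dtype=float)
    n = len(l)
    J = np.empty((2, n))
    for j in range(n):
        J[0, j] = -np.sum(l[j:] * np.sin(c[j:]))
        J[1, j] = np.sum(l[j:] * np.cos(c[j:]))
    return J


@dataclass(frozen=True)
class AssistiveElbowSpec:
    """Assistive virtual-elbow scenario on a 3-link planar chain.

    The user directly drives the two proximal joints (hip ``q1``, shoulder
    ``q2``) to move the chain's end point along scripted reaching segments;
    the distal prosthetic elbow ``q3`` runs the assistive controller

        ``q3_dot = J3# v - N3 K (q - q_hat)``,  ``v_dot = -alpha (v - x_dot)``

    where ``J3#`` and ``N3`` are the elbow rows of the weighted
    pseudo-inverse and projector under ``W = diag(ik_weights)``, ``v`` is a
    first-order low-pass of the measured end-point velocity and the posture
    term cancels proximal compensation (gains ``K``, rest posture
    ``q_hat``).  The elbow angle is clamped to ``elbow_limits``.

    The human driver is scripted: minimum-jerk end-point segments between
    targets drawn inside the reachable workspace, realized on the two
    proximal joints through the square sub-Jacobian with proportional
    end-point correction.
    """

    ik_weights: Tuple[float, float, float] = (1.0, 1.0, 0.15)
    posture_gains: Tuple[float, float, float] = (2.0, 0.2, 0.0)
    rest_posture: Tuple[float, float, float] = (0.0, -2.7, 0.0)
    filter_rate: float = 40.0
    elbow_limits: Tuple[float, float] = (0.0, math.pi)
    link_lengths: Tuple[float, float, float] = (0.5, 0.3, 0.35)
    initial_posture: Tuple[float, float, float] = (0.1, -1.2, 1.2)
    n_targets: int = 8
    segment_duration: float = 3.0
    dt: float = 0.01
    tracking_gain: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.filter_rate <= 0:
            raise ValueError("filter_rate must be positive")
        if self.elbow_limits[0] >= self.elbow_limits[1]:
            raise ValueError("elbow_limits must be ordered")
        if self.dt <= 0 or self.filter_rate * self.dt >= 2.0:
            raise ValueError("dt too large for stable integration of the velocity filter")
        if self.n_targets < 1 or self.segment_duration <= 0:
            raise ValueError("need at least one target with positive duration")

    @property
    def duration(self) -> float:
        return self.n_targets * self.segment_duration

    @property
    def n_steps(self) -> int:
        return round(self.duration / self.dt)


def _min_jerk(s: float) -> Tuple[float, float]:
    """Normalized minimum-jerk position and velocity profiles on s in [0, 1]."""
    pos = 10 * s**3 - 15 * s**4 + 6 * s**5
    vel = 30 * s**2 - 60 * s**3 + 30 * s**4
    return pos, vel


def simulate_assistive_elbow(spec: AssistiveElbowSpec) -> KinematicDataset:
    """Simulate the assistive condition and emit 3-joint planar samples."""
    rng = np.random.default_rng(spec.seed)
    l = np.asarray(spec.link_lengths)
    W = np.asarray(spec.ik_weights)
    Kg = np.asarray(spec.posture_gains)
    q_hat = np.asarray(spec.rest_posture)

    # Reachable targets: sample joint configurations, take their end points.
    targets = []
    for _ in range(spec.n_targets):
        qt = np.array(
            [
                rng.uniform(-0.3, 0.3),
                rng.uniform(-2.0, -0.5),
                rng.uniform(0.3, 2.6),
            ]
        )
        targets.append(planar_forward_kinematics(qt, l))

    q = np.array(spec.initial_posture, dtype=float)
    v = np.zeros(2)  # filtered end-point velocity
    x_dot_meas = np.zeros(2)
    K_steps = spec.n_steps
    steps_per_segment = round(spec.segment_duration / spec.dt)

    Q = np.empty((3, K_steps))
    X = np.empty((2, K_steps))
    P = np.empty((3, K_steps))
    Jarr = np.empty((K_steps, 2, 3))

    seg_start_x = planar_forward_kinematics(q, l)
    seg_idx = -1
    for k in range(K_steps):
        new_seg = k // steps_per_segment
        if new_seg != seg_idx:
            seg_idx = new_seg
            seg_start_x = planar_forward_kinematics(q, l)
            seg_target = targets[seg_idx]
            seg_t0 = k * spec.dt

        t_seg = (k * spec.dt - seg_t0) / spec.segment_duration
        pos_s, vel_s = _min_jerk(min(t_seg, 1.0))
        x_ref = seg_start_x + pos_s * (seg_target - seg_start_x)
        xd_ref = (vel_s / spec.segment_duration) * (seg_target - seg_start_x)

        J = planar_jacobian(q, l)
        x = planar_forward_kinematics(q, l)

        # Human leader: proximal joints realize the reference end-point motion.
        J12 = J[:, :2]
        xd_des = xd_ref + spec.tracking_gain * (x_ref - x)
        qd12 = np.linalg.solve(J12, xd_des)
        qd12 = np.clip(qd12, -4.0, 4.0)  # physiological rate limit

        # Assistive elbow controller.
        v = v + spec.dt * (-spec.filter_rate * (v - x_dot_meas))
        J_sharp = weighted_pseudo_inverse(J, WeightVector.from_values(W))
        N = np.eye(3) - J_sharp @ J
        qd3 = float(J_sharp[2] @ v - N[2] @ (Kg * (q - q_hat)))

        qd = np.array([qd12[0], qd12[1], qd3])
        q_next = q + spec.dt * qd
        if not spec.elbow_limits[0] <= q_next[2] <= spec.elbow_limits[1]:
            q_next[2] = np.clip(q_next[2], *spec.elbow_limits)
            qd[2] = (q_next[2] - q[2]) / spec.dt  # realized rate after clamping

        P[:, k] = q
        Q[:, k] = qd
        Jarr[k] = J
        X[:, k] = J @ qd
        x_dot_meas = J @ qd
        q = q_next

    return KinematicDataset(
        joint_velocities=Q,
        endeffector_velocities=X,
        jacobians=Jarr,
        joint_positions=P,
        dt=spec.dt,
        labels={"generator": "assistive_elbow", "seed": spec.seed},
    )
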