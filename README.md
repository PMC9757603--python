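# ikweights

Model-based quantification of inter-joint coordination in kinematically
redundant systems — for movement scientists, rehabilitation researchers and
assistive-robotics engineers who want to know *how much each joint
contributes to an end-effector task*, not merely how joints correlate.

## The idea

A chain with $n$ joints performing an $m$-dimensional task ($n > m$) obeys
$\dot{x} = J(q)\,\dot{q}$. The inverse map is under-determined; the weighted
pseudo-inverse

$$J^{\#} = W^{-1} J^{\top} (J W^{-1} J^{\top})^{-1}$$

picks the joint velocity minimizing $\dot{q}^{\top} W \dot{q}$ subject to
$J\dot{q} = \dot{x}$. The diagonal of $W$ prices each joint: a heavy weight
means a costly joint that contributes little to the task. Any choice of $W$
splits an observed velocity into a task part $J^{\#}\dot{x}$ and a
null-space part $N\dot{q}$, $N = I - J^{\#}J$ — so the weights *are* the
model of the coordination strategy, and `ikweights` estimates them from
recorded $(\dot{q}, \dot{x}, J)$ samples.

Estimation is iterative: a fraction $\gamma \in [0,1]$ (the null-space
projection ratio) of the currently unexplained velocity is attributed to
the null space, the model is linearized through the auxiliary variable
$\bar{u}_k = J_k^{\top}(J_k \bar{W}^{-1} J_k^{\top})^{-1}\dot{x}_k$, and
the weight diagonal is updated by a box-constrained QP
($w_i \in (0, 1]$), then max-normalized. At $\gamma = 1$ any $W$ fits
perfectly (no update ever happens); small $\gamma$ risks explaining genuine
null-space motion through the task model. Estimated weights are also
re-expressed as contribution coefficients
$\beta_i = w_i^{-1} / \sum_k w_k^{-1}$, each joint's share of the task.

## Worked example

Two serial prismatic joints, one-dimensional task, observed
$\dot{q} = [0, 1]^\top$ with $J = [1, 1]$:

```python
import numpy as np
from ikweights import (KinematicSample, WeightVector, decompose_velocity,
    TwoJointSimSpec, simulate_two_joint_chain, EstimationConfig,
    estimate_weights, contribution_coefficients)

sample = KinematicSample(joint_velocity=[0.0, 1.0],
                         endeffector_velocity=[1.0],
                         jacobian=[[1.0, 1.0]])
for w in ([1.0, 1.0], [1.0, 1.0/9.0]):
    d = decompose_velocity(sample, WeightVector.from_values(w))
    print(f"W = diag({w}): task = {d.task_velocity}, null = {d.null_velocity}")

dataset = simulate_two_joint_chain(TwoJointSimSpec())
result = estimate_weights(dataset, EstimationConfig(gamma=0.9))
w = np.asarray(result.weights)
print("estimated weights:", w.round(4))
print("contribution coefficients:", contribution_coefficients(w).round(4))
```

prints

```
W = diag([1.0, 1.0]): task = [0.5 0.5], null = [-0.5  0.5]
W = diag([1.0, 0.1111111111111111]): task = [0.1 0.9], null = [-0.1  0.1]
estimated weights: [1.     0.0903]
contribution coefficients: [0.0828 0.9172]
```

Under identity weights half the task is attributed to each joint and the
first joint's stillness is "explained" by null-space motion; under
$W = \mathrm{diag}([1, 1/9])$ the observation is almost pure task motion.
The estimator, run on a simulated run of that chain whose ground-truth
strategy is $w^* = [1, 0.01]$, recovers the ordering: joint 2 is cheap and
carries ~92% of the task contribution.

## Command line

```sh
ikweights benchmark random --seed 5 --out bench/        # synthetic dataset
ikweights estimate bench/ --gamma 0.6 --out result.json # weights + β + trace
ikweights contributions 1.0 0.5                         # cost -> share transform
ikweights reproduce fig1 --repetitions 100 --out fig1.json
ikweights contrast recordings.mat --experiment 1 --gamma 0.9 --out contrast.json
```

Datasets travel in a neutral interchange format (CSV triplet plus JSON
sidecar per trial); supplementary-style MAT-file cohorts are read directly.

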