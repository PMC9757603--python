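"""Cohort workflows: loaders, per-participant estimation, contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy.io import savemat

from ikweights import (
    CohortRecordings,
    DatasetLayoutError,
    EstimationConfig,
    KinematicDataset,
    RandomBenchmarkSpec,
    aggregate_null_profiles,
    contribution_coefficients,
    estimate_cohort_weights,
    generate_random_benchmark,
    group_contribution_coefficients,
    load_cohort,
    load_paper_dataset,
    nullspace_utilization,
    paired_hotelling_contrast,
    save_cohort,
    simulate_assistive_elbow,
    AssistiveElbowSpec,
)


def synthetic_trial(weights, seed, n=None, m=3, K=40, sigma=0.0):
    n = len(weights) if n is None else n
    spec = RandomBenchmarkSpec(
        joint_count=n, task_dim=m, sample_count=K, nominal_weights=tuple(weights),
        null_noise_sigma=sigma, seed=seed,
    )
    return generate_random_benchmark(spec)


def mat_trial_dict(ds):
    K, m, n = ds.n_samples, ds.m, ds.n
    return {
        "dq": ds.joint_velocities.T,
        "dx": ds.endeffector_velocities.T,
        "J": ds.jacobians.reshape(K, m * n),
        "dt": 0.009,
    }


#: estimator settings for noise-free recovery fixtures: low gamma converges
#: fast on decorrelated data, the tight threshold stops only near the optimum
RECOVERY_CONFIG = dict(gamma=0.3, error_threshold=1e-6, max_iterations=300)


@pytest.fixture
def synthetic_cohort():
    """Three 'participants' with per-participant nominal weights, two conditions."""
    nominal = {
        "P01": [1.0, 0.7, 0.4, 0.9, 0.6],
        "P02": [0.8, 1.0, 0.3, 0.6, 0.5],
        "P03": [1.0, 0.5, 0.9, 0.2, 0.7],
    }
    trials = {}
    for i, (pid, w) in enumerate(nominal.items()):
        trials[pid] = {
            "Natural": {"target1": [synthetic_trial(w, 10 * i), synthetic_trial(w, 10 * i + 1)]},
            "Viscous": {"target1": [synthetic_trial(np.roll(w, 1), 10 * i + 5)]},
        }
    return CohortRecordings(trials=trials), nominal


class TestMatLoader:
    def make_mat(self, tmp_path, n_participants=2):
        participants = np.empty(n_participants, dtype=object)
        for p in range(n_participants):
            participants[p] = {
                "Natural": {
                    "target1": np.array(
                        [mat_trial_dict(synthetic_trial([1, 0.7, 0.4, 0.9], 3 * p + t)) for t in range(2)],
                        dtype=object,
                    ),
                    "target2": np.array(
                        [mat_trial_dict(synthetic_trial([1, 0.7, 0.4, 0.9], 50 + p))], dtype=object
                    ),
                },
                "Viscous": {
                    "target1": np.array(
                        [mat_trial_dict(synthetic_trial([1, 0.9, 0.6, 0.8], 70 + p))], dtype=object
                    ),
                },
            }
        path = tmp_path / "exp1.mat"
        savemat(path, {"participants": participants})
        return path

    def test_experiment1_layout_loaded(self, tmp_path):
        rec = load_paper_dataset(self.make_mat(tmp_path), experiment=1)
        assert rec.participants == ["P01", "P02"]
        assert rec.conditions == ["Natural", "Viscous"]
        t = rec.trials["P01"]["Natural"]["target1"][0]
        assert (t.n, t.m, t.n_samples) == (4, 3, 40)
        assert t.dt == pytest.approx(0.009)
        # concatenation over targets and trials
        assert rec.condition_dataset("P01", "Natural").n_samples == 120

    def test_experiment2_single_trial_per_condition(self, tmp_path):
        participants = np.empty(2, dtype=object)
        for p in range(2):
            participants[p] = {
                cond: mat_trial_dict(synthetic_trial([1, 0.5, 0.2, 0.8], 5 * p + i))
                for i, cond in enumerate(["Natural", "Locked", "Coupled", "Assistive"])
            }
        path = tmp_path / "exp2.mat"
        savemat(path, {"participants": participants})
        rec = load_paper_dataset(path, experiment=2)
        assert rec.conditions == ["Natural", "Locked", "Coupled", "Assistive"]
        assert all(
            len(rec.trials[p][c]["all"]) == 1 for p in rec.participants for c in rec.conditions
        )

    def test_missing_condition_reported_by_name(self, tmp_path):
        participants = np.empty(1, dtype=object)
        participants[0] = {
            "Natural": {
                "target1": np.array(
                    [mat_trial_dict(synthetic_trial([1, 0.7, 0.4, 0.9], 0))], dtype=object
                )
            }
        }
        path = tmp_path / "bad.mat"
        savemat(path, {"participants": participants})
        with pytest.raises(DatasetLayoutError, match="Viscous"):
            load_paper_dataset(path, experiment=1)

    def test_dimension_mismatch_names_trial(self, tmp_path):
        bad = mat_trial_dict(synthetic_trial([1, 0.7, 0.4, 0.9], 0))
        bad["dx"] = bad["dx"][:10]
        participants = np.empty(1, dtype=object)
        participants[0] = {
            "Natural": {"target1": np.array([bad], dtype=object)},
            "Viscous": {"target1": np.array([mat_trial_dict(synthetic_trial([1, 0.7, 0.4, 0.9], 1))], dtype=object)},
        }
        path = tmp_path / "bad.mat"
        savemat(path, {"participants": participants})
        with pytest.raises(DatasetLayoutError, match="P01.*Natural.*target1.*trial 0"):
            load_paper_dataset(path, experiment=1)

    def test_roundtrip_through_interchange_tree(self, tmp_path, synthetic_cohort):
        rec, _ = synthetic_cohort
        out = save_cohort(rec, tmp_path / "tree")
        rec2 = load_cohort(out)
        a = rec.trials["P02"]["Natural"]["target1"][1]
        b = rec2.trials["P02"]["Natural"]["target1"][1]
        np.testing.assert_array_equal(a.joint_velocities, b.joint_velocities)
        np.testing.assert_array_equal(a.jacobians, b.jacobians)


class TestCohortEstimation:
    def test_per_participant_recovery_of_nominal_weights(self, synthetic_cohort):
        rec, nominal = synthetic_cohort
        table = estimate_cohort_weights(rec, EstimationConfig(**RECOVERY_CONFIG))
        for pid, w in nominal.items():
            est = table.loc[(pid, "Natural"), [f"w{j}" for j in range(1, 6)]].to_numpy(float)
            np.testing.assert_allclose(est, np.asarray(w) / max(w), atol=0.01)

    def test_grouping_invariance_on_noise_free_cohort(self, synthetic_cohort):
        rec, _ = synthetic_cohort
        cfg = EstimationConfig(**RECOVERY_CONFIG)
        concat = estimate_cohort_weights(rec, cfg, grouping="per-condition-concatenated")
        per_trial = estimate_cohort_weights(rec, cfg, grouping="per-trial")
        wcols = [f"w{j}" for j in range(1, 6)]
        a = concat.loc[("P01", "Natural"), wcols].to_numpy(float)
        b = per_trial.xs(("P01", "Natural"), level=["participant", "condition"])[wcols].to_numpy(float)
        np.testing.assert_allclose(b, np.tile(a, (b.shape[0], 1)), atol=0.02)

    def test_betas_accompany_weights(self, synthetic_cohort):
        rec, _ = synthetic_cohort
        table = estimate_cohort_weights(rec, EstimationConfig(gamma=0.3))
        betas = table[[f"beta{j}" for j in range(1, 6)]].to_numpy(float)
        np.testing.assert_allclose(betas.sum(axis=1), 1.0, atol=1e-9)

    def test_overspecified_joint_convention(self, rng):
        """With the distal joint outside the others' span, its weight is pinned to 1."""
        n, m, K = 4, 3, 60
        Jarr = np.empty((K, m, n))
        w_nom = np.array([1.0, 0.6, 0.3, 0.5])  # w4 unidentifiable
        Q = np.empty((n, K))
        X = np.empty((m, K))
        from ikweights import weighted_pseudo_inverse, WeightVector

        for k in range(K):
            a, b = rng.standard_normal((2, m))
            Jarr[k, :, 0] = a
            Jarr[k, :, 1] = b
            Jarr[k, :, 2] = a + 0.5 * b  # first three joints span only rank 2
            Jarr[k, :, 3] = rng.standard_normal(m)
            J_sharp = weighted_pseudo_inverse(Jarr[k], WeightVector(w_nom))
            x = rng.standard_normal(m)
            qd = J_sharp @ x
            Q[:, k] = qd
            X[:, k] = Jarr[k] @ qd
        ds = KinematicDataset(Q, X, Jarr)
        rec = CohortRecordings(trials={"P01": {"Natural": {"target1": [ds]}}})
        table = estimate_cohort_weights(
            rec, EstimationConfig(gamma=0.3, overspecified_joints=(3,))
        )
        row = table.loc[("P01", "Natural")]
        assert row["w4"] == 1.0
        assert max(row["w1"], row["w2"], row["w3"]) == 1.0


class TestNullspaceUtilization:
    def test_nominal_weights_explain_noise_free_motion(self, synthetic_cohort):
        rec, _ = synthetic_cohort
        table = estimate_cohort_weights(rec, EstimationConfig(**RECOVERY_CONFIG))
        profiles = nullspace_utilization(rec, table)
        rms_est = np.sqrt((profiles["null_estimated"] ** 2).mean())
        rms_eye = np.sqrt((profiles["null_identity"] ** 2).mean())
        assert rms_est < 0.1 * rms_eye  # estimated weights leave far less null motion
        agg = aggregate_null_profiles(profiles)
        assert {"condition", "time_index", "joint"} <= set(agg.columns.get_level_values(0))


class TestPairedHotelling:
    def test_matches_independent_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        A = rng.normal(0.6, 0.15, (17, 2))
        B = A + rng.normal(0.08, 0.05, (17, 2))
        mine = paired_hotelling_contrast(A, B)
        ref = pingouin.multivariate_ttest(A - B)
        assert mine.t_squared == pytest.approx(float(ref["T2"].iloc[0]), abs=1e-10)
        assert mine.f_statistic == pytest.approx(float(ref["F"].iloc[0]), abs=1e-10)
        assert mine.df == (int(ref["df1"].iloc[0]), int(ref["df2"].iloc[0]))
        assert mine.p_value == pytest.approx(float(ref["pval"].iloc[0]), abs=1e-12)

    def test_textbook_formula_agreement(self, rng):
        """T2 = N dbar' S^-1 dbar and its exact F transform, spelled out."""
        A = rng.normal(size=(17, 2))
        B = rng.normal(size=(17, 2))
        mine = paired_hotelling_contrast(A, B)
        D = A - B
        N, p = D.shape
        dbar = D.mean(0)
        S = np.cov(D.T, ddof=1)
        t2 = N * dbar @ np.linalg.inv(S) @ dbar
        assert mine.t_squared == pytest.approx(t2, abs=1e-10)
        assert mine.f_statistic == pytest.approx((N - p) / (p * (N - 1)) * t2, abs=1e-10)
        assert mine.df == (2, 15)

    def test_identical_conditions_give_null_result(self):
        A = np.random.default_rng(0).normal(size=(6, 2))
        res = paired_hotelling_contrast(A, A.copy())
        assert res.t_squared == 0.0
        assert res.p_value == 1.0

    def test_degenerate_constant_differences_raise(self):
        A = np.ones((4, 1))
        B = np.zeros((4, 1))
        with pytest.raises(np.linalg.LinAlgError, match="covariance"):
            paired_hotelling_contrast(A, B)

    def test_requires_more_participants_than_components(self):
        with pytest.raises(ValueError, match="participants"):
            paired_hotelling_contrast(np.ones((2, 3)), np.zeros((2, 3)))

    def test_p_value_floor_display(self, rng):
        A = rng.normal(0.0, 0.01, (17, 2))
        B = A + 5.0 + rng.normal(0.0, 0.01, (17, 2))
        res = paired_hotelling_contrast(A, B)
        assert res.formatted_p() == "< 0.001"


class TestGroupContributionCoefficients:
    def test_all_documented_aggregations_sum_to_one(self, synthetic_cohort):
        rec, _ = synthetic_cohort
        table = estimate_cohort_weights(rec, EstimationConfig(gamma=0.3))
        for method in ("median", "mean", "transform-then-aggregate"):
            beta = group_contribution_coefficients(table, "Natural", method=method)
            assert beta.sum() == pytest.approx(1.0)
            assert np.all(beta > 0)

    def test_median_aggregation_matches_hand_computation(self):
        idx = pd.MultiIndex.from_product(
            [["P01", "P02", "P03"], ["Natural"]], names=["participant", "condition"]
        )
        table = pd.DataFrame(
            {"w1": [1.0, 1.0, 1.0], "w2": [0.5, 0.25, 0.75]}, index=idx
        )
        beta = group_contribution_coefficients(table, "Natural", method="median")
        np.testing.assert_allclose(beta, contribution_coefficients([1.0, 0.5]))

    def test_assistive_synthetic_condition_favors_the_elbow(self):
        """On assistive-controller data the prosthetic elbow carries the largest
        contribution share, mirroring the proximal-to-distal assistance pattern."""
        trials = {
            f"P{p}": {"Assistive": {"all": [simulate_assistive_elbow(AssistiveElbowSpec(seed=p, n_targets=4))]}}
            for p in range(3)
        }
        rec = CohortRecordings(trials=trials)
        table = estimate_cohort_weights(rec, EstimationConfig(gamma=0.9))
        beta = group_contribution_coefficients(table, "Assistive", method="median")
        assert beta.argmax() == 2
        assert beta[2] > 0.5
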