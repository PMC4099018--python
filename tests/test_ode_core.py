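"""Simulation correctness, fit metrics, and identifiability arithmetic."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from grninfer import (
    FitMetrics,
    NetworkModel,
    compute_metrics,
    count_potential_interactions,
    min_samples_for_identification,
    per_gene_max_error,
    simulate_trajectories,
)

TIMES = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 12.0])


def random_stable_model(rng, n, m):
    """Random model with eigenvalues pushed into the left half-plane."""
    A = rng.normal(0.0, 0.5, (n, n))
    A -= (np.abs(A).sum(axis=1) + 0.5) * np.eye(n)  # diagonally dominant, stable
    B = rng.normal(0.0, 1.0, (n, m))
    return NetworkModel(A, B)


class TestSimulateTrajectories:
    def test_scalar_step_response_closed_form(self):
        """dx/dt = -x + u gives x(t) = 1 - exp(-t)."""
        model = NetworkModel([[-1.0]], [[1.0]])
        traj = simulate_trajectories(model, 0, np.array([0.0, 1.0, 2.0]))
        np.testing.assert_allclose(
            traj[0], [0.0, 1 - np.exp(-1), 1 - np.exp(-2)], atol=1e-12
        )
        assert traj[0, 1] == pytest.approx(0.63212, abs=1e-5)

    def test_zero_model_stays_at_zero(self):
        model = NetworkModel(np.zeros((3, 3)), np.zeros((3, 2)))
        traj = simulate_trajectories(model, 1, TIMES)
        assert np.all(traj == 0.0)

    def test_pure_integrator_is_linear_ramp(self):
        """With a = 0 and b = 2 the response is x(t) = 2t."""
        model = NetworkModel([[0.0]], [[2.0]])
        traj = simulate_trajectories(model, 0, TIMES)
        np.testing.assert_allclose(traj[0], 2.0 * TIMES, atol=1e-12)

    @pytest.mark.parametrize("n,m", [(1, 1), (2, 1), (3, 2), (5, 3)])
    def test_agrees_with_adaptive_integrator(self, rng, n, m):
        """Cross-check against an independent stiff-capable ODE solver."""
        model = random_stable_model(rng, n, m)
        traj = simulate_trajectories(model, 0, TIMES)

        def rhs(t, x):
            return model.A @ x + model.B[:, 0]

        ref = solve_ivp(
            rhs, (0.0, TIMES[-1]), np.zeros(n), t_eval=TIMES, method="Radau",
            rtol=1e-10, atol=1e-12,
        )
        np.testing.assert_allclose(traj, ref.y, atol=1e-6)

    @pytest.mark.parametrize("n", [1, 2, 4])
    def test_agrees_with_matrix_closed_form(self, rng, n):
        """For invertible A the step response is A^-1 (e^{At} - I) B."""
        model = random_stable_model(rng, n, 1)
        traj = simulate_trajectories(model, 0, TIMES)
        inv = np.linalg.inv(model.A)
        for ti, t in enumerate(TIMES):
            closed = inv @ (expm(model.A * t) - np.eye(n)) @ model.B[:, 0]
            np.testing.assert_allclose(traj[:, ti], closed, atol=1e-9)

    def test_trajectories_linear_in_input_weights(self, rng):
        """For fixed A the response is linear in B (superposition)."""
        model = random_stable_model(rng, 3, 2)
        base = simulate_trajectories(model, 0, TIMES)
        scaled = NetworkModel(model.A, 2.5 * model.B)
        np.testing.assert_allclose(
            simulate_trajectories(scaled, 0, TIMES), 2.5 * base, atol=1e-9
        )

    def test_rejects_bad_time_grid(self):
        model = NetworkModel([[-1.0]], [[1.0]])
        with pytest.raises(ValueError):
            simulate_trajectories(model, 0, np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            simulate_trajectories(model, 0, np.array([0.0, 2.0, 2.0]))


class TestMetrics:
    def test_exact_model_has_zero_error(self, cascade):
        truth, design, dataset = cascade
        # the standardized data are a rescaled version of the truth run;
        # rescale the model rows accordingly so it reproduces them exactly
        sim = {
            s: simulate_trajectories(truth.model, k, np.asarray(design.time_points))
            for k, s in enumerate(design.stimuli)
        }
        scales = np.array(
            [
                max(np.abs(sim[s][g]).max() for s in design.stimuli)
                for g in range(design.n_genes)
            ]
        )
        D = np.diag(1.0 / scales)
        rescaled = NetworkModel(
            D @ truth.model.A @ np.diag(scales),
            D @ truth.model.B,
            truth.model.gene_order,
            truth.model.stimulus_order,
        )
        metrics = compute_metrics(rescaled, dataset)
        assert metrics.max_abs_error < 1e-9
        assert metrics.avg_mse < 1e-18

    def test_zero_model_mse_is_mean_squared_data(self, cascade):
        _, design, dataset = cascade
        model = NetworkModel(
            np.zeros((3, 3)), np.zeros((3, 1)), dataset.gene_order, list(design.stimuli)
        )
        metrics = compute_metrics(model, dataset)
        expected = np.mean(
            [dataset.per_stimulus[s] ** 2 for s in design.stimuli]
        )
        assert metrics.avg_mse == pytest.approx(expected)
        assert metrics.max_abs_error == pytest.approx(
            max(np.abs(dataset.per_stimulus[s]).max() for s in design.stimuli)
        )

    def test_error_vanishes_continuously_with_perturbation(self, cascade):
        """Perturbing one weight by eps changes the error continuously."""
        truth, design, dataset = cascade
        errors = []
        for eps in (0.1, 0.01, 0.001):
            A = truth.model.A.copy()
            A[1, 0] += eps
            perturbed = NetworkModel(
                A, truth.model.B, truth.model.gene_order, truth.model.stimulus_order
            )
            res = compute_metrics(perturbed, dataset)
            base = compute_metrics(truth.model, dataset)
            errors.append(abs(res.max_abs_error - base.max_abs_error))
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 0.01

    def test_metrics_invariant_under_gene_permutation(self, bench10):
        truth, design, dataset = bench10
        model = truth.model
        perm = np.array([3, 1, 4, 0, 2, 9, 5, 7, 8, 6])
        permuted_model = NetworkModel(
            model.A[np.ix_(perm, perm)],
            model.B[perm],
            [model.gene_order[i] for i in perm],
            model.stimulus_order,
        )
        from grninfer import StandardizedDataset

        permuted_data = StandardizedDataset(
            {s: dataset.per_stimulus[s][perm] for s in design.stimuli},
            design,
            [dataset.gene_order[i] for i in perm],
        )
        m1 = compute_metrics(model, dataset)
        m2 = compute_metrics(permuted_model, permuted_data)
        assert m1.max_abs_error == pytest.approx(m2.max_abs_error)
        assert m1.avg_mse == pytest.approx(m2.avg_mse)
        np.testing.assert_allclose(
            np.sort(per_gene_max_error(model, dataset)),
            np.sort(per_gene_max_error(permuted_model, permuted_data)),
        )

    def test_fit_metrics_invariant(self):
        m = FitMetrics(max_abs_error=0.5, avg_mse=0.1)
        assert m.avg_mse <= m.max_abs_error**2


class TestIdentifiabilityArithmetic:
    @pytest.mark.parametrize(
        "n,m,expected", [(24, 4, 672), (1, 1, 2), (10, 2, 120), (0, 0, 0)]
    )
    def test_potential_interaction_count(self, n, m, expected):
        assert count_potential_interactions(n, m) == expected

    def test_minimum_sample_count(self):
        assert min_samples_for_identification(24, 4) == 28

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            count_potential_interactions(-1, 2)
        with pytest.raises(ValueError):
            min_samples_for_identification(2, -1)


class TestSerialization:
    def test_edge_table_round_trip(self, bench10, tmp_path):
        truth, _, _ = bench10
        path = tmp_path / "edges.tsv"
        truth.model.write_edge_table(path)
        import pandas as pd

        table = pd.read_csv(path, sep="\t")
        rebuilt = NetworkModel.from_edge_table(
            table, truth.model.gene_order, truth.model.stimulus_order
        )
        np.testing.assert_allclose(rebuilt.A, truth.model.A, rtol=1e-14)
        np.testing.assert_allclose(rebuilt.B, truth.model.B, rtol=1e-14)
        assert rebuilt.edge_set() == truth.model.edge_set()

    def test_matrix_csv_round_trip(self, bench10, tmp_path):
        truth, _, _ = bench10
        truth.model.write_matrices(tmp_path / "A.csv", tmp_path / "B.csv")
        rebuilt = NetworkModel.read_matrices(tmp_path / "A.csv", tmp_path / "B.csv")
        np.testing.assert_allclose(rebuilt.A, truth.model.A)
        np.testing.assert_allclose(rebuilt.B, truth.model.B)
        assert rebuilt.gene_order == truth.model.gene_order
        assert rebuilt.stimulus_order == truth.model.stimulus_order

    def test_rejects_non_finite_weights(self):
        with pytest.raises(ValueError):
            NetworkModel([[np.nan]], [[1.0]])
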