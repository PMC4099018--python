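"""Greedy sparse structure search, model selection, and the error budget."""

import itertools

import numpy as np
import pytest

from grninfer import (
    ExperimentDesign,
    GroundTruth,
    InferenceConfig,
    NetworkModel,
    PriorMatrix,
    dataset_to_frame,
    infer_gene_submodel,
    infer_network,
    per_gene_max_error,
    select_model,
    simulate_dataset,
    standardize_dataset,
    sweep_allowed_error,
)
from grninfer.benchmark import benchmark_config
from grninfer.inference import SweepRecord, _fit_structure, _Workspace

TIMES = (0.0, 1.0, 2.0, 4.0, 12.0)


def exhaustive_parent_set(dataset, gene, budget, max_size=2):
    """Independent oracle: smallest regulator subset meeting the error
    budget, ties broken by SSE; searched exhaustively."""
    ws = _Workspace(dataset)
    n_cand = ws.n_genes + ws.n_stimuli
    candidates = [c for c in range(n_cand) if c != gene]
    for size in range(max_size + 1):
        hits = []
        for sub in itertools.combinations(candidates, size):
            fit = _fit_structure(ws, gene, list(sub), refine=True)
            if fit.max_err <= budget:
                hits.append((fit.sse, sub))
        if hits:
            return set(min(hits)[1])
    return None


class TestGeneSubmodel:
    def test_flat_gene_returns_empty_row(self):
        design = ExperimentDesign(("u1",), TIMES, 1, 2)
        A = np.array([[-1.0, 0.0], [0.0, -0.5]])
        B = np.array([[1.0], [0.0]])  # gene 2 receives nothing
        truth = GroundTruth(NetworkModel(A, B, ["g1", "g2"], ["u1"]), 0.0, 0)
        sim = simulate_dataset(truth, design)
        ds = standardize_dataset(dataset_to_frame(sim), design, ["g1", "g2"])
        fit = infer_gene_submodel("g2", ds, None, benchmark_config())
        assert fit.selected == []
        assert np.all(fit.row_a == 0.0) and np.all(fit.row_b == 0.0)
        assert fit.converged

    def test_single_gene_recovers_stimulus_drive_within_5_percent(self):
        """One gene, one stimulus, a=-1, b=1: weights recovered to < 5 %."""
        design = ExperimentDesign(("u1",), TIMES, 1, 1)
        truth = GroundTruth(NetworkModel([[-1.0]], [[1.0]], ["g1"], ["u1"]), 0.0, 0)
        sim = simulate_dataset(truth, design)
        ds = standardize_dataset(dataset_to_frame(sim), design, ["g1"])
        fit = infer_gene_submodel("g1", ds, None, benchmark_config())
        assert fit.selected == [1]  # the stimulus
        assert fit.row_a[0] == pytest.approx(-1.0, rel=0.05)
        assert fit.row_b[0] == pytest.approx(1.0, rel=0.05)

    def test_cascade_parent_sets_match_exhaustive_oracle(self, cascade):
        """Each cascade gene's regulators equal the true parents, which the
        exhaustive subset oracle independently confirms as the unique
        minimal structure within the budget."""
        truth, design, dataset = cascade
        config = benchmark_config()
        expected_parents = {0: {3}, 1: {0}, 2: {1}}  # candidate ids; 3 = u1
        for gi in range(3):
            oracle = exhaustive_parent_set(dataset, gi, config.allowed_error)
            assert oracle == expected_parents[gi]
            fit = infer_gene_submodel(gi, dataset, None, config)
            assert set(fit.selected) == oracle


class TestInferNetwork:
    def test_edge_count_bounded_by_truth(self, bench10):
        """Noise-free data, generous budget: no more edges than the truth
        has (plus nothing for decay, which is bookkept separately)."""
        truth, design, dataset = bench10
        result = infer_network(dataset, None, InferenceConfig(allowed_error=0.045))
        assert result.model.n_edges() <= truth.model.n_edges() + design.n_genes

    def test_huge_budget_gives_empty_network(self, bench10):
        _, _, dataset = bench10
        result = infer_network(dataset, None, InferenceConfig(allowed_error=1e6))
        assert result.model.n_edges() == 0
        assert np.all(result.model.A == 0.0)
        assert all(result.converged.values())

    def test_deterministic_given_inputs(self, bench10):
        _, _, dataset = bench10
        r1 = infer_network(dataset, None, benchmark_config())
        r2 = infer_network(dataset, None, benchmark_config())
        np.testing.assert_array_equal(r1.model.A, r2.model.A)
        np.testing.assert_array_equal(r1.model.B, r2.model.B)
        assert r1.converged == r2.converged

    def test_converged_genes_meet_error_budget(self, bench10):
        """The budget contract: every converged gene's coupled simulation
        stays within allowed_error at all stimuli and time points."""
        _, _, dataset = bench10
        config = benchmark_config()
        result = infer_network(dataset, None, config)
        errors = per_gene_max_error(result.model, dataset)
        budget = config.allowed_error * (1 + 1e-9) + 1e-12
        for gene, err in zip(result.model.gene_order, errors):
            if result.converged[gene]:
                assert err <= budget
        assert any(result.converged.values())

    def test_zero_prior_bonus_disables_prior(self, bench10):
        """Soft integration with weight 0 must leave the result untouched."""
        truth, _, dataset = bench10
        prior = PriorMatrix.all_na(truth.model.gene_order)
        prior.codes.iloc[:, :] = "1"  # maximally opinionated prior
        cfg = InferenceConfig(allowed_error=0.01, prior_bonus=0.0)
        with_prior = infer_network(dataset, prior, cfg)
        without = infer_network(dataset, None, cfg)
        np.testing.assert_array_equal(with_prior.model.A, without.model.A)
        np.testing.assert_array_equal(with_prior.model.B, without.model.B)

    def test_true_prior_does_not_reduce_true_edge_yield(self, bench10):
        """A prior encoding the true signed structure biases the search
        toward (at least as many) true edges."""
        truth, _, dataset = bench10
        genes = truth.model.gene_order
        prior = PriorMatrix.all_na(genes)
        for i, tgt in enumerate(genes):
            for j, src in enumerate(genes):
                if i != j and truth.model.A[i, j] != 0:
                    prior.codes.loc[tgt, src] = "10" if truth.model.A[i, j] > 0 else "-10"
        true_edges = truth.model.edge_set()
        base = infer_network(dataset, None, InferenceConfig(allowed_error=0.01))
        biased = infer_network(
            dataset, prior, InferenceConfig(allowed_error=0.01, prior_bonus=0.05)
        )
        base_hits = len(base.model.edge_set() & true_edges)
        biased_hits = len(biased.model.edge_set() & true_edges)
        assert biased_hits >= base_hits


class TestSweepAndSelect:
    def test_single_value_single_record(self, cascade):
        _, _, dataset = cascade
        records = sweep_allowed_error(dataset, None, [0.05])
        assert len(records) == 1
        assert records[0].allowed_error == 0.05

    def test_prior_edges_never_exceed_edges(self, cascade):
        truth, _, dataset = cascade
        prior = PriorMatrix.all_na(truth.model.gene_order)
        prior.codes.iloc[:, :] = "1"
        for rec in sweep_allowed_error(dataset, prior, [0.01, 0.1, 0.5]):
            assert rec.n_prior_edges <= rec.n_edges

    def test_looser_budget_gives_sparser_model_on_monotone_fixture(self, cascade):
        """The cascade admits strictly fewer edges at a loose budget."""
        _, _, dataset = cascade
        records = sweep_allowed_error(dataset, None, [0.01, 2.0])
        assert records[1].n_edges <= records[0].n_edges
        assert records[1].n_edges == 0  # the zero model already satisfies 2.0

    def test_empty_grid_rejected(self, cascade):
        _, _, dataset = cascade
        with pytest.raises(ValueError):
            sweep_allowed_error(dataset, None, [])

    @staticmethod
    def record(ae, mse, edges, prior_edges):
        return SweepRecord(
            allowed_error=ae, avg_mse=mse, n_edges=edges, n_prior_edges=prior_edges,
            result=None,
        )

    def test_single_record_selected(self):
        rec = self.record(0.1, 1.0, 5, 2)
        assert select_model([rec]) is rec

    def test_lower_mse_wins_between_otherwise_equal_records(self):
        good = self.record(0.1, 0.5, 5, 2)
        bad = self.record(0.2, 5.0, 5, 2)
        assert select_model([good, bad]) is good

    def test_prior_edge_tiebreak_then_sparsity_then_budget(self):
        """Within the MSE window the record with more prior-supported
        edges wins; remaining ties fall to fewer edges, then smaller
        allowed_error."""
        a = self.record(0.10, 1.00, 8, 3)
        b = self.record(0.20, 1.20, 9, 5)  # most prior edges, within window
        c = self.record(0.30, 1.10, 7, 5)  # same prior edges, fewer edges
        assert select_model([a, b, c]) is c
        d = self.record(0.05, 1.05, 7, 5)  # ties with c except smaller budget
        assert select_model([a, b, c, d]) is d
        assert select_model([a, self.record(0.2, 9.0, 5, 5)]) is a  # outside window

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            select_model([])


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"allowed_error": 0.0},
            {"allowed_error": -0.1},
            {"max_regulators": 0},
            {"min_improvement": -1e-3},
            {"candidate_rule": "random"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            InferenceConfig(**kwargs)
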