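"""Ground-truth recovery benchmarks on synthetic data.

These helpers wire the full pipeline — generate a sparse ground-truth
network, simulate its multi-stimuli step responses, standardize, infer,
and (optionally) run the noise-perturbation consensus — and score the
result against the generating structure.

Edge scoring uses unsigned identities (source, target, kind).  Self-loops
are excluded from precision/recall because the generator gives every gene
a self-decay term by construction, and edges whose source gene has a flat
trajectory under every stimulus (no direct or inherited excitation) are
excluded from both sides of the comparison: no method can recover an edge
that leaves no trace in the data.

The benchmark inference budget defaults to ``allowed_error = 0.01``: the
benchmark data are noise-free, so the budget reflects only the numerical
error of the decoupled fit, an order of magnitude below the noise-scale
default used on measured data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import InferenceConfig, infer_network
from .ode_core import NetworkModel
from .preprocess import standardize_dataset
from .stability import StabilityConfig, build_consensus, run_stability
from .synthetic import (
    ExperimentDesign,
    GroundTruth,
    dataset_to_frame,
    generate_random_network,
    simulate_dataset,
)

__all__ = [
    "benchmark_design",
    "benchmark_config",
    "make_benchmark_dataset",
    "flat_genes",
    "scoreable_truth_edges",
    "precision_recall",
    "recovery_benchmark",
    "consensus_benchmark",
]


def benchmark_config() -> InferenceConfig:
    """Inference configuration used for the noise-free benchmarks."""
    return InferenceConfig(allowed_error=0.01)


def benchmark_design(n_genes: int = 10, n_stimuli: int = 2) -> ExperimentDesign:
    """Reduced-scale benchmark design: same time grid, single replicate."""
    stimuli = tuple(f"u{k + 1}" for k in range(n_stimuli))
    return ExperimentDesign(stimuli, (0.0, 1.0, 2.0, 4.0, 12.0), 1, n_genes)


def make_benchmark_dataset(
    design: ExperimentDesign,
    seed: int,
    density: float = 0.15,
    noise_sd: float = 0.0,
):
    """Generate truth, simulate, and standardize one benchmark instance."""
    truth = generate_random_network(
        design, gene_edge_density=density, stim_edge_density=density, seed=seed
    )
    sim = simulate_dataset(truth, design, noise_sd=noise_sd)
    dataset = standardize_dataset(
        dataset_to_frame(sim), design, truth.model.gene_order
    )
    return truth, dataset


def flat_genes(dataset) -> set[str]:
    """Genes whose standardized trajectory is flat under every stimulus."""
    out = set()
    for gi, gene in enumerate(dataset.gene_order):
        peak = max(
            float(np.abs(dataset.per_stimulus[s][gi]).max())
            for s in dataset.design.stimuli
        )
        if peak < 1e-9:
            out.add(gene)
    return out


def scoreable_truth_edges(
    truth: GroundTruth, flat: set[str] | None = None
) -> set[tuple[str, str, str]]:
    """Truth edges that leave a signal in the data (active source, no self-loops)."""
    flat = set(truth.flat_genes) if flat is None else flat
    return {
        (src, tgt, kind)
        for (src, tgt, kind) in truth.model.edge_set(include_diagonal=False)
        if kind == "stimulus" or src not in flat
    }


def _scored_edges(
    model: NetworkModel, flat: set[str]
) -> set[tuple[str, str, str]]:
    return {
        (src, tgt, kind)
        for (src, tgt, kind) in model.edge_set(include_diagonal=False)
        if kind == "stimulus" or src not in flat
    }


def precision_recall(
    inferred: NetworkModel, truth: GroundTruth, flat: set[str] | None = None
) -> tuple[float, float, int]:
    """Unsigned edge precision and recall against the generating structure.

    An empty inferred edge set has precision 1.0 (no false positives).
    Returns (precision, recall, n_inferred_edges).
    """
    flat = set(truth.flat_genes) if flat is None else flat
    truth_edges = scoreable_truth_edges(truth, flat)
    found = _scored_edges(inferred, flat)
    tp = len(found & truth_edges)
    precision = tp / len(found) if found else 1.0
    recall = tp / len(truth_edges) if truth_edges else 1.0
    return precision, recall, len(found)


@dataclass
class RecoveryReport:
    """Pooled and per-seed structure-recovery scores."""

    precision: float  # pooled over seeds (micro-average)
    recall: float
    per_seed: list[tuple[float, float]]
    budget_violations: int  # converged genes exceeding the error budget
    n_converged_genes: int


def recovery_benchmark(
    n_seeds: int = 20,
    design: ExperimentDesign | None = None,
    density: float = 0.15,
    config: InferenceConfig | None = None,
    base_seed: int = 0,
) -> RecoveryReport:
    """Noise-free structure recovery over ``n_seeds`` random ground truths.

    Also audits the error-budget contract: every gene flagged converged
    must meet ``allowed_error`` in the coupled simulation of the assembled
    model.
    """
    design = design or benchmark_design()
    config = config or benchmark_config()
    tp = fp = fn = 0
    per_seed = []
    violations = 0
    n_converged = 0
    for s in range(n_seeds):
        truth, dataset = make_benchmark_dataset(design, seed=base_seed + s, density=density)
        result = infer_network(dataset, None, config)
        flat = flat_genes(dataset)
        p, r, _ = precision_recall(result.model, truth, flat)
        per_seed.append((p, r))
        truth_edges = scoreable_truth_edges(truth, flat)
        found = _scored_edges(result.model, flat)
        tp += len(found & truth_edges)
        fp += len(found - truth_edges)
        fn += len(truth_edges - found)
        budget = config.allowed_error * (1.0 + 1e-9) + 1e-12
        for gene, ok in result.converged.items():
            if ok:
                n_converged += 1
                if result.gene_max_errors[gene] > budget:
                    violations += 1
    return RecoveryReport(
        precision=tp / (tp + fp) if tp + fp else 1.0,
        recall=tp / (tp + fn) if tp + fn else 1.0,
        per_seed=per_seed,
        budget_violations=violations,
        n_converged_genes=n_converged,
    )


@dataclass
class ConsensusReport:
    """Per-seed comparison of single-run and consensus networks."""

    single_precision: list[float]
    consensus_precision: list[float]
    single_edges: list[int]
    consensus_edges: list[int]

    @property
    def frac_consensus_ge_single(self) -> float:
        wins = sum(
            c >= s for c, s in zip(self.consensus_precision, self.single_precision)
        )
        return wins / len(self.single_precision)

    @property
    def frac_consensus_not_larger(self) -> float:
        wins = sum(c <= s for c, s in zip(self.consensus_edges, self.single_edges))
        return wins / len(self.single_edges)


def consensus_benchmark(
    n_seeds: int = 20,
    n_runs: int = 50,
    noise_sd: float = 0.05,
    threshold: int | None = None,
    design: ExperimentDesign | None = None,
    density: float = 0.15,
    config: InferenceConfig | None = None,
    base_seed: int = 0,
) -> ConsensusReport:
    """Consensus-vs-single-run comparison on the standard synthetic fixture.

    The acceptance threshold defaults to just over half the runs, scaling
    the 51-of-100 rule to the chosen ``n_runs``.  The inference budget
    defaults to the noise-scale study value (0.045), matching the
    perturbation noise the stability procedure injects.
    """
    design = design or benchmark_design()
    config = config or InferenceConfig()
    if threshold is None:
        threshold = n_runs // 2 + (1 if n_runs >= 100 else 0)
    report = ConsensusReport([], [], [], [])
    for s in range(n_seeds):
        truth, dataset = make_benchmark_dataset(design, seed=base_seed + s, density=density)
        scfg = StabilityConfig(
            n_runs=n_runs,
            noise_sd=noise_sd,
            frequency_threshold=threshold,
            seed=base_seed + 1000 * (s + 1),
        )
        stab = run_stability(dataset, None, config, scfg)
        consensus = build_consensus(stab, dataset)
        flat = flat_genes(dataset)
        sp, _, se = precision_recall(stab.reference.model, truth, flat)
        cp, _, ce = precision_recall(consensus.model, truth, flat)
        report.single_precision.append(sp)
        report.consensus_precision.append(cp)
        report.single_edges.append(stab.reference.model.n_edges())
        report.consensus_edges.append(consensus.model.n_edges())
    return report
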