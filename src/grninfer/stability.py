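"""Noise-perturbation stability analysis and the consensus network.

A single inferred network may hinge on idiosyncrasies of the measured
values.  To keep only robust structure, small Gaussian noise (default
sd 0.05, commensurate with the standardized [-1, 1] scale) is added to the
data and the inference repeated many times (default 100).  Every edge's
occurrence across the runs is tallied; edges whose absolute frequency
strictly exceeds the threshold (default 51 of 100) are regarded as stable
and integrated into the final consensus model, whose weights are refit by
least squares on the unperturbed data with the structure held fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import InferenceConfig, InferenceResult, infer_network, refit_structure
from .ode_core import NetworkModel
from .preprocess import StandardizedDataset, build_stacked_matrix, standardize_series

logger = logging.getLogger("grninfer")

__all__ = [
    "StabilityConfig",
    "StabilityResult",
    "ConsensusNetwork",
    "perturb_dataset",
    "run_stability",
    "build_consensus",
]


@dataclass(frozen=True)
class StabilityConfig:
    """Parameters of the noise-perturbation consensus procedure.

    ``frequency_threshold`` is strict: an edge needs frequency
    >= threshold + 1 to enter the consensus.  ``restandardize`` switches
    the perturbation mode from "noise on the standardized values, t = 0
    anchored at 0" (default) to "noise on all values, then re-standardize".
    """

    n_runs: int = 100
    noise_sd: float = 0.05
    frequency_threshold: int = 51
    seed: int = 0
    restandardize: bool = False

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be at least 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0 <= self.frequency_threshold <= self.n_runs):
            raise ValueError("frequency_threshold must lie in [0, n_runs]")


def perturb_dataset(
    dataset: StandardizedDataset,
    noise_sd: float,
    run_seed: int,
    restandardize: bool = False,
) -> StandardizedDataset:
    """Add i.i.d. Gaussian noise to every standardized value.

    In the default mode the t = 0 anchor stays exactly 0 (standardization
    defines it so) and perturbed values are clipped to [-1, 1] to preserve
    the standardized-scale invariant.  With ``restandardize`` the noise is
    applied to all values and each series is standardized again.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(run_seed)
    perturbed: dict[str, np.ndarray] = {}
    for stim in dataset.design.stimuli:
        mat = dataset.per_stimulus[stim]
        noisy = mat + rng.normal(0.0, noise_sd, size=mat.shape)
        if restandardize:
            noisy = np.apply_along_axis(standardize_series, 1, noisy)
        else:
            noisy[:, 0] = 0.0
            noisy = np.clip(noisy, -1.0, 1.0)
        perturbed[stim] = noisy
    return build_stacked_matrix(perturbed, dataset.design, dataset.gene_order)


@dataclass
class StabilityResult:
    """Edge-frequency table plus the per-run and reference models."""

    frequency: pd.DataFrame  # columns source, target, source_type, frequency
    run_models: list[NetworkModel]
    reference: InferenceResult
    config: StabilityConfig

    def edge_frequency(self, source: str, target: str, source_type: str) -> int:
        mask = (
            (self.frequency["source"] == source)
            & (self.frequency["target"] == target)
            & (self.frequency["source_type"] == source_type)
        )
        hits = self.frequency.loc[mask, "frequency"]
        return int(hits.iloc[0]) if len(hits) else 0


def run_stability(
    dataset: StandardizedDataset,
    prior,
    inference_config: InferenceConfig,
    stability_config: StabilityConfig,
) -> StabilityResult:
    """Repeated perturb-and-infer cycles with edge-occurrence accounting.

    Run *r* uses seed ``master_seed + r``.  The frequency table covers the
    union of the unperturbed model's edges and any novel edges appearing in
    perturbed runs; edge identity ignores weight sign and magnitude.
    Unconverged runs still contribute their realized edges.
    """
    reference = infer_network(dataset, prior, inference_config)
    counts: dict[tuple[str, str, str], int] = {
        e: 0 for e in reference.model.edge_set()
    }
    run_models: list[NetworkModel] = []
    for r in range(stability_config.n_runs):
        noisy = perturb_dataset(
            dataset,
            stability_config.noise_sd,
            run_seed=stability_config.seed + r,
            restandardize=stability_config.restandardize,
        )
        result = infer_network(noisy, prior, inference_config)
        run_models.append(result.model)
        for edge in result.model.edge_set():
            counts[edge] = counts.get(edge, 0) + 1
    rows = [
        (src, tgt, kind, freq)
        for (src, tgt, kind), freq in sorted(counts.items())
    ]
    frequency = pd.DataFrame(rows, columns=["source", "target", "source_type", "frequency"])
    return StabilityResult(frequency, run_models, reference, stability_config)


@dataclass
class ConsensusNetwork:
    """Stable edge set surviving the frequency threshold, with refit weights.

    ``edges`` has one row per accepted edge: source, target, source_type,
    weight (refit on the unperturbed data), frequency, and stability
    (frequency / n_runs).
    """

    model: NetworkModel
    edges: pd.DataFrame
    n_runs: int
    threshold: int


def build_consensus(
    stability: StabilityResult,
    dataset: StandardizedDataset,
    threshold: int | None = None,
) -> ConsensusNetwork:
    """Keep edges with frequency strictly above ``threshold`` and refit.

    Frequency 52 of 100 at threshold 51 is kept; frequency 51 is dropped.
    Weights of the accepted structure are re-estimated by least squares on
    the unperturbed dataset; per-edge stability scores are frequencies
    normalized by the number of runs.  An empty consensus is returned with
    a warning, not an error.
    """
    cfg = stability.config
    thr = cfg.frequency_threshold if threshold is None else int(threshold)
    if thr > cfg.n_runs:
        raise ValueError("threshold cannot exceed n_runs")
    accepted = stability.frequency[stability.frequency["frequency"] > thr]
    edge_ids = {
        (row.source, row.target, row.source_type)
        for row in accepted.itertuples(index=False)
    }
    if not edge_ids:
        logger.warning(
            "no edge reached frequency > %d of %d runs; consensus is empty", thr, cfg.n_runs
        )
    model = refit_structure(dataset, edge_ids)
    weights = {
        (r.source, r.target, r.source_type): r.weight
        for r in model.edge_table().itertuples(index=False)
    }
    rows = []
    for row in accepted.itertuples(index=False):
        key = (row.source, row.target, row.source_type)
        rows.append(
            (*key, weights.get(key, 0.0), int(row.frequency), row.frequency / cfg.n_runs)
        )
    edges = pd.DataFrame(
        rows,
        columns=["source", "target", "source_type", "weight", "frequency", "stability"],
    )
    return ConsensusNetwork(model=model, edges=edges, n_runs=cfg.n_runs, threshold=thr)
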