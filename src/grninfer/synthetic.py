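"""Synthetic ground-truth networks and simulated multi-stimuli time courses.

Emulates the shape of a stimulation study on cultured cells: a panel of N
genes is profiled at a handful of time points after application of one of M
external stimuli, with several biological replicates per stimulus.  The
default design mirrors a 24-gene, 4-stimulus experiment sampled at
0/1/2/4/12 h with 6 replicates per stimulus (120 arrays in total).

A ground-truth :class:`~grninfer.ode_core.NetworkModel` is drawn with sparse
random gene-to-gene and stimulus-to-gene edges and strictly negative
self-decay on every gene, the noise-free step responses are simulated
exactly, and replicate measurements are produced by adding a
replicate-specific baseline offset (biological, patient-to-patient
variance) plus i.i.d. Gaussian measurement noise on the raw scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ode_core import GENE, STIMULUS, NetworkModel, simulate_trajectories

__all__ = [
    "ExperimentDesign",
    "GroundTruth",
    "SimulatedDataset",
    "generate_random_network",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
    "write_truth_edges",
]

#: Self-decay range for diagonal entries a_ii (always negative so that the
#: step response is bounded, as measured transcriptional responses are).
DECAY_RANGE = (-2.0, -0.2)

#: Replicate baseline-offset sd, as a fraction of the measurement noise sd.
BASELINE_RATIO = 0.5


@dataclass(frozen=True)
class ExperimentDesign:
    """Shape of a multi-stimuli time-course study."""

    stimuli: tuple[str, ...]
    time_points: tuple[float, ...]
    n_replicates: int
    n_genes: int

    def __post_init__(self) -> None:
        if len(self.stimuli) < 1 or self.n_genes < 1 or self.n_replicates < 1:
            raise ValueError("need at least one stimulus, gene, and replicate")
        tp = np.asarray(self.time_points, dtype=float)
        if tp.size == 0 or tp[0] != 0.0 or np.any(np.diff(tp) <= 0):
            raise ValueError("time_points must be strictly increasing and start at 0")

    @property
    def n_stimuli(self) -> int:
        return len(self.stimuli)

    @property
    def n_times(self) -> int:
        return len(self.time_points)

    @property
    def n_arrays(self) -> int:
        """Total number of expression samples (arrays) in the study."""
        return self.n_stimuli * self.n_times * self.n_replicates

    def gene_labels(self) -> list[str]:
        return [f"g{i + 1:02d}" for i in range(self.n_genes)]


def default_design(
    n_genes: int = 24,
    stimuli: tuple[str, ...] = ("IL1b", "TNFa", "TGFb", "PDGFD"),
    time_points: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 12.0),
    n_replicates: int = 6,
) -> ExperimentDesign:
    """The study-scale default: 24 genes, 4 stimuli, 5 time points, 6 replicates."""
    return ExperimentDesign(tuple(stimuli), tuple(time_points), n_replicates, n_genes)


@dataclass(frozen=True)
class GroundTruth:
    """A generating model together with its replicate-noise level and seed."""

    model: NetworkModel
    noise_sd: float
    seed: int
    flat_genes: tuple[str, ...] = ()  # genes with no incoming edge, constitutively flat

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SimulatedDataset:
    """Raw replicate measurements plus the paired noise-free truth.

    ``values`` has shape (n_genes, n_times, n_replicates, n_stimuli);
    ``truth_trajectories`` maps stimulus label -> gene x time array.
    """

    values: np.ndarray
    truth_trajectories: dict[str, np.ndarray]
    design: ExperimentDesign
    truth: GroundTruth


def generate_random_network(
    design: ExperimentDesign,
    gene_edge_density: float = 0.15,
    stim_edge_density: float = 0.15,
    weight_range: tuple[float, float] = (0.5, 2.0),
    seed: int = 0,
) -> GroundTruth:
    """Draw a sparse random ground-truth network.

    Off-diagonal gene-to-gene edges appear independently with probability
    ``gene_edge_density`` and stimulus-to-gene edges with
    ``stim_edge_density``; edge weights are uniform on
    ``±[weight_range[0], weight_range[1]]`` (sign chosen by fair coin).
    Every diagonal entry a_ii is drawn from the negative range
    ``DECAY_RANGE`` regardless of density — self-decay keeps every step
    response bounded — and is bookkept separately from edges.

    Genes left with no incoming gene or stimulus edge are constitutively
    flat and recorded in ``GroundTruth.flat_genes``.
    """
    if not (0 < gene_edge_density <= 1) or not (0 < stim_edge_density <= 1):
        raise ValueError("edge densities must lie in (0, 1]")
    lo, hi = float(weight_range[0]), float(weight_range[1])
    if not (0 < lo <= hi):
        raise ValueError("weight_range must be positive magnitudes (lo, hi), lo <= hi")
    rng = np.random.default_rng(seed)
    n, m = design.n_genes, design.n_stimuli

    def draw_weights(mask: np.ndarray) -> np.ndarray:
        w = rng.uniform(lo, hi, size=mask.shape) * rng.choice([-1.0, 1.0], size=mask.shape)
        return np.where(mask, w, 0.0)

    off_mask = rng.random((n, n)) < gene_edge_density
    np.fill_diagonal(off_mask, False)
    A = draw_weights(off_mask)
    np.fill_diagonal(A, rng.uniform(DECAY_RANGE[0], DECAY_RANGE[1], size=n))
    B = draw_weights(rng.random((n, m)) < stim_edge_density)

    model = NetworkModel(A, B, design.gene_labels(), list(design.stimuli))
    incoming = (np.count_nonzero(A, axis=1) - 1) + np.count_nonzero(B, axis=1)
    flat = tuple(g for g, deg in zip(model.gene_order, incoming) if deg == 0)
    return GroundTruth(model=model, noise_sd=0.05, seed=int(seed), flat_genes=flat)


def simulate_dataset(
    truth: GroundTruth,
    design: ExperimentDesign,
    noise_sd: float | None = None,
) -> SimulatedDataset:
    """Simulate the study: per-stimulus step responses plus replicate noise.

    For each stimulus the noise-free trajectory is computed with only that
    input active, then each replicate receives a constant baseline offset
    (sd ``BASELINE_RATIO * noise_sd``, emulating between-individual
    variance) and i.i.d. Gaussian measurement noise (sd ``noise_sd``), both
    on the raw, pre-standardization scale.  ``noise_sd = 0`` yields
    replicates identical to the truth.
    """
    model = truth.model
    if model.n_genes != design.n_genes or model.n_stimuli != design.n_stimuli:
        raise ValueError(
            f"model ({model.n_genes} genes x {model.n_stimuli} stimuli) does not "
            f"match design ({design.n_genes} x {design.n_stimuli})"
        )
    sd = truth.noise_sd if noise_sd is None else float(noise_sd)
    if sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(truth.seed)
    times = np.asarray(design.time_points, dtype=float)
    n, t, r, m = design.n_genes, times.size, design.n_replicates, design.n_stimuli

    values = np.zeros((n, t, r, m))
    truth_traj: dict[str, np.ndarray] = {}
    for k, stim in enumerate(design.stimuli):
        clean = simulate_trajectories(model, k, times)
        truth_traj[stim] = clean
        baseline = rng.normal(0.0, BASELINE_RATIO * sd, size=(n, 1, r))
        noise = rng.normal(0.0, sd, size=(n, t, r))
        values[:, :, :, k] = clean[:, :, None] + baseline + noise
    return SimulatedDataset(values=values, truth_trajectories=truth_traj, design=design, truth=truth)


# ---------------------------------------------------------------------------
# Plain-text IO (long-format measurement table, ground-truth edge list)
# ---------------------------------------------------------------------------

def dataset_to_frame(sim: SimulatedDataset) -> pd.DataFrame:
    """Long-format table with columns gene, stimulus, time_h, replicate, value."""
    design = sim.design
    genes = sim.truth.model.gene_order
    rows = []
    for k, stim in enumerate(design.stimuli):
        for ti, time in enumerate(design.time_points):
            for r in range(design.n_replicates):
                for gi, gene in enumerate(genes):
                    rows.append((gene, stim, time, r + 1, sim.values[gi, ti, r, k]))
    return pd.DataFrame(rows, columns=["gene", "stimulus", "time_h", "replicate", "value"])


def write_dataset(sim: SimulatedDataset, path) -> None:
    dataset_to_frame(sim).to_csv(path, sep="\t", index=False)


def read_dataset(path) -> pd.DataFrame:
    """Read a long-format measurement table (tab- or comma-separated)."""
    table = pd.read_csv(path, sep=None, engine="python")
    required = {"gene", "stimulus", "time_h", "replicate", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"dataset table is missing columns: {sorted(missing)}")
    return table


def write_truth_edges(truth: GroundTruth, path) -> None:
    """Ground-truth edge list (source, target, weight, type) kept with the data."""
    table = truth.model.edge_table().rename(columns={"source_type": "type"})
    table.to_csv(path, sep="\t", index=False)


def read_truth_edges(path, gene_order: list[str], stimulus_order: list[str]) -> NetworkModel:
    table = pd.read_csv(path, sep="\t").rename(columns={"type": "source_type"})
    return NetworkModel.from_edge_table(table, gene_order, stimulus_order)


# re-exported names used by edge tables
_ = (GENE, STIMULUS)
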