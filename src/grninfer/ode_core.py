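"""Linear ODE network model: structure, simulation, and fit metrics.

The regulatory model is the linear time-invariant system

    dx_i/dt = sum_j a_ij x_j(t) + sum_k b_ik u_k(t),      x(0) = 0,

where ``x_i`` is the standardized expression of gene *i*, ``a_ij`` the
gene-to-gene interaction weight (regulation of gene *i* by gene *j*),
``b_ik`` the input weight of external stimulus *k*, and ``u_k`` a unit step
(0 before stimulation, 1 from t = 0 on).  Positive weights encode
activation, negative weights repression.  Each biological experiment block
applies exactly one stimulus, so simulation proceeds block by block with a
one-hot input vector.

Because the system is LTI with piecewise-constant input, trajectories are
propagated exactly between sampling times with the augmented matrix
exponential; an adaptive numerical integrator serves as the independent
cross-check in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

logger = logging.getLogger("grninfer")

GENE = "gene"
STIMULUS = "stimulus"

__all__ = [
    "NetworkModel",
    "FitMetrics",
    "simulate_trajectories",
    "compute_metrics",
    "per_gene_max_error",
    "count_potential_interactions",
    "min_samples_for_identification",
]


@dataclass
class NetworkModel:
    """Signed, sparse interaction structure of a gene regulatory network.

    Parameters
    ----------
    A : ndarray of shape (N, N)
        Gene-to-gene weights; ``A[i, j]`` is the effect of gene *j* on the
        rate of gene *i*.  Structural zeros are exact zeros.
    B : ndarray of shape (N, M)
        Stimulus-to-gene input weights; ``B[i, k]`` is the effect of the
        step input of stimulus *k* on gene *i*.
    gene_order, stimulus_order : list of str
        Node labels, fixing the row/column interpretation.
    """

    A: np.ndarray
    B: np.ndarray
    gene_order: list[str] = field(default_factory=list)
    stimulus_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError(f"A must be square, got shape {self.A.shape}")
        if self.B.ndim != 2 or self.B.shape[0] != self.A.shape[0]:
            raise ValueError(
                f"B must have one row per gene: A is {self.A.shape}, B is {self.B.shape}"
            )
        if not self.gene_order:
            self.gene_order = [f"g{i + 1:02d}" for i in range(self.A.shape[0])]
        if not self.stimulus_order:
            self.stimulus_order = [f"u{k + 1}" for k in range(self.B.shape[1])]
        if len(self.gene_order) != self.A.shape[0]:
            raise ValueError("gene_order length does not match A")
        if len(self.stimulus_order) != self.B.shape[1]:
            raise ValueError("stimulus_order length does not match B")
        if not (np.isfinite(self.A).all() and np.isfinite(self.B).all()):
            raise ValueError("model weights must be finite")

    @property
    def n_genes(self) -> int:
        return self.A.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.B.shape[1]

    def n_edges(self) -> int:
        """Total edge count: non-zero off-diagonal entries of A plus non-zero
        entries of B.  Diagonal entries are per-gene decay terms, bookkept
        separately from regulatory edges."""
        off = np.count_nonzero(self.A) - np.count_nonzero(np.diag(self.A))
        return int(off + np.count_nonzero(self.B))

    def edge_table(self) -> pd.DataFrame:
        """Edge list with columns source, target, weight, source_type."""
        rows = []
        for i, tgt in enumerate(self.gene_order):
            for j, src in enumerate(self.gene_order):
                if self.A[i, j] != 0.0:
                    rows.append((src, tgt, self.A[i, j], GENE))
            for k, src in enumerate(self.stimulus_order):
                if self.B[i, k] != 0.0:
                    rows.append((src, tgt, self.B[i, k], STIMULUS))
        return pd.DataFrame(rows, columns=["source", "target", "weight", "source_type"])

    def edge_set(self, include_diagonal: bool = False) -> set[tuple[str, str, str]]:
        """Unsigned edge identities ``(source, target, source_type)``.

        Diagonal decay terms are excluded by default; pass
        ``include_diagonal=True`` to treat self-loops as edges.
        """
        edges = set()
        for i, tgt in enumerate(self.gene_order):
            for j, src in enumerate(self.gene_order):
                if self.A[i, j] != 0.0 and (include_diagonal or i != j):
                    edges.add((src, tgt, GENE))
            for k, src in enumerate(self.stimulus_order):
                if self.B[i, k] != 0.0:
                    edges.add((src, tgt, STIMULUS))
        return edges

    def write_edge_table(self, path) -> None:
        self.edge_table().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_edge_table(
        cls,
        table: pd.DataFrame,
        gene_order: list[str],
        stimulus_order: list[str],
    ) -> "NetworkModel":
        """Rebuild the weight matrices from an edge list.

        ``gene_order``/``stimulus_order`` must be given because an edge list
        does not record isolated nodes.
        """
        gi = {g: i for i, g in enumerate(gene_order)}
        si = {s: k for k, s in enumerate(stimulus_order)}
        A = np.zeros((len(gene_order), len(gene_order)))
        B = np.zeros((len(gene_order), len(stimulus_order)))
        for row in table.itertuples(index=False):
            if row.source_type == GENE:
                A[gi[row.target], gi[row.source]] = row.weight
            elif row.source_type == STIMULUS:
                B[gi[row.target], si[row.source]] = row.weight
            else:
                raise ValueError(f"unknown source_type {row.source_type!r}")
        return cls(A, B, list(gene_order), list(stimulus_order))

    def write_matrices(self, a_path, b_path) -> None:
        """Serialize A and B as a pair of labeled square/rectangular CSVs."""
        pd.DataFrame(self.A, index=self.gene_order, columns=self.gene_order).to_csv(a_path)
        pd.DataFrame(self.B, index=self.gene_order, columns=self.stimulus_order).to_csv(b_path)

    @classmethod
    def read_matrices(cls, a_path, b_path) -> "NetworkModel":
        a = pd.read_csv(a_path, index_col=0)
        b = pd.read_csv(b_path, index_col=0)
        return cls(a.to_numpy(), b.to_numpy(), list(a.index), list(b.columns))


@dataclass(frozen=True)
class FitMetrics:
    """Goodness-of-fit of simulated kinetics against measured series.

    ``max_abs_error`` is the largest absolute deviation over all genes,
    stimuli, and time points — the quantity bounded by the ``allowed_error``
    budget.  ``avg_mse`` is the per-series mean squared error averaged over
    all (gene, stimulus) series.
    """

    max_abs_error: float
    avg_mse: float


def simulate_trajectories(
    model: NetworkModel, stimulus: int | str, times: np.ndarray
) -> np.ndarray:
    """Step response of the network to a single stimulus.

    Solves ``dx/dt = A x + B[:, k]`` with ``x(0) = 0`` (the standardized
    scale anchors every series at zero) and the unit step of stimulus ``k``
    active from t = 0; all other inputs stay off.  Values are exact at the
    requested times up to the accuracy of the matrix exponential: the state
    is advanced interval by interval with ``expm`` of the augmented system
    ``[[A, b], [0, 0]]``.

    Returns a gene x time array aligned with ``times``.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0 or times[0] != 0.0:
        raise ValueError("times must start at 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    k = model.stimulus_order.index(stimulus) if isinstance(stimulus, str) else int(stimulus)
    n = model.n_genes
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = model.A
    aug[:n, n] = model.B[:, k]
    state = np.zeros(n + 1)
    state[n] = 1.0  # the step input, constant for t >= 0
    out = np.zeros((n, times.size))
    for idx in range(1, times.size):
        dt = times[idx] - times[idx - 1]
        state = expm(aug * dt) @ state
        out[:, idx] = state[:n]
    return out


def _residual_blocks(model: NetworkModel, dataset) -> np.ndarray:
    """Stacked (stimulus, gene, time) residual array simulated - measured."""
    if model.n_genes != dataset.design.n_genes or model.n_stimuli != len(
        dataset.design.stimuli
    ):
        raise ValueError(
            "model dimensions do not match dataset design "
            f"({model.n_genes} genes x {model.n_stimuli} stimuli vs "
            f"{dataset.design.n_genes} x {len(dataset.design.stimuli)})"
        )
    times = np.asarray(dataset.design.time_points, dtype=float)
    res = np.zeros((model.n_stimuli, model.n_genes, times.size))
    for k, stim in enumerate(dataset.design.stimuli):
        sim = simulate_trajectories(model, k, times)
        res[k] = sim - dataset.per_stimulus[stim]
    return res


def compute_metrics(model: NetworkModel, dataset) -> FitMetrics:
    """Fit metrics of a model against a :class:`StandardizedDataset`.

    Each stimulus block is simulated independently from x(0) = 0 and
    compared at the measured time points only.
    """
    res = _residual_blocks(model, dataset)
    return FitMetrics(
        max_abs_error=float(np.abs(res).max()) if res.size else 0.0,
        avg_mse=float(np.mean(res**2)) if res.size else 0.0,
    )


def per_gene_max_error(model: NetworkModel, dataset) -> np.ndarray:
    """Per-gene max |simulated - measured| over all stimuli and time points."""
    res = _residual_blocks(model, dataset)
    return np.abs(res).max(axis=(0, 2))


def count_potential_interactions(n_genes: int, n_stimuli: int) -> int:
    """Number of candidate edges in the fully connected model: N^2 + M*N.

    Every gene can be regulated by every gene (self-regulation included)
    and by every stimulus.
    """
    if n_genes < 0 or n_stimuli < 0:
        raise ValueError("gene and stimulus counts must be non-negative")
    return n_genes * n_genes + n_stimuli * n_genes


def min_samples_for_identification(n_genes: int, n_stimuli: int) -> int:
    """Lower bound on the number of expression samples needed to identify
    the fully connected model.

    Each sample contributes N expression values, i.e. N equations, while
    the full model has ``N^2 + M*N`` unknown weights; at least ``N + M``
    samples are therefore required.
    """
    if n_genes < 0 or n_stimuli < 0:
        raise ValueError("gene and stimulus counts must be non-negative")
    return n_genes + n_stimuli
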