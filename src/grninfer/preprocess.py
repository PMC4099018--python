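"""Replicate averaging, standardization, and the stacked inference matrix.

Standardization makes time series from different genes and stimuli
comparable: each series is centered by subtracting its 0 h value (so every
series starts at 0) and scaled by its absolute extreme (so values lie in
[-1, 1]).  Averaging over biological replicates precedes standardization.
The per-stimulus gene x time matrices are finally stacked, stimulus-major,
into a single (M*T) x N matrix — e.g. 4 stimuli x 5 time points x 24 genes
gives a 20 x 24 inference matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ExperimentDesign

__all__ = [
    "StandardizedDataset",
    "average_replicates",
    "standardize_series",
    "build_stacked_matrix",
    "standardize_dataset",
]


@dataclass
class StandardizedDataset:
    """Standardized per-stimulus expression matrices plus their stacking.

    ``per_stimulus[stim]`` is a gene x time array of standardized values;
    rows follow ``gene_order`` and columns ``design.time_points``.
    """

    per_stimulus: dict[str, np.ndarray]
    design: ExperimentDesign
    gene_order: list[str]

    def __post_init__(self) -> None:
        t = self.design.n_times
        for stim in self.design.stimuli:
            mat = np.asarray(self.per_stimulus[stim], dtype=float)
            if mat.shape != (self.design.n_genes, t):
                raise ValueError(
                    f"matrix for stimulus {stim!r} has shape {mat.shape}, "
                    f"expected ({self.design.n_genes}, {t})"
                )
            if np.abs(mat[:, 0]).max(initial=0.0) > 1e-12:
                raise ValueError(f"series for stimulus {stim!r} do not start at 0")
            if np.abs(mat).max(initial=0.0) > 1.0 + 1e-9:
                raise ValueError(f"standardized values for {stim!r} exceed [-1, 1]")
            self.per_stimulus[stim] = mat

    @property
    def stacked(self) -> np.ndarray:
        """(M*T) x N matrix; rows are (stimulus, time) pairs, stimulus-major."""
        return np.vstack([self.per_stimulus[s].T for s in self.design.stimuli])

    def to_frame(self) -> pd.DataFrame:
        index = pd.MultiIndex.from_product(
            [self.design.stimuli, self.design.time_points], names=["stimulus", "time_h"]
        )
        return pd.DataFrame(self.stacked, index=index, columns=self.gene_order)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path, n_replicates: int = 1) -> "StandardizedDataset":
        frame = pd.read_csv(path, sep="\t", index_col=[0, 1])
        stimuli = list(dict.fromkeys(frame.index.get_level_values(0)))
        times = tuple(sorted(set(frame.index.get_level_values(1))))
        genes = list(frame.columns)
        design = ExperimentDesign(tuple(stimuli), times, n_replicates, len(genes))
        per_stim = {
            s: frame.loc[s].reindex(list(times)).to_numpy().T for s in stimuli
        }
        return cls(per_stim, design, genes)


def average_replicates(
    raw: pd.DataFrame, design: ExperimentDesign, gene_order: list[str] | None = None
) -> dict[str, np.ndarray]:
    """Arithmetic mean over replicates, per (gene, stimulus, time) cell.

    ``raw`` is the long-format table with columns gene, stimulus, time_h,
    replicate, value.  Every cell must hold at least one replicate value;
    a missing cell raises a data-completeness error naming it.
    """
    if gene_order is None:
        gene_order = list(pd.unique(raw["gene"]))
    means = raw.groupby(["stimulus", "gene", "time_h"], sort=False)["value"].mean()
    out: dict[str, np.ndarray] = {}
    for stim in design.stimuli:
        mat = np.full((len(gene_order), design.n_times), np.nan)
        for gi, gene in enumerate(gene_order):
            for ti, time in enumerate(design.time_points):
                try:
                    mat[gi, ti] = means[(stim, gene, time)]
                except KeyError:
                    raise ValueError(
                        f"no measurement for gene={gene!r}, stimulus={stim!r}, "
                        f"time_h={time}"
                    ) from None
        out[stim] = mat
    return out


def standardize_series(series: np.ndarray) -> np.ndarray:
    """Center a time series at its first value and scale to [-1, 1].

    Returns ``(series - series[0]) / max|series - series[0]|``; the result
    starts at 0 and its extreme reaches ±1.  A constant series (no dynamic
    signal) maps to all zeros, avoiding division by zero.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("series must be non-empty")
    centered = series - series[0]
    extreme = np.abs(centered).max()
    if extreme == 0.0:
        return np.zeros_like(centered)
    return centered / extreme


def build_stacked_matrix(
    per_stimulus: dict[str, np.ndarray],
    design: ExperimentDesign,
    gene_order: list[str],
) -> StandardizedDataset:
    """Assemble per-stimulus standardized matrices into the inference input."""
    shapes = {s: np.asarray(m).shape for s, m in per_stimulus.items()}
    if len(set(shapes.values())) > 1:
        raise ValueError(f"per-stimulus matrices have inconsistent shapes: {shapes}")
    return StandardizedDataset(dict(per_stimulus), design, list(gene_order))


def standardize_dataset(
    raw: pd.DataFrame, design: ExperimentDesign, gene_order: list[str] | None = None
) -> StandardizedDataset:
    """Average replicates, standardize every gene/stimulus series, stack.

    Genes whose series is constant under some stimulus carry no dynamic
    information there; they standardize to all zeros and are logged.
    """
    import logging

    if gene_order is None:
        gene_order = list(pd.unique(raw["gene"]))
    averaged = average_replicates(raw, design, gene_order)
    standardized: dict[str, np.ndarray] = {}
    for stim, mat in averaged.items():
        out = np.zeros_like(mat)
        for gi in range(mat.shape[0]):
            out[gi] = standardize_series(mat[gi])
            if np.all(out[gi] == 0.0):
                logging.getLogger("grninfer").info(
                    "gene %s is constant under stimulus %s; standardized to zeros",
                    gene_order[gi],
                    stim,
                )
        standardized[stim] = out
    return build_stacked_matrix(standardized, design, gene_order)
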