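"""Edge classification against prior knowledge, summaries, and export.

Inferred edges fall into three classes, mirroring the conventional
green/black/red network coloring:

* ``prior_supported`` (green): gene-to-gene edge with an unsigned prior
  connection (code 1), or a signed prior (10 / -10) whose sign the fitted
  weight matches;
* ``predicted`` (black): no prior information — code NA, and every
  stimulus-to-gene edge, for which no prior exists;
* ``contradictory`` (red): fitted sign violates a signed prior, or the
  prior asserts "no connection" (code 0) for a realized edge.

Networks are exported as SIF, GraphML, or a delimited edge table.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .ode_core import GENE, STIMULUS, NetworkModel
from .prior_knowledge import PriorMatrix, prior_preference
from .stability import ConsensusNetwork

__all__ = [
    "EdgeClassification",
    "classify_edges",
    "summarize_network",
    "export_network",
    "import_graphml",
    "plot_fit",
]

LABELS = ("prior_supported", "predicted", "contradictory")
LABEL_COLORS = {"prior_supported": "green", "predicted": "black", "contradictory": "red"}


def _edge_frame(network: NetworkModel | ConsensusNetwork) -> pd.DataFrame:
    if isinstance(network, ConsensusNetwork):
        return network.edges.copy()
    table = network.edge_table()
    # diagonal entries are per-gene decay terms, not regulatory edges
    decay = (table["source"] == table["target"]) & (table["source_type"] == GENE)
    return table[~decay].reset_index(drop=True)


def _network_model(network: NetworkModel | ConsensusNetwork) -> NetworkModel:
    return network.model if isinstance(network, ConsensusNetwork) else network


@dataclass
class EdgeClassification:
    """Per-edge labels plus summary counts by label and by edge kind."""

    table: pd.DataFrame  # edge columns + "label"
    counts: dict[str, int]
    counts_by_kind: dict[str, dict[str, int]]

    @property
    def n_edges(self) -> int:
        return len(self.table)


def _classify_one(weight: float, code: str) -> str:
    pref = prior_preference(code)
    if pref.favored == "neutral":
        return "predicted"
    if pref.favored == "no":
        return "contradictory"
    if pref.sign_constraint is None:  # code 1 asserts existence only
        return "prior_supported"
    matches = (weight > 0) == (pref.sign_constraint > 0)
    return "prior_supported" if matches else "contradictory"


def classify_edges(
    network: NetworkModel | ConsensusNetwork, prior: PriorMatrix
) -> EdgeClassification:
    """Label every edge of the network against the prior matrix.

    Stimulus-to-gene edges have no prior and are always ``predicted``.
    """
    edges = _edge_frame(network)
    labels = []
    for row in edges.itertuples(index=False):
        if row.source_type == STIMULUS:
            labels.append("predicted")
        else:
            labels.append(_classify_one(row.weight, prior.code(row.target, row.source)))
    table = edges.assign(label=labels)
    counts = {lab: int((table["label"] == lab).sum()) for lab in LABELS}
    by_kind = {
        kind: {
            lab: int(((table["label"] == lab) & (table["source_type"] == kind)).sum())
            for lab in LABELS
        }
        for kind in (STIMULUS, GENE)
    }
    return EdgeClassification(table=table, counts=counts, counts_by_kind=by_kind)


def summarize_network(network: NetworkModel | ConsensusNetwork) -> dict:
    """Edge counts by kind plus the per-stimulus out-degree table."""
    model = _network_model(network)
    edges = _edge_frame(network)
    n_stim = int((edges["source_type"] == STIMULUS).sum())
    n_gene = int((edges["source_type"] == GENE).sum())
    out_degree = {
        stim: int(
            ((edges["source"] == stim) & (edges["source_type"] == STIMULUS)).sum()
        )
        for stim in model.stimulus_order
    }
    return {
        "n_edges_total": n_stim + n_gene,
        "n_stimulus_edges": n_stim,
        "n_gene_edges": n_gene,
        "stimulus_out_degree": out_degree,
    }


def _to_graph(
    network: NetworkModel | ConsensusNetwork,
    classification: EdgeClassification | None,
) -> nx.DiGraph:
    model = _network_model(network)
    edges = (
        classification.table if classification is not None else _edge_frame(network)
    )
    graph = nx.DiGraph()
    for gene in model.gene_order:
        graph.add_node(gene, kind=GENE)
    for stim in model.stimulus_order:
        graph.add_node(stim, kind=STIMULUS)
    for row in edges.itertuples(index=False):
        attrs = {"weight": float(row.weight), "source_type": row.source_type}
        if hasattr(row, "frequency"):
            attrs["frequency"] = int(row.frequency)
        if hasattr(row, "stability"):
            attrs["stability"] = float(row.stability)
        if hasattr(row, "label"):
            attrs["label"] = row.label
            attrs["color"] = LABEL_COLORS[row.label]
        graph.add_edge(row.source, row.target, **attrs)
    return graph


def export_network(
    network: NetworkModel | ConsensusNetwork,
    path,
    fmt: str = "edge-table",
    classification: EdgeClassification | None = None,
) -> None:
    """Write the network as ``sif``, ``graphml``, or ``edge-table``.

    SIF rows read "source activates|represses target" by weight sign;
    GraphML carries weight, frequency, and classification label as edge
    attributes and round-trips through :func:`import_graphml`.
    """
    if fmt == "edge-table":
        edges = (
            classification.table if classification is not None else _edge_frame(network)
        )
        edges.to_csv(path, sep="\t", index=False)
    elif fmt == "sif":
        edges = _edge_frame(network)
        with open(path, "w") as fh:
            for row in edges.itertuples(index=False):
                kind = "activates" if row.weight > 0 else "represses"
                fh.write(f"{row.source}\t{kind}\t{row.target}\n")
    elif fmt == "graphml":
        nx.write_graphml(_to_graph(network, classification), path)
    else:
        raise ValueError(f"unknown export format {fmt!r}; use sif, graphml, or edge-table")


def import_graphml(path) -> nx.DiGraph:
    """Read back a GraphML export with all edge attributes."""
    return nx.read_graphml(path)


def plot_fit(
    model: NetworkModel,
    dataset,
    path,
    n_dense: int = 120,
) -> None:
    """Per-gene panels of measured (dashed, linearly interpolated) versus
    simulated (solid) standardized expression, one colored line per stimulus.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    from .ode_core import simulate_trajectories

    times = np.asarray(dataset.design.time_points, dtype=float)
    dense = np.unique(np.concatenate([np.linspace(0.0, times[-1], n_dense), times]))
    genes = model.gene_order
    ncols = min(4, len(genes))
    nrows = -(-len(genes) // ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 2.4 * nrows), squeeze=False
    )
    colors = plt.cm.tab10.colors
    for k, stim in enumerate(dataset.design.stimuli):
        sim = simulate_trajectories(model, k, dense)
        meas = dataset.per_stimulus[stim]
        for gi, gene in enumerate(genes):
            ax = axes[gi // ncols][gi % ncols]
            c = colors[k % len(colors)]
            ax.plot(times, meas[gi], "--", color=c, lw=1, label=f"{stim} measured")
            ax.plot(dense, sim[gi], "-", color=c, lw=1.2, label=f"{stim} simulated")
            ax.set_title(gene, fontsize=8)
            ax.set_ylim(-1.15, 1.15)
    for idx in range(len(genes), nrows * ncols):
        axes[idx // ncols][idx % ncols].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
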