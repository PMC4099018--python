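"""Literature prior-knowledge matrix in the five-code scheme.

Curated knowledge about gene-to-gene regulation enters the inference as an
N x N table of codes, entry (i, j) describing regulation of gene *i* (row,
target) by gene *j* (column, regulator):

====  =============================================
code  meaning
====  =============================================
1     a connection exists (sign unknown)
10    an activation exists (positive sign expected)
-10   an inhibition exists (negative sign expected)
0     no connection exists
NA    no information available
====  =============================================

Integration is *soft*: codes bias the structure search (candidate ordering
bonus) but never force or forbid an edge, so the fit can drop a literature
edge or keep one that contradicts it; contradictions are reported
downstream.  Priors cover gene-to-gene interactions only — stimulus inputs
carry no prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ode_core import NetworkModel

__all__ = [
    "PriorMatrix",
    "PriorPreference",
    "read_prior",
    "prior_preference",
    "count_prior_edges",
]

VALID_CODES = ("NA", "0", "1", "10", "-10")


@dataclass(frozen=True)
class PriorPreference:
    """Soft-integration semantics of one prior code."""

    favored: str  # "yes" | "no" | "neutral"
    sign_constraint: int | None  # +1, -1 or None

    @property
    def bias(self) -> float:
        """Ordering bias: +1 favored, -1 disfavored, 0 neutral."""
        return {"yes": 1.0, "no": -1.0, "neutral": 0.0}[self.favored]


_PREFERENCES = {
    "1": PriorPreference("yes", None),
    "10": PriorPreference("yes", +1),
    "-10": PriorPreference("yes", -1),
    "0": PriorPreference("no", None),
    "NA": PriorPreference("neutral", None),
}


def prior_preference(code: str) -> PriorPreference:
    """Map a prior code to its soft-integration preference."""
    code = str(code)
    if code not in _PREFERENCES:
        raise ValueError(f"unknown prior code {code!r}; valid codes: {VALID_CODES}")
    return _PREFERENCES[code]


@dataclass
class PriorMatrix:
    """N x N table of prior codes; rows are targets, columns regulators."""

    codes: pd.DataFrame

    def __post_init__(self) -> None:
        if self.codes.shape[0] == 0:
            raise ValueError("prior matrix is empty")
        if self.codes.shape[0] != self.codes.shape[1]:
            raise ValueError(f"prior matrix must be square, got {self.codes.shape}")
        if list(self.codes.index) != list(self.codes.columns):
            raise ValueError("prior matrix row and column gene orders differ")
        self.codes = self.codes.astype(str)
        for i, row in enumerate(self.codes.itertuples(index=False)):
            for j, val in enumerate(row):
                if val not in VALID_CODES:
                    raise ValueError(
                        f"unknown prior code {val!r} at "
                        f"({self.codes.index[i]!r}, {self.codes.columns[j]!r})"
                    )

    @property
    def gene_order(self) -> list[str]:
        return list(self.codes.index)

    def code(self, target: str, regulator: str) -> str:
        return str(self.codes.at[target, regulator])

    def bias_matrix(self, gene_order: list[str]) -> np.ndarray:
        """Ordering-bias matrix aligned to ``gene_order`` (+1/0/-1 entries)."""
        aligned = self.codes.reindex(index=gene_order, columns=gene_order, fill_value="NA")
        return np.vectorize(lambda c: prior_preference(c).bias)(aligned.to_numpy())

    def write(self, path) -> None:
        self.codes.to_csv(path)

    @classmethod
    def all_na(cls, gene_order: list[str]) -> "PriorMatrix":
        """Uninformative prior: every entry NA."""
        frame = pd.DataFrame("NA", index=list(gene_order), columns=list(gene_order))
        return cls(frame)


def read_prior(path) -> PriorMatrix:
    """Read a prior-knowledge CSV with literal tokens NA, 0, 1, 10, -10.

    The file carries a header row and an index column of gene labels;
    lines starting with ``#`` are comments.  Gene order is taken from the
    file.
    """
    try:
        frame = pd.read_csv(
            path, index_col=0, dtype=str, keep_default_na=False, comment="#"
        )
    except pd.errors.EmptyDataError:
        raise ValueError(f"prior file {path} is empty") from None
    return PriorMatrix(frame)


def count_prior_edges(model: NetworkModel, prior: PriorMatrix) -> int:
    """Count realized gene-to-gene edges backed by prior knowledge.

    An edge counts when its prior code is 1, 10 or -10, regardless of
    whether the fitted sign matches the code (sign agreement is reported
    separately by edge classification).  Diagonal decay terms are not
    edges and never count.
    """
    count = 0
    genes = model.gene_order
    for i, tgt in enumerate(genes):
        for j, src in enumerate(genes):
            if i != j and model.A[i, j] != 0.0 and prior.code(tgt, src) in ("1", "10", "-10"):
                count += 1
    return count
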