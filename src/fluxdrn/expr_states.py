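"""Expression-state calls: gene HIGH/LOW/UNDETERMINED labels per cell line,
and the derived partition of enzymatic reactions into R_H, R_L and
undetermined.

The reaction rule: a reaction is highly expressed (R_H) if at least one of
its genes is highly expressed; lowly expressed (R_L) only if *all* of its
observed genes are lowly expressed; otherwise undetermined.  Genes absent
from the expression table are ignored by the rule; a reaction whose genes are
all absent is undetermined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .metnet import MetabolicNetwork, enzymatic_subset

__all__ = [
    "HIGH",
    "LOW",
    "UNDETERMINED",
    "ExpressionMatrix",
    "GeneStateMatrix",
    "ReactionStateAssignment",
    "load_expression",
    "classify_genes",
    "reaction_states",
]

HIGH = "H"
LOW = "L"
UNDETERMINED = "U"


@dataclass
class ExpressionMatrix:
    """Gene × cell-line normalized expression values (no missing entries).

    Genes with any missing value are dropped at load time rather than
    imputed; reactions whose genes were all dropped end up undetermined.
    """

    gene_ids: list[str]
    cell_line_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_cell_lines)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_line_ids)):
            raise ValidationError("expression matrix shape does not match id lists")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_line_ids)) != len(self.cell_line_ids):
            raise ValidationError("duplicate cell line ids")
        if np.isnan(self.values).any():
            raise ValidationError("expression matrix contains missing values after load")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_line_ids)


@dataclass
class GeneStateMatrix:
    """H/L/U labels, same shape and id order as the source ExpressionMatrix."""

    gene_ids: list[str]
    cell_line_ids: list[str]
    states: np.ndarray  # dtype '<U1', shape (n_genes, n_cell_lines)

    def state_of(self, gene: str, cell_line: str) -> str:
        return str(
            self.states[self.gene_ids.index(gene), self.cell_line_ids.index(cell_line)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.states, index=self.gene_ids, columns=self.cell_line_ids)


@dataclass
class ReactionStateAssignment:
    """Disjoint partition of a network's enzymatic reactions for one cell line."""

    cell_line: str
    R_H: frozenset[str]
    R_L: frozenset[str]
    undetermined: frozenset[str]

    def __post_init__(self) -> None:
        self.R_H = frozenset(self.R_H)
        self.R_L = frozenset(self.R_L)
        self.undetermined = frozenset(self.undetermined)
        if (self.R_H & self.R_L) or (self.R_H & self.undetermined) or (
            self.R_L & self.undetermined
        ):
            raise ValidationError("R_H, R_L and undetermined must be disjoint")

    def state_of(self, rid: str) -> str:
        if rid in self.R_H:
            return HIGH
        if rid in self.R_L:
            return LOW
        if rid in self.undetermined:
            return UNDETERMINED
        raise KeyError(rid)


def load_expression(path: str | Path) -> ExpressionMatrix:
    """Read the expression TSV (first column gene id, then one column per
    cell line).  Genes with any missing value are dropped."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df = df.dropna(axis=0, how="any")
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        cell_line_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def classify_genes(
    expr: ExpressionMatrix,
    q_low: float = 0.25,
    q_high: float = 0.75,
    method: str = "quantile",
) -> GeneStateMatrix:
    """Label genes per cell line.

    With ``method="quantile"`` (default) the thresholds are the per-cell-line
    ``q_low`` / ``q_high`` quantiles of that cell line's values: strictly below
    the low threshold → LOW, strictly above the high threshold → HIGH, else
    UNDETERMINED.  With ``method="absolute"`` the two numbers are used as
    absolute expression cutoffs, identical in every cell line.

    The published analysis never states its thresholding; per-cell-line
    quartiles are this package's documented default.
    """
    if expr.values.size == 0:
        raise ValidationError("empty expression matrix")
    if not q_low < q_high:
        raise ValidationError(f"q_low ({q_low}) must be < q_high ({q_high})")
    if method == "quantile":
        lo = np.quantile(expr.values, q_low, axis=0)
        hi = np.quantile(expr.values, q_high, axis=0)
    elif method == "absolute":
        lo = np.full(len(expr.cell_line_ids), q_low)
        hi = np.full(len(expr.cell_line_ids), q_high)
    else:
        raise ValueError(f"unknown method {method!r}")
    states = np.full(expr.values.shape, UNDETERMINED, dtype="<U1")
    states[expr.values < lo] = LOW
    states[expr.values > hi] = HIGH
    return GeneStateMatrix(list(expr.gene_ids), list(expr.cell_line_ids), states)


def reaction_states(
    net: MetabolicNetwork, gene_states: GeneStateMatrix, cell_line: str
) -> ReactionStateAssignment:
    """Partition the enzymatic reactions of ``net`` for one cell line.

    HIGH if ≥1 observed gene is HIGH; LOW if all observed genes are LOW;
    otherwise (any mix involving UNDETERMINED, or no observed genes)
    UNDETERMINED.
    """
    if cell_line not in gene_states.cell_line_ids:
        raise ValidationError(f"unknown cell line {cell_line!r}")
    col = gene_states.cell_line_ids.index(cell_line)
    gene_index = {g: i for i, g in enumerate(gene_states.gene_ids)}
    r_h, r_l, und = set(), set(), set()
    for rid in enzymatic_subset(net):
        observed = [
            gene_states.states[gene_index[g], col]
            for g in net.reaction(rid).genes
            if g in gene_index
        ]
        if any(s == HIGH for s in observed):
            r_h.add(rid)
        elif observed and all(s == LOW for s in observed):
            r_l.add(rid)
        else:
            und.add(rid)
    return ReactionStateAssignment(cell_line, frozenset(r_h), frozenset(r_l), frozenset(und))


def export_gene_states(states: GeneStateMatrix, path: str | Path) -> None:
    """Audit TSV of H/L/U labels."""
    states.to_frame().to_csv(path, sep="\t", index_label="gene_id")
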