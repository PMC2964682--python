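"""Reaction flux profiles and cosine flux similarity.

A reaction's profile is its vector of predicted fluxes across the cell-line
panel; reactions inactive in every cell line (|flux| < ε throughout) carry no
signal and are filtered out before similarity is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .flux_lp import FluxSolution

__all__ = [
    "FluxProfileMatrix",
    "SimilarityMatrix",
    "assemble_profiles",
    "filter_active",
    "flux_similarity",
]

_SIM_KINDS = {"flux", "structure_max", "structure_avg", "structure_min", "integrated"}


@dataclass
class FluxProfileMatrix:
    """Reactions × cell-lines flux values; row i is reaction i's profile."""

    reaction_ids: list[str]
    cell_line_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.reaction_ids), len(self.cell_line_ids)):
            raise ValidationError("profile matrix shape does not match id lists")

    def profile(self, rid: str) -> np.ndarray:
        return self.values[self.reaction_ids.index(rid)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.reaction_ids, columns=self.cell_line_ids
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="reaction_id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FluxProfileMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            [str(i) for i in df.index], [str(c) for c in df.columns], df.to_numpy(float)
        )


@dataclass
class SimilarityMatrix:
    """Symmetric reaction × reaction similarity scores.

    ``kind`` records the provenance: cosine flux similarity, one of the three
    sequence-aggregation structure similarities, or their λ-weighted
    integration.
    """

    ids: list[str]
    values: np.ndarray
    kind: str = "flux"

    def __post_init__(self) -> None:
        if self.kind not in _SIM_KINDS:
            raise ValidationError(f"unknown similarity kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError("similarity matrix must be square over its ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("similarity matrix must be symmetric")

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def subset(self, ids: list[str]) -> "SimilarityMatrix":
        idx = [self.ids.index(i) for i in ids]
        return SimilarityMatrix(list(ids), self.values[np.ix_(idx, idx)], self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="reaction_id")

    @classmethod
    def read_tsv(cls, path: str | Path, kind: str = "flux") -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(i) for i in df.index], df.to_numpy(float), kind)


def assemble_profiles(
    solutions: list[tuple[str, FluxSolution]], reaction_ids: list[str]
) -> FluxProfileMatrix:
    """Stack per-cell-line optimal fluxes into a profile matrix.

    ``f[i, j]`` is reaction i's flux in cell line j, columns in the given
    cell-line order.  Every requested reaction must be present in every
    solution; duplicate cell-line ids are rejected.
    """
    cell_lines = [cl for cl, _ in solutions]
    if len(set(cell_lines)) != len(cell_lines):
        raise ValidationError("duplicate cell line id in solutions")
    cols = []
    for cl, sol in solutions:
        index = {rid: i for i, rid in enumerate(sol.reaction_ids)}
        missing = [rid for rid in reaction_ids if rid not in index]
        if missing:
            raise ValidationError(
                f"cell line {cl!r} solution missing reactions {missing}"
            )
        cols.append([sol.v[index[rid]] for rid in reaction_ids])
    values = np.array(cols, dtype=float).T if cols else np.empty((len(reaction_ids), 0))
    return FluxProfileMatrix(list(reaction_ids), cell_lines, values)


def filter_active(F: FluxProfileMatrix, epsilon: float) -> FluxProfileMatrix:
    """Keep reactions active (|flux| ≥ ε) in at least one cell line.

    Mirrors the removal of always-inactive reactions before similarity:
    a profile entirely inside the open band (−ε, ε) is dropped.  Row order is
    preserved; an empty result is allowed.
    """
    if epsilon <= 0:
        raise ValidationError(f"epsilon must be > 0, got {epsilon}")
    keep = np.max(np.abs(F.values), axis=1) >= epsilon if F.values.size else np.zeros(
        len(F.reaction_ids), dtype=bool
    )
    ids = [rid for rid, k in zip(F.reaction_ids, keep) if k]
    return FluxProfileMatrix(ids, list(F.cell_line_ids), F.values[keep])


def flux_similarity(F: FluxProfileMatrix) -> SimilarityMatrix:
    """Cosine similarity between reaction flux profiles.

    s_RF(i, j) = f_i · f_j / (‖f_i‖ ‖f_j‖) ∈ [−1, 1], unit diagonal.  A
    zero-norm profile has no direction; call :func:`filter_active` first.
    """
    norms = np.linalg.norm(F.values, axis=1)
    if np.any(norms == 0):
        bad = [rid for rid, nn in zip(F.reaction_ids, norms) if nn == 0]
        raise ValidationError(
            f"zero-norm flux profile(s) {bad}; apply filter_active before flux_similarity"
        )
    unit = F.values / norms[:, None]
    sims = np.clip(unit @ unit.T, -1.0, 1.0)
    sims = (sims + sims.T) / 2.0
    np.fill_diagonal(sims, 1.0)
    return SimilarityMatrix(list(F.reaction_ids), sims, "flux")
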