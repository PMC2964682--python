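"""Reaction structure similarity from enzyme target sequences.

Two reactions are structurally similar when their catalyzing enzymes have
similar protein sequences.  The chain is: Smith-Waterman local alignment
score between two enzyme sequences → normalized target-sequence similarity
s_TS ∈ [0, 1] → reaction structure similarity s_RS, the max / average / min of
all cross-pair s_TS values between the two reactions' enzyme sets → the
integrated reaction similarity s_R = λ·s_RF + (1 − λ)·s_RS.

Alignment is delegated to :class:`Bio.Align.PairwiseAligner` in local mode.
Defaults are BLOSUM62 with affine gap penalties (open 10, extend 1); a simple
match/mismatch mode exists so scores stay hand-checkable in tests.  The
normalization is by the geometric mean of the two self-alignment scores,
which is symmetric, scale-free and exactly 1 on identical sequences.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import ValidationError
from .metnet import MetabolicNetwork
from .profiles import SimilarityMatrix

__all__ = [
    "AMINO_ACIDS",
    "ProteinSequence",
    "AlignmentParams",
    "read_fasta",
    "smith_waterman_score",
    "normalized_ts",
    "pairwise_ts",
    "reaction_structure_similarity",
    "structure_similarity_matrix",
    "integrate_similarity",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinSequence:
    """A protein id and its residue string (standard 20-letter alphabet)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"protein {self.id!r}: empty sequence")
        bad = set(self.residues.upper()) - AMINO_ACIDS
        if bad:
            raise ValidationError(
                f"protein {self.id!r}: invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignmentParams:
    """Smith-Waterman scoring configuration.

    ``matrix`` names a biopython substitution matrix ("BLOSUM62", "PAM250"…)
    or the special value ``"simple"``, which scores ``match``/``mismatch``
    per residue pair.  Gap penalties are non-negative magnitudes (affine:
    opening a gap costs ``gap_open``, each further position ``gap_extend``;
    equal values give a linear gap penalty).
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    match: float = 2.0
    mismatch: float = -1.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValidationError("gap penalties must be non-negative")


def _aligner(params: AlignmentParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    if params.matrix == "simple":
        aligner.match_score = params.match
        aligner.mismatch_score = params.mismatch
    else:
        aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -float(params.gap_open)
    aligner.extend_gap_score = -float(params.gap_extend)
    return aligner


def read_fasta(path: str | Path) -> dict[str, ProteinSequence]:
    """Load protein sequences from FASTA, keyed by record id."""
    seqs: dict[str, ProteinSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = ProteinSequence(rec.id, str(rec.seq).upper())
    return seqs


def smith_waterman_score(
    s: ProteinSequence, t: ProteinSequence, params: AlignmentParams | None = None
) -> float:
    """Optimal local-alignment score of two sequences (≥ 0, symmetric)."""
    params = params or AlignmentParams()
    score = float(_aligner(params).score(s.residues.upper(), t.residues.upper()))
    return max(score, 0.0)


def normalized_ts(
    s: ProteinSequence, t: ProteinSequence, params: AlignmentParams | None = None
) -> float:
    """Target-sequence similarity s_TS ∈ [0, 1].

    s_TS(s, t) = SW(s, t) / sqrt(SW(s, s) · SW(t, t)).  Self-similarity is 1
    by construction.  A sequence whose self-alignment scores 0 cannot be
    normalized and is an error (cannot happen under BLOSUM62, whose diagonal
    is positive).
    """
    params = params or AlignmentParams()
    self_s = smith_waterman_score(s, s, params)
    self_t = smith_waterman_score(t, t, params)
    if self_s <= 0 or self_t <= 0:
        raise ValidationError(
            "zero self-alignment score; s_TS undefined under this scoring scheme"
        )
    return smith_waterman_score(s, t, params) / float(np.sqrt(self_s * self_t))


def pairwise_ts(
    sequences: dict[str, ProteinSequence], params: AlignmentParams | None = None
) -> dict[frozenset[str], float]:
    """All-pairs s_TS cache (self pairs included), keyed by unordered id pair."""
    params = params or AlignmentParams()
    ids = sorted(sequences)
    cache: dict[frozenset[str], float] = {}
    for a in ids:
        cache[frozenset([a])] = 1.0
    for a, b in itertools.combinations(ids, 2):
        cache[frozenset([a, b])] = normalized_ts(sequences[a], sequences[b], params)
    return cache


def _ts_lookup(ts: dict[frozenset[str], float], a: str, b: str) -> float:
    key = frozenset([a, b])
    if key not in ts:
        raise ValidationError(f"missing s_TS value for pair ({a!r}, {b!r})")
    return ts[key]


def reaction_structure_similarity(
    M_i: frozenset[str] | set[str],
    M_j: frozenset[str] | set[str],
    ts: dict[frozenset[str], float],
    mode: str = "max",
) -> float:
    """Aggregate enzyme-pair sequence similarities between two reactions.

    ``mode`` selects max (default — it performs best for prediction), avg or
    min over {s_TS(s, t) : s ∈ M_i, t ∈ M_j}.  Non-enzymatic reactions (empty
    enzyme set) have no structure similarity and are an error.
    """
    if not M_i or not M_j:
        raise ValidationError("reaction structure similarity needs non-empty enzyme sets")
    vals = [_ts_lookup(ts, a, b) for a in sorted(M_i) for b in sorted(M_j)]
    if mode == "max":
        return max(vals)
    if mode == "avg":
        return float(np.mean(vals))
    if mode == "min":
        return min(vals)
    raise ValueError(f"unknown mode {mode!r}")


def structure_similarity_matrix(
    net: MetabolicNetwork,
    reaction_ids: list[str],
    ts: dict[frozenset[str], float],
    mode: str = "max",
) -> SimilarityMatrix:
    """s_RS over a reaction list, as a :class:`SimilarityMatrix`."""
    enzyme_sets = [net.reaction(rid).enzymes for rid in reaction_ids]
    n = len(reaction_ids)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            vals[i, j] = vals[j, i] = reaction_structure_similarity(
                enzyme_sets[i], enzyme_sets[j], ts, mode
            )
    return SimilarityMatrix(list(reaction_ids), vals, f"structure_{mode}")


def integrate_similarity(
    s_rf: SimilarityMatrix, s_rs: SimilarityMatrix, lam: float
) -> SimilarityMatrix:
    """Integrated reaction similarity s_R = λ·s_RF + (1 − λ)·s_RS.

    λ weights the flux (functional) component; λ = 1 returns s_RF exactly and
    λ = 0 returns s_RS exactly.  The two matrices must share id list and
    order.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValidationError(f"lambda must lie in [0, 1], got {lam}")
    if s_rf.ids != s_rs.ids:
        raise ValidationError("similarity matrices have mismatched id lists")
    return SimilarityMatrix(
        list(s_rf.ids), lam * s_rf.values + (1.0 - lam) * s_rs.values, "integrated"
    )


def write_ts_cache(ts: dict[frozenset[str], float], path: str | Path) -> None:
    rows = []
    for key, val in sorted(ts.items(), key=lambda kv: sorted(kv[0])):
        pair = sorted(key)
        a = pair[0]
        b = pair[-1]
        rows.append({"protein_a": a, "protein_b": b, "similarity": val})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ts_cache(path: str | Path) -> dict[frozenset[str], float]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
    return {
        frozenset([r.protein_a, r.protein_b]): float(r.similarity)
        for r in df.itertuples()
    }
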