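"""Bipartite Drug-Reaction Network (DRN) and its descriptive statistics.

A drug interacts with a reaction when at least one of the drug's target
proteins catalyzes the reaction as an enzyme; the intersection of the drug's
target set with the reaction's enzyme set is the edge's *witness* set.  Drugs
and reactions without any edge are not part of the network.

On top of the network sit the pair statistics used to judge similarity
metrics: Γ_RDR (reaction pairs sharing ≥1 drug), Γ_RER (pairs sharing ≥1
enzyme), the β statistic — the fraction of drug-sharing pairs that also share
an enzyme — and the conditional probabilities P_D(t) / P_E(t) that a pair
shares drugs / enzymes given its similarity exceeds t.  Every cutoff is
strict (> t), and pairs are unordered with distinct members.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import UndefinedStatisticError, ValidationError
from .metnet import MetabolicNetwork
from .profiles import SimilarityMatrix

__all__ = [
    "DrugTargetMap",
    "PairSets",
    "load_drug_targets",
    "build_drn",
    "drug_nodes",
    "reaction_nodes",
    "degree_histogram",
    "shared_pair_sets",
    "beta_statistic",
    "conditional_probability",
    "statistic_curves",
    "write_sif",
    "write_graphml",
]

Pair = tuple[str, str]


def _pair(a: str, b: str) -> Pair:
    """Canonical unordered pair: lexicographically smaller id first."""
    if a == b:
        raise ValidationError("pair members must be distinct")
    return (a, b) if a < b else (b, a)


@dataclass
class DrugTargetMap:
    """drug id → non-empty set of target protein ids, with optional metadata."""

    targets: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)
    atc_classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.targets = {d: frozenset(t) for d, t in self.targets.items()}
        empty = [d for d, t in self.targets.items() if not t]
        if empty:
            raise ValidationError(f"drugs with empty target sets: {empty}")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.targets)


@dataclass(frozen=True)
class PairSets:
    """Γ_RDR and Γ_RER: unordered reaction pairs sharing drugs / enzymes."""

    gamma_rdr: frozenset[Pair]
    gamma_rer: frozenset[Pair]


def load_drug_targets(path: str | Path) -> DrugTargetMap:
    """Read the drug-target TSV (drug_id, drug_name, atc_class, target_protein_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    targets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    atc: dict[str, str] = {}
    for row in df.itertuples():
        targets.setdefault(row.drug_id, set()).add(row.target_protein_id)
        if getattr(row, "drug_name", ""):
            names[row.drug_id] = row.drug_name
        if getattr(row, "atc_class", ""):
            atc[row.drug_id] = row.atc_class
    return DrugTargetMap(
        {d: frozenset(t) for d, t in targets.items()}, names=names, atc_classes=atc
    )


def build_drn(drugs: DrugTargetMap, net: MetabolicNetwork) -> nx.Graph:
    """Construct the bipartite DRN as a networkx graph.

    Nodes carry ``type`` ("drug" / "reaction") plus ATC class or subsystem
    labels; each edge carries its sorted ``witness`` enzyme list.  Drugs whose
    targets catalyze no reaction, and reactions targeted by no drug, are
    omitted entirely.
    """
    g = nx.Graph()
    for drug_id, target_set in drugs.targets.items():
        for rxn in net.reactions:
            witness = target_set & rxn.enzymes
            if not witness:
                continue
            if drug_id not in g:
                g.add_node(
                    drug_id,
                    type="drug",
                    bipartite=0,
                    name=drugs.names.get(drug_id, ""),
                    atc_class=drugs.atc_classes.get(drug_id, ""),
                )
            if rxn.id not in g:
                g.add_node(rxn.id, type="reaction", bipartite=1, subsystem=rxn.subsystem)
            g.add_edge(drug_id, rxn.id, witness=sorted(witness))
    return g


def drug_nodes(drn: nx.Graph) -> list[str]:
    return sorted(n for n, d in drn.nodes(data=True) if d["type"] == "drug")


def reaction_nodes(drn: nx.Graph) -> list[str]:
    return sorted(n for n, d in drn.nodes(data=True) if d["type"] == "reaction")


def degree_histogram(drn: nx.Graph, max_degree: int = 20) -> pd.DataFrame:
    """Node counts per degree 1..max_degree for all nodes / drugs / reactions.

    Degrees above ``max_degree`` land in an overflow row (degree column
    ``>max_degree``); the column sums therefore equal the node counts.
    """
    if max_degree < 1:
        raise ValidationError("max_degree must be ≥ 1")
    rows = {str(d): {"all": 0, "drugs": 0, "reactions": 0} for d in range(1, max_degree + 1)}
    rows[f">{max_degree}"] = {"all": 0, "drugs": 0, "reactions": 0}
    for node, data in drn.nodes(data=True):
        deg = drn.degree(node)
        key = str(deg) if deg <= max_degree else f">{max_degree}"
        rows[key]["all"] += 1
        rows[key]["drugs" if data["type"] == "drug" else "reactions"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "degree"
    return df


def shared_pair_sets(
    drn: nx.Graph, net: MetabolicNetwork, reactions: set[str] | list[str]
) -> PairSets:
    """Γ_RDR / Γ_RER over the given reaction set.

    A pair enters Γ_RDR when the two reactions have a common adjacent drug in
    the DRN, and Γ_RER when their enzyme sets intersect — a pair can be in
    either, both or neither (same drug via different enzymes is Γ_RDR only).
    """
    reactions = sorted(set(reactions))
    adj_drugs = {
        r: set(drn.neighbors(r)) if r in drn else set() for r in reactions
    }
    rdr, rer = set(), set()
    for a, b in itertools.combinations(reactions, 2):
        if adj_drugs[a] & adj_drugs[b]:
            rdr.add(_pair(a, b))
        if net.reaction(a).enzymes & net.reaction(b).enzymes:
            rer.add(_pair(a, b))
    return PairSets(frozenset(rdr), frozenset(rer))


def _surviving(pairs: frozenset[Pair], sim: SimilarityMatrix, t: float) -> set[Pair]:
    index = {rid: i for i, rid in enumerate(sim.ids)}
    out = set()
    for a, b in pairs:
        if a not in index or b not in index:
            raise ValidationError(f"similarity matrix does not cover pair ({a!r}, {b!r})")
        if sim.values[index[a], index[b]] > t:
            out.add((a, b))
    return out


def beta_statistic(
    pairs: PairSets, sim: SimilarityMatrix | None = None, t: float | None = None
) -> float:
    """Fraction of drug-sharing reaction pairs that also share an enzyme.

    With a similarity cutoff, both counts are restricted to pairs with
    similarity strictly above t:

        β(t) = |{p ∈ Γ_RER ∩ Γ_RDR : s(p) > t}| / |{p ∈ Γ_RDR : s(p) > t}|

    Without a cutoff it is the plain ratio |Γ_RER ∩ Γ_RDR| / |Γ_RDR|.  An
    empty denominator raises :class:`UndefinedStatisticError` rather than
    returning 0.
    """
    if t is None:
        denom_pairs = pairs.gamma_rdr
        numer_pairs = pairs.gamma_rdr & pairs.gamma_rer
    else:
        if sim is None:
            raise ValidationError("a similarity matrix is required when t is given")
        denom_pairs = frozenset(_surviving(pairs.gamma_rdr, sim, t))
        numer_pairs = frozenset(
            _surviving(pairs.gamma_rdr & pairs.gamma_rer, sim, t)
        )
    if not denom_pairs:
        raise UndefinedStatisticError(
            "beta undefined: no drug-sharing pairs above the cutoff"
        )
    return len(numer_pairs) / len(denom_pairs)


def conditional_probability(
    gamma: frozenset[Pair] | set[Pair],
    sim: SimilarityMatrix,
    t: float,
    universe: frozenset[Pair] | set[Pair],
) -> float:
    """P(t) = |{p ∈ γ : s(p) > t}| / |{p ∈ universe : s(p) > t}|.

    With γ = Γ_RDR this is P_D(t); with γ = Γ_RER it is P_E(t).  Pairs with
    similarity exactly t are excluded from both counts (strict inequality).
    """
    universe = frozenset(_pair(a, b) for a, b in universe)
    gamma = frozenset(_pair(a, b) for a, b in gamma)
    if not gamma <= universe:
        raise ValidationError("gamma must be a subset of the pair universe")
    denom = _surviving(universe, sim, t)
    if not denom:
        raise UndefinedStatisticError(
            f"conditional probability undefined: no pairs with similarity > {t}"
        )
    return len(frozenset(gamma) & denom) / len(denom)


def all_pairs(reaction_ids: list[str]) -> frozenset[Pair]:
    """Universe of unordered distinct pairs over a reaction list."""
    return frozenset(_pair(a, b) for a, b in itertools.combinations(sorted(set(reaction_ids)), 2))


def statistic_curves(
    pairs: PairSets,
    sim: SimilarityMatrix,
    cutoffs: list[float],
    universe: frozenset[Pair] | None = None,
) -> pd.DataFrame:
    """β(t), P_D(t) and P_E(t) over a cutoff grid; NaN where undefined."""
    universe = all_pairs(sim.ids) if universe is None else universe
    rows = []
    for t in cutoffs:
        row = {"t": t, "beta": float("nan"), "P_D": float("nan"), "P_E": float("nan")}
        try:
            row["beta"] = beta_statistic(pairs, sim, t)
        except UndefinedStatisticError:
            pass
        try:
            row["P_D"] = conditional_probability(pairs.gamma_rdr, sim, t, universe)
            row["P_E"] = conditional_probability(pairs.gamma_rer, sim, t, universe)
        except UndefinedStatisticError:
            pass
        rows.append(row)
    return pd.DataFrame(rows)


def write_sif(drn: nx.Graph, path: str | Path) -> None:
    """SIF export: `drug  targets_reaction  reaction` per edge."""
    with open(path, "w") as fh:
        for a, b, _ in sorted(drn.edges(data=True)):
            drug, rxn = (a, b) if drn.nodes[a]["type"] == "drug" else (b, a)
            fh.write(f"{drug}\ttargets_reaction\t{rxn}\n")


def write_graphml(drn: nx.Graph, path: str | Path) -> None:
    g = drn.copy()
    for _, _, data in g.edges(data=True):
        data["witness"] = ";".join(data["witness"])
    nx.write_graphml(g, str(path))
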