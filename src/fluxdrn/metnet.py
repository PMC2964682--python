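"""Metabolic network data model and I/O.

A :class:`MetabolicNetwork` holds an ordered list of metabolites, an ordered
list of reactions and the stoichiometric matrix ``S`` (one row per metabolite,
one column per reaction).  Gene-protein-reaction associations are stored flat:
each reaction carries a set of gene ids and a set of enzyme (protein) ids, the
set of target enzymes of the reaction.  Boolean AND/OR structure of gene rules
is intentionally not modelled — every downstream rule only quantifies over the
gene set ("at least one gene high", "all genes low").

Two on-disk dialects are supported:

* a single JSON file with top-level keys ``metabolites`` and ``reactions``
  (each reaction maps metabolite ids to stoichiometric coefficients), and
* a TSV triple ``metabolites.tsv`` / ``reactions.tsv`` / ``stoichiometry.tsv``
  in one directory.

All files refer to entities by id only, never by index.  Exchange/boundary
reactions are ordinary (possibly single-entry) columns of ``S``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "load_network",
    "save_network",
    "enzymatic_subset",
]


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass
class Reaction:
    """A metabolic reaction with flux bounds and gene/enzyme associations.

    ``enzymes`` is the set of target enzymes (proteins) catalyzing the
    reaction; ``genes`` the set of genes encoding them.  Both may be empty
    (non-enzymatic reaction, e.g. spontaneous or exchange).  Bounds are in
    arbitrary flux units (conventionally mmol·gDW⁻¹·h⁻¹).
    """

    id: str
    name: str = ""
    subsystem: str = ""
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    genes: frozenset[str] = field(default_factory=frozenset)
    enzymes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        self.enzymes = frozenset(self.enzymes)
        if not math.isfinite(self.lower_bound) or not math.isfinite(self.upper_bound):
            raise ValidationError(f"reaction {self.id!r}: bounds must be finite")
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )


class MetabolicNetwork:
    """Stoichiometric model: metabolites × reactions matrix plus annotations.

    Parameters
    ----------
    metabolites, reactions:
        Ordered entity lists; ids must be unique within each list.
    stoichiometry:
        Mapping ``reaction id -> {metabolite id: coefficient}``.  Negative
        coefficients consume, positive produce.
    """

    def __init__(
        self,
        metabolites: list[Metabolite],
        reactions: list[Reaction],
        stoichiometry: dict[str, dict[str, float]],
    ) -> None:
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        met_ids = [m.id for m in self.metabolites]
        rxn_ids = [r.id for r in self.reactions]
        for label, ids in (("metabolite", met_ids), ("reaction", rxn_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise SchemaError(f"duplicate {label} id {i!r}")
                seen.add(i)
        self.metabolite_index = {m: i for i, m in enumerate(met_ids)}
        self.reaction_index = {r: j for j, r in enumerate(rxn_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for rid, row in stoichiometry.items():
            if rid not in self.reaction_index:
                raise ValidationError(f"stoichiometry references unknown reaction {rid!r}")
            for mid, coef in row.items():
                if mid not in self.metabolite_index:
                    raise ValidationError(
                        f"reaction {rid!r} references unknown metabolite {mid!r}"
                    )
                S[self.metabolite_index[mid], self.reaction_index[rid]] = float(coef)
        self.S = S

    # -- convenience accessors -------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self.reaction_index[rid]]

    def stoichiometry_of(self, rid: str) -> dict[str, float]:
        col = self.S[:, self.reaction_index[rid]]
        return {
            self.metabolites[i].id: float(col[i]) for i in np.nonzero(col)[0]
        }

    def lower_bounds(self) -> np.ndarray:
        return np.array([r.lower_bound for r in self.reactions])

    def upper_bounds(self) -> np.ndarray:
        return np.array([r.upper_bound for r in self.reactions])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MetabolicNetwork({len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions)"
        )


def enzymatic_subset(net: MetabolicNetwork) -> list[str]:
    """Reaction ids with a non-empty gene set, in network order.

    These are the enzymatic reactions — the only ones that can interact with
    drugs through enzyme targets and the only ones the expression-state rule
    applies to.
    """
    return [r.id for r in net.reactions if r.genes]


# -- I/O ----------------------------------------------------------------------

def _network_from_records(
    met_records: list[dict], rxn_records: list[dict], stoich: dict[str, dict[str, float]]
) -> MetabolicNetwork:
    metabolites = [
        Metabolite(
            id=str(m["id"]),
            name=str(m.get("name", "")),
            compartment=str(m.get("compartment", "")),
        )
        for m in met_records
    ]
    reactions = []
    for r in rxn_records:
        try:
            reactions.append(
                Reaction(
                    id=str(r["id"]),
                    name=str(r.get("name", "")),
                    subsystem=str(r.get("subsystem", "")),
                    lower_bound=float(r["lower_bound"]),
                    upper_bound=float(r["upper_bound"]),
                    genes=frozenset(map(str, r.get("genes", []))),
                    enzymes=frozenset(map(str, r.get("enzymes", []))),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"reaction record missing field {exc}") from exc
    return MetabolicNetwork(metabolites, reactions, stoich)


def load_network(path: str | Path, dialect: str | None = None) -> MetabolicNetwork:
    """Load a network from the JSON dialect or the three-file TSV dialect.

    ``dialect`` is ``"json"`` or ``"tsv"``; when omitted it is inferred (a
    directory or a ``.tsv`` path means TSV, otherwise JSON).
    """
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.is_dir() or path.suffix == ".tsv" else "json"
    if dialect == "json":
        with open(path) as fh:
            doc = json.load(fh)
        if not isinstance(doc, dict) or "metabolites" not in doc or "reactions" not in doc:
            raise SchemaError(f"{path}: expected top-level 'metabolites' and 'reactions'")
        stoich = {
            str(r["id"]): {str(k): float(v) for k, v in r.get("metabolites", {}).items()}
            for r in doc["reactions"]
            if "id" in r
        }
        return _network_from_records(doc["metabolites"], doc["reactions"], stoich)
    if dialect == "tsv":
        d = path if path.is_dir() else path.parent
        mets = pd.read_csv(d / "metabolites.tsv", sep="\t", dtype=str).fillna("")
        rxns = pd.read_csv(d / "reactions.tsv", sep="\t", dtype=str).fillna("")
        st = pd.read_csv(d / "stoichiometry.tsv", sep="\t", dtype=str)
        rxn_records = []
        for rec in rxns.to_dict("records"):
            rec["genes"] = [g for g in str(rec.get("genes", "")).split(";") if g]
            rec["enzymes"] = [e for e in str(rec.get("enzymes", "")).split(";") if e]
            rxn_records.append(rec)
        stoich: dict[str, dict[str, float]] = {}
        for _, row in st.iterrows():
            stoich.setdefault(str(row["reaction_id"]), {})[str(row["metabolite_id"])] = float(
                row["coefficient"]
            )
        return _network_from_records(mets.to_dict("records"), rxn_records, stoich)
    raise ValueError(f"unknown dialect {dialect!r}")


def save_network(net: MetabolicNetwork, path: str | Path) -> None:
    """Write the JSON dialect; round-trips bounds, genes, enzymes and S exactly."""
    doc = {
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in net.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "subsystem": r.subsystem,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "genes": sorted(r.genes),
                "enzymes": sorted(r.enzymes),
                "metabolites": net.stoichiometry_of(r.id),
            }
            for r in net.reactions
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
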