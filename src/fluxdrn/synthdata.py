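"""Self-contained toy instance generator.

Emulates, at desk scale, the four inputs of the real study — a metabolic
network (stoichiometry + gene/enzyme associations), a gene × cell-line
expression table, a drug → target map, and enzyme protein sequences — with a
single latent *module* grouping driving all of them:

* the network is a set of independent linear pathways ("modules"), each with
  inflow/outflow exchange reactions so each module supports a nonzero
  steady-state flux; every interior reaction carries exactly one synthetic
  gene and one synthetic enzyme;
* each module is "on" in a random subset of cell lines; genes of on-modules
  draw high expression, off-modules low, so same-module genes are correlated
  across the panel;
* each drug homes on one module and targets that module's enzymes (with
  probability ``p_within`` per reaction, otherwise a random outside enzyme);
* enzyme sequences form one family per module (point-mutated copies of a
  random ancestor).

Because flux similarity, enzyme sharing and drug sharing are all induced by
the same grouping, the generated data reproduces qualitatively the empirical
relationship the pipeline exploits: reaction pairs with higher similarity are
more likely to share drugs and enzymes.  Every operation is deterministic in
the master seed, with independent per-operation substreams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .drn import DrugTargetMap
from .errors import ValidationError
from .expr_states import ExpressionMatrix
from .metnet import MetabolicNetwork, Metabolite, Reaction, save_network
from .predict import InteractionMatrix
from .struct_sim import ProteinSequence

__all__ = [
    "SynthConfig",
    "make_toy_network",
    "module_activity_pattern",
    "simulate_expression",
    "plant_interactions",
    "make_sequence_families",
    "write_instance",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"

# substream tags keep the generators independent of each other
_STREAM_EXPR = 1
_STREAM_DRUGS = 2
_STREAM_SEQS = 3
_STREAM_NOISE = 4


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the toy instance.

    Defaults: 4 pathway modules of 5 reactions profiled over 20 cell lines
    with 8 drugs at ``p_within`` = 0.9.  Expression levels are on a
    log2-microarray-like scale (high 8, low 2, sd 0.8).  Sequences are 150
    residues with a 5% per-residue substitution rate within a family.
    """

    n_modules: int = 4
    reactions_per_module: int = 5
    n_cell_lines: int = 20
    n_drugs: int = 8
    expression_noise: float = 0.8
    high_level: float = 8.0
    low_level: float = 2.0
    p_within: float = 0.9
    seq_mutation_rate: float = 0.05
    seq_length: int = 150
    flux_bound: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_modules, self.reactions_per_module, self.n_cell_lines,
               self.n_drugs, self.seq_length) < 1:
            raise ValidationError("all counts must be ≥ 1")
        if not 0.0 <= self.p_within <= 1.0 or not 0.0 <= self.seq_mutation_rate <= 1.0:
            raise ValidationError("probabilities must lie in [0, 1]")
        if self.expression_noise < 0:
            raise ValidationError("expression noise must be ≥ 0")


def _rng(cfg: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def _module_reactions(cfg: SynthConfig) -> dict[int, list[str]]:
    """module index -> interior reaction ids, in network order."""
    return {
        m: [f"r_M{m + 1}_{k + 1}" for k in range(cfg.reactions_per_module)]
        for m in range(cfg.n_modules)
    }


def _enzyme_of(rid: str) -> str:
    return "E_" + rid[2:]


def _gene_of(rid: str) -> str:
    return "G_" + rid[2:]


def make_toy_network(cfg: SynthConfig) -> MetabolicNetwork:
    """Linear-pathway modules with exchange inflow/outflow.

    Module m is the chain  EX_M{m}_in → r_M{m}_1 → … → r_M{m}_R → EX_M{m}_out
    over metabolites A_M{m}_0 … A_M{m}_R; all bounds [0, flux_bound].  Each
    interior reaction gets one gene G_… and one enzyme E_…; exchanges are
    non-enzymatic.  Deterministic — the topology depends only on the counts.
    """
    metabolites, reactions, stoich = [], [], {}
    for m in range(cfg.n_modules):
        tag = f"M{m + 1}"
        mets = [f"A_{tag}_{k}" for k in range(cfg.reactions_per_module + 1)]
        metabolites.extend(Metabolite(mid, compartment="c") for mid in mets)
        ex_in = f"EX_{tag}_in"
        reactions.append(
            Reaction(ex_in, name=f"{tag} inflow", subsystem="Exchange",
                     lower_bound=0.0, upper_bound=cfg.flux_bound)
        )
        stoich[ex_in] = {mets[0]: 1.0}
        for k, rid in enumerate(_module_reactions(cfg)[m]):
            reactions.append(
                Reaction(
                    rid,
                    name=f"{tag} step {k + 1}",
                    subsystem=f"Module {tag}",
                    lower_bound=0.0,
                    upper_bound=cfg.flux_bound,
                    genes=frozenset([_gene_of(rid)]),
                    enzymes=frozenset([_enzyme_of(rid)]),
                )
            )
            stoich[rid] = {mets[k]: -1.0, mets[k + 1]: 1.0}
        ex_out = f"EX_{tag}_out"
        reactions.append(
            Reaction(ex_out, name=f"{tag} outflow", subsystem="Exchange",
                     lower_bound=0.0, upper_bound=cfg.flux_bound)
        )
        stoich[ex_out] = {mets[-1]: -1.0}
    return MetabolicNetwork(metabolites, reactions, stoich)


def module_activity_pattern(cfg: SynthConfig) -> np.ndarray:
    """Planted module × cell-line on/off pattern (boolean).

    Bernoulli(0.5) per entry, then adjusted so every module is on in at least
    one cell line and (when the panel has ≥ 2 cell lines) off in at least
    one — an always-off module would leave its reactions inactive everywhere
    and carry no profile signal.
    """
    rng = _rng(cfg, _STREAM_EXPR)
    pattern = rng.random((cfg.n_modules, cfg.n_cell_lines)) < 0.5
    for m in range(cfg.n_modules):
        if not pattern[m].any():
            pattern[m, rng.integers(cfg.n_cell_lines)] = True
        if pattern[m].all() and cfg.n_cell_lines > 1:
            pattern[m, rng.integers(cfg.n_cell_lines)] = False
    return pattern


def simulate_expression(net: MetabolicNetwork, cfg: SynthConfig) -> ExpressionMatrix:
    """Gene × cell-line expression from the planted on/off pattern.

    On-module genes draw Normal(high_level, noise), off-module genes
    Normal(low_level, noise); the pattern itself comes from
    :func:`module_activity_pattern` on the same seed, so the two stay
    consistent.
    """
    pattern = module_activity_pattern(cfg)
    rng = _rng(cfg, _STREAM_NOISE)
    gene_ids, rows = [], []
    for m, rids in _module_reactions(cfg).items():
        means = np.where(pattern[m], cfg.high_level, cfg.low_level)
        for rid in rids:
            gene_ids.append(_gene_of(rid))
            rows.append(means + rng.normal(0.0, cfg.expression_noise, cfg.n_cell_lines))
    cell_lines = [f"CL{j + 1:02d}" for j in range(cfg.n_cell_lines)]
    return ExpressionMatrix(gene_ids, cell_lines, np.array(rows))


def plant_interactions(
    net: MetabolicNetwork, cfg: SynthConfig
) -> tuple[DrugTargetMap, InteractionMatrix]:
    """Drug → target map planted on the module structure, plus ground truth.

    Drugs home on modules round-robin (drug i → module i mod n_modules), so
    every module is covered.  For each reaction of the home module the drug
    targets its enzyme with probability ``p_within``; otherwise it targets a
    uniformly random enzyme outside the module.  A drug left with no targets
    by the coin flips falls back to one random home-module enzyme (target
    sets must be non-empty).  The returned interaction matrix is exactly the
    drug-reaction network the map induces over the enzymatic reactions.
    """
    rng = _rng(cfg, _STREAM_DRUGS)
    modrxns = _module_reactions(cfg)
    outside = {
        m: sorted(
            _enzyme_of(rid)
            for mm, rids in modrxns.items() if mm != m
            for rid in rids
        )
        for m in range(cfg.n_modules)
    }
    targets: dict[str, frozenset[str]] = {}
    for d in range(cfg.n_drugs):
        home = d % cfg.n_modules
        tset: set[str] = set()
        for rid in modrxns[home]:
            if rng.random() < cfg.p_within:
                tset.add(_enzyme_of(rid))
            elif outside[home]:
                tset.add(outside[home][rng.integers(len(outside[home]))])
        if not tset:
            tset.add(_enzyme_of(modrxns[home][rng.integers(len(modrxns[home]))]))
        targets[f"D{d + 1:02d}"] = frozenset(tset)
    drug_map = DrugTargetMap(targets)
    enzymatic = [r.id for r in net.reactions if r.genes]
    x = np.array(
        [
            [1 if targets[d] & net.reaction(rid).enzymes else 0 for rid in enzymatic]
            for d in sorted(targets)
        ],
        dtype=np.int8,
    )
    return drug_map, InteractionMatrix(sorted(targets), enzymatic, x)


def make_sequence_families(cfg: SynthConfig) -> dict[str, ProteinSequence]:
    """One sequence family per module: a random ancestor, point-mutated copies.

    Each interior reaction's enzyme gets a copy of its module's ancestor with
    per-residue substitutions at ``seq_mutation_rate`` (to a uniformly random
    different residue), so within-family similarity exceeds between-family
    similarity in expectation.
    """
    rng = _rng(cfg, _STREAM_SEQS)
    aa = np.array(list(_AA))
    seqs: dict[str, ProteinSequence] = {}
    for m, rids in _module_reactions(cfg).items():
        ancestor = rng.choice(aa, cfg.seq_length)
        for rid in rids:
            member = ancestor.copy()
            mutate = rng.random(cfg.seq_length) < cfg.seq_mutation_rate
            for pos in np.nonzero(mutate)[0]:
                choices = [c for c in _AA if c != member[pos]]
                member[pos] = choices[rng.integers(len(choices))]
            eid = _enzyme_of(rid)
            seqs[eid] = ProteinSequence(eid, "".join(member))
    return seqs


def write_instance(cfg: SynthConfig, out_dir: str | Path) -> dict[str, Path]:
    """Emit a complete instance in the on-disk dialects consumed upstream.

    Writes network.json, expression.tsv, drug_targets.tsv, sequences.fasta
    and ground_truth.json (module membership, planted on/off pattern and the
    induced interaction matrix) and returns the paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    net = make_toy_network(cfg)
    expr = simulate_expression(net, cfg)
    drug_map, truth = plant_interactions(net, cfg)
    seqs = make_sequence_families(cfg)

    paths = {
        "network": out_dir / "network.json",
        "expression": out_dir / "expression.tsv",
        "drug_targets": out_dir / "drug_targets.tsv",
        "sequences": out_dir / "sequences.fasta",
        "ground_truth": out_dir / "ground_truth.json",
    }
    save_network(net, paths["network"])
    expr.to_frame().to_csv(paths["expression"], sep="\t", index_label="gene_id")
    with open(paths["drug_targets"], "w") as fh:
        fh.write("drug_id\tdrug_name\tatc_class\ttarget_protein_id\n")
        for drug in sorted(drug_map.targets):
            for enzyme in sorted(drug_map.targets[drug]):
                fh.write(f"{drug}\t{drug}\tsynthetic\t{enzyme}\n")
    with open(paths["sequences"], "w") as fh:
        for eid in sorted(seqs):
            fh.write(f">{eid}\n{seqs[eid].residues}\n")
    truth_doc = {
        "config": asdict(cfg),
        "modules": {
            f"M{m + 1}": rids for m, rids in _module_reactions(cfg).items()
        },
        "module_on_pattern": module_activity_pattern(cfg).astype(int).tolist(),
        "cell_line_ids": expr.cell_line_ids,
        "interaction_matrix": {
            "drug_ids": truth.drug_ids,
            "reaction_ids": truth.reaction_ids,
            "x": truth.x.tolist(),
        },
    }
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth_doc, fh, indent=1)
    return paths
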