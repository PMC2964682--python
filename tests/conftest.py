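import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from fluxdrn.expr_states import ReactionStateAssignment
from fluxdrn.metnet import MetabolicNetwork, Metabolite, Reaction
from fluxdrn.pipeline import run_synthetic_pipeline
from fluxdrn.synthdata import SynthConfig


def make_chain_network(bound: float = 10.0) -> MetabolicNetwork:
    """Three-reaction chain: r1 (inflow → A), r2 (A → B), r3 (B → outflow).

    All bounds [0, bound]; only r2 carries a gene/enzyme, so it is the only
    reaction expression states can apply to.
    """
    mets = [Metabolite("A"), Metabolite("B")]
    rxns = [
        Reaction("r1", lower_bound=0, upper_bound=bound),
        Reaction("r2", lower_bound=0, upper_bound=bound,
                 genes=frozenset({"g2"}), enzymes=frozenset({"e2"})),
        Reaction("r3", lower_bound=0, upper_bound=bound),
    ]
    stoich = {
        "r1": {"A": 1.0},
        "r2": {"A": -1.0, "B": 1.0},
        "r3": {"B": -1.0},
    }
    return MetabolicNetwork(mets, rxns, stoich)


@pytest.fixture
def chain_net() -> MetabolicNetwork:
    return make_chain_network()


def chain_states(r_h=(), r_l=(), cell_line="CL1") -> ReactionStateAssignment:
    enzymatic = {"r2"}
    return ReactionStateAssignment(
        cell_line,
        frozenset(r_h),
        frozenset(r_l),
        frozenset(enzymatic - set(r_h) - set(r_l)),
    )


@pytest.fixture(scope="session")
def pipeline_results():
    """Full synthetic pipeline on the default study conditions, seeds 0..9.

    Session-scoped: the LP solves are shared by the planted-recovery,
    metric-quality and network-statistics tests.
    """
    return {seed: run_synthetic_pipeline(SynthConfig(seed=seed)) for seed in range(10)}
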