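import pytest

from cscnet.types import (
    DrugTargetTable,
    ExpressionProfile,
    PathwayGraph,
    RegulatoryNetwork,
)


def make_profile(dataset_id, values, extra_universe=()):
    """Build a profile from a dict; None values mean measured-but-missing."""
    present = {g: v for g, v in values.items() if v is not None}
    return ExpressionProfile(
        dataset_id=dataset_id,
        values=present,
        universe=frozenset(values) | frozenset(extra_universe),
    )


def make_pathway(pid, edges, entries=(), extra_nodes=()):
    nodes = {n for e in edges for n in e} | set(entries) | set(extra_nodes)
    return PathwayGraph(
        pathway_id=pid,
        nodes=frozenset(nodes),
        edges=frozenset(edges),
        entry_nodes=frozenset(entries),
    )


@pytest.fixture
def diamond():
    """A -> {B, C} -> D with declared entry A."""
    return make_pathway("diamond", [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")],
                        entries=["A"])


@pytest.fixture
def small_net():
    return RegulatoryNetwork.from_edges(
        [("TFA", "G1"), ("TFA", "G2"), ("TFA", "G3"), ("TFB", "G4"), ("TFB", "G5")]
    )


@pytest.fixture
def two_profiles():
    genes = {"G1": 2.0, "G2": 1.5, "G3": 1.0, "G4": 0.2, "G5": -1.0,
             "TFA": 0.1, "TFB": None}
    d1 = make_profile("d1", genes)
    d2 = make_profile("d2", {**genes, "G3": 1.2, "G4": 0.5})
    return [d1, d2]


@pytest.fixture
def drug_table():
    return DrugTargetTable(frozenset([("DrugX", "B"), ("DrugY", "G1"),
                                      ("DrugZ", "D")]))
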