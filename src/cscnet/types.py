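"""Domain containers: expression profiles, regulatory and pathway networks,
drug-target tables, cascades, enrichment results, and the role-typed core
network.

Gene identity convention: symbols are upper-cased, whitespace-free labels.
Composite regulator names (e.g. ``TAL1_TCF4``) are kept verbatim as opaque
labels and never split. Missing fold changes are a first-class state — a gene
may belong to a profile's universe without carrying a value; absence is never
coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional

import networkx as nx

__all__ = [
    "normalize_symbol",
    "ExpressionProfile",
    "RegulatoryNetwork",
    "PathwayGraph",
    "DrugTargetTable",
    "EnrichmentStat",
    "EnrichmentResult",
    "Cascade",
    "CoreNetwork",
    "ROLES",
    "ROLE_PRECEDENCE",
    "EDGE_KINDS",
]

#: node roles of the core network, in no particular order
ROLES = ("start", "transduction", "tf", "target", "drug")

#: precedence when one gene plays several parts (highest wins); drugs never
#: collide with genes by construction
ROLE_PRECEDENCE = ("tf", "start", "transduction", "target")

EDGE_KINDS = ("signals", "regulates", "targets")


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol: strip surrounding whitespace, upper-case.

    Raises ``ValueError`` on empty or internally whitespace-containing
    symbols; callers reading files wrap this into a located FormatError.
    """
    s = str(symbol).strip().upper()
    if not s:
        raise ValueError("empty gene symbol")
    if any(c.isspace() for c in s):
        raise ValueError(f"gene symbol contains whitespace: {symbol!r}")
    return s


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-dataset map gene -> log2 fold change (CSC vs non-CSC).

    ``values`` holds only the genes with a measured value; ``universe`` is the
    full set of measured gene symbols and may contain genes whose fold change
    is missing (printed as NA in tables).
    """

    dataset_id: str
    values: Mapping[str, float]
    universe: frozenset[str]

    def __post_init__(self):
        missing = set(self.values) - set(self.universe)
        if missing:
            raise ValueError(
                f"profile {self.dataset_id}: values outside universe: {sorted(missing)[:5]}"
            )

    def get(self, gene: str) -> Optional[float]:
        return self.values.get(gene)

    def __contains__(self, gene: str) -> bool:
        return gene in self.universe


@dataclass(frozen=True)
class RegulatoryNetwork:
    """TF -> target relation as a deduplicated directed edge set."""

    edges: frozenset[tuple[str, str]]

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "RegulatoryNetwork":
        return cls(frozenset((tf, tg) for tf, tg in edges))

    @property
    def tfs(self) -> frozenset[str]:
        return frozenset(tf for tf, _ in self.edges)

    @property
    def all_targets(self) -> frozenset[str]:
        return frozenset(tg for _, tg in self.edges)

    def targets(self, tf: str) -> frozenset[str]:
        return frozenset(tg for t, tg in self.edges if t == tf)

    def target_map(self) -> dict[str, set[str]]:
        """Materialize tf -> target-set once; cheaper for whole-network scans."""
        out: dict[str, set[str]] = {}
        for tf, tg in self.edges:
            out.setdefault(tf, set()).add(tg)
        return out


@dataclass(frozen=True)
class PathwayGraph:
    """Directed gene/protein graph of one signaling pathway.

    ``entry_nodes`` are the declared "beginning" genes (receptors/ligands
    initiating signaling); the set may be empty, in which case entries are
    inferred downstream from in-degree. Cycles are allowed.
    """

    pathway_id: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    entry_nodes: frozenset[str] = frozenset()
    edge_labels: Mapping[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self):
        for s, t in self.edges:
            if s not in self.nodes or t not in self.nodes:
                raise ValueError(
                    f"pathway {self.pathway_id}: edge ({s},{t}) endpoint outside nodes"
                )
        if not self.entry_nodes <= self.nodes:
            raise ValueError(f"pathway {self.pathway_id}: entry nodes outside nodes")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for s, t in sorted(self.edges):
            g.add_edge(s, t, interaction=self.edge_labels.get((s, t)))
        return g


@dataclass(frozen=True)
class DrugTargetTable:
    """Deduplicated (drug, target-gene) pairs."""

    rows: frozenset[tuple[str, str]]

    @property
    def drugs(self) -> frozenset[str]:
        return frozenset(d for d, _ in self.rows)

    def targets_of(self, drug: str) -> frozenset[str]:
        return frozenset(t for d, t in self.rows if d == drug)


class EnrichmentStat(NamedTuple):
    """One dataset's hypergeometric counts and p-value for one TF.

    k: up-regulated targets in the universe; K: targets in the universe;
    n: up-regulated genes in the universe; N: universe size.
    """

    dataset_id: str
    k: int
    K: int
    n: int
    N: int
    p_value: float


@dataclass(frozen=True)
class EnrichmentResult:
    tf: str
    per_dataset: tuple[EnrichmentStat, ...]
    activated: bool

    @property
    def max_p(self) -> float:
        return max(s.p_value for s in self.per_dataset)


@dataclass(frozen=True)
class Cascade:
    """A simple directed path entry -> ... -> TF inside one pathway.

    ``score`` is the mean combined log2 fold change of the path genes whose
    combined fold change is positive; ``n_scored`` counts those genes.
    """

    pathway_id: str
    nodes: tuple[str, ...]
    score: float
    n_scored: int

    def __post_init__(self):
        if len(self.nodes) != len(set(self.nodes)):
            raise ValueError("cascade nodes must form a simple path")
        if (self.score == 0.0) != (self.n_scored == 0):
            raise ValueError("score is 0 exactly when no gene contributes")

    @property
    def tf(self) -> str:
        return self.nodes[-1]


@dataclass
class CoreNetwork:
    """Merged role-typed graph of cascades, TFs, common targets and drugs.

    ``nodes`` maps label -> role; ``edges`` holds (source, target, kind)
    triples with kind in {signals, regulates, targets}; ``provenance`` maps
    each edge to the contributing pathway ids, or the markers "regulon" /
    "drug".
    """

    nodes: dict[str, str] = field(default_factory=dict)
    edges: set[tuple[str, str, str]] = field(default_factory=set)
    provenance: dict[tuple[str, str, str], frozenset[str]] = field(default_factory=dict)

    def validate(self) -> None:
        for label, role in self.nodes.items():
            if role not in ROLES:
                raise ValueError(f"node {label}: unknown role {role!r}")
        for s, t, kind in self.edges:
            if kind not in EDGE_KINDS:
                raise ValueError(f"edge ({s},{t}): unknown kind {kind!r}")
            if s not in self.nodes or t not in self.nodes:
                raise ValueError(f"edge ({s},{t},{kind}): endpoint not a node")
            if kind == "regulates" and self.nodes[s] != "tf":
                raise ValueError(f"regulates edge from non-tf node {s}")
            if kind == "targets" and (
                self.nodes[s] != "drug" or self.nodes[t] == "drug"
            ):
                raise ValueError(f"targets edge must run drug -> gene: ({s},{t})")

    def sorted_nodes(self) -> list[tuple[str, str]]:
        return sorted(self.nodes.items())

    def sorted_edges(self) -> list[tuple[str, str, str]]:
        return sorted(self.edges)

    def copy(self) -> "CoreNetwork":
        return CoreNetwork(
            nodes=dict(self.nodes),
            edges=set(self.edges),
            provenance=dict(self.provenance),
        )
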