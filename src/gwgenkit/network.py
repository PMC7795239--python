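"""Domain types for genome-wide genetic and epigenetic networks (GWGENs).

A GWGEN is the union of a protein-protein interaction network (PPIN) and a
gene regulatory network (GRN) over proteins, genes, transcription factors
(TFs), lncRNAs and miRNAs.  Protein-protein interaction (``ppi``) edges are
undirected and stored with canonical ``source < target`` ordering; every
regulatory edge is directed.  miRNA regulation is repressive by convention:
its regression coefficient is constrained to be non-positive.

The same container is used for the *candidate* network (database-mined edge
hypotheses), the *real* network (the data-supported subnetwork surviving AIC
pruning, with fitted abilities attached) and the *core* network (top nodes
after principal network projection).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator


class NodeKind(str, Enum):
    PROTEIN = "protein"
    GENE = "gene"
    TF = "TF"
    LNCRNA = "lncRNA"
    MIRNA = "miRNA"


class EdgeMode(str, Enum):
    PPI = "ppi"
    TF_GENE = "tf->gene"
    TF_LNCRNA = "tf->lncRNA"
    TF_MIRNA = "tf->miRNA"
    LNCRNA_GENE = "lncRNA->gene"
    LNCRNA_LNCRNA = "lncRNA->lncRNA"
    LNCRNA_MIRNA = "lncRNA->miRNA"
    MIRNA_GENE = "miRNA->gene"
    MIRNA_LNCRNA = "miRNA->lncRNA"
    MIRNA_MIRNA = "miRNA->miRNA"


#: admissible (source kind, target kind) pairs per edge mode
_MODE_KINDS: dict[EdgeMode, tuple[set[NodeKind], set[NodeKind]]] = {
    EdgeMode.PPI: ({NodeKind.PROTEIN}, {NodeKind.PROTEIN}),
    EdgeMode.TF_GENE: ({NodeKind.TF}, {NodeKind.GENE}),
    EdgeMode.TF_LNCRNA: ({NodeKind.TF}, {NodeKind.LNCRNA}),
    EdgeMode.TF_MIRNA: ({NodeKind.TF}, {NodeKind.MIRNA}),
    EdgeMode.LNCRNA_GENE: ({NodeKind.LNCRNA}, {NodeKind.GENE}),
    EdgeMode.LNCRNA_LNCRNA: ({NodeKind.LNCRNA}, {NodeKind.LNCRNA}),
    EdgeMode.LNCRNA_MIRNA: ({NodeKind.LNCRNA}, {NodeKind.MIRNA}),
    EdgeMode.MIRNA_GENE: ({NodeKind.MIRNA}, {NodeKind.GENE}),
    EdgeMode.MIRNA_LNCRNA: ({NodeKind.MIRNA}, {NodeKind.LNCRNA}),
    EdgeMode.MIRNA_MIRNA: ({NodeKind.MIRNA}, {NodeKind.MIRNA}),
}

#: modes whose regression coefficient is sign-constrained (<= 0)
MIRNA_MODES = frozenset(
    {EdgeMode.MIRNA_GENE, EdgeMode.MIRNA_LNCRNA, EdgeMode.MIRNA_MIRNA}
)


class NetworkError(ValueError):
    """Raised for structurally invalid networks or edge tables."""


@dataclass(frozen=True)
class Node:
    id: str
    kind: NodeKind

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("node id must be nonempty")


@dataclass(frozen=True)
class Edge:
    """A candidate or identified interaction/regulation.

    ``ability`` is ``None`` before system identification.  For ``ppi`` edges
    the pair is canonicalized so that ``source < target``.
    """

    source: str
    target: str
    mode: EdgeMode
    ability: float | None = None

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise NetworkError("edge endpoints must be nonempty ids")
        if self.mode is EdgeMode.PPI and self.source > self.target:
            s, t = self.source, self.target
            object.__setattr__(self, "source", t)
            object.__setattr__(self, "target", s)

    @property
    def key(self) -> tuple[str, str, str]:
        """Identity of the edge: endpoints + mode, ability excluded."""
        return (self.source, self.target, self.mode.value)

    def with_ability(self, ability: float) -> "Edge":
        return replace(self, ability=ability)

    def touches(self, node_id: str) -> bool:
        return node_id in (self.source, self.target)

    def other(self, node_id: str) -> str:
        if node_id == self.source:
            return self.target
        if node_id == self.target:
            return self.source
        raise KeyError(node_id)


@dataclass
class GWGEN:
    """A genome-wide genetic and epigenetic network.

    Invariants: node ids unique; every edge endpoint exists; edge modes are
    consistent with endpoint kinds; at most one edge per (source, target,
    mode) key.
    """

    nodes: dict[str, Node] = field(default_factory=dict)
    edges: dict[tuple[str, str, str], Edge] = field(default_factory=dict)

    @classmethod
    def build(cls, nodes: Iterable[Node], edges: Iterable[Edge]) -> "GWGEN":
        net = cls()
        for node in nodes:
            net.add_node(node)
        for edge in edges:
            net.add_edge(edge)
        return net

    def add_node(self, node: Node) -> None:
        existing = self.nodes.get(node.id)
        if existing is not None and existing.kind is not node.kind:
            raise NetworkError(
                f"node {node.id!r} redeclared with kind {node.kind.value}, "
                f"was {existing.kind.value}"
            )
        self.nodes[node.id] = node

    def add_edge(self, edge: Edge) -> None:
        for endpoint in (edge.source, edge.target):
            if endpoint not in self.nodes:
                raise NetworkError(f"edge endpoint {endpoint!r} not in nodes")
        src_kinds, tgt_kinds = _MODE_KINDS[edge.mode]
        if self.nodes[edge.source].kind not in src_kinds:
            raise NetworkError(
                f"edge {edge.key}: source kind "
                f"{self.nodes[edge.source].kind.value} invalid for mode "
                f"{edge.mode.value}"
            )
        if self.nodes[edge.target].kind not in tgt_kinds:
            raise NetworkError(
                f"edge {edge.key}: target kind "
                f"{self.nodes[edge.target].kind.value} invalid for mode "
                f"{edge.mode.value}"
            )
        self.edges[edge.key] = edge

    def __contains__(self, key: tuple[str, str, str]) -> bool:
        return key in self.edges

    def __len__(self) -> int:
        return len(self.edges)

    def iter_edges(self) -> Iterator[Edge]:
        return iter(self.edges.values())

    def nodes_of_kind(self, *kinds: NodeKind) -> list[Node]:
        return sorted(
            (n for n in self.nodes.values() if n.kind in kinds),
            key=lambda n: n.id,
        )

    def edges_into(self, target_id: str) -> list[Edge]:
        """Directed edges regulating ``target_id`` plus ppi edges touching it."""
        out = []
        for e in self.edges.values():
            if e.mode is EdgeMode.PPI:
                if e.touches(target_id):
                    out.append(e)
            elif e.target == target_id:
                out.append(e)
        return sorted(out, key=lambda e: e.key)

    def induced_subnetwork(self, node_ids: set[str]) -> "GWGEN":
        """Subnetwork on ``node_ids``: edges with both endpoints retained."""
        sub = GWGEN()
        for nid in node_ids:
            if nid in self.nodes:
                sub.add_node(self.nodes[nid])
        for e in self.edges.values():
            if e.source in sub.nodes and e.target in sub.nodes:
                sub.add_edge(e)
        return sub

    def edge_keys(self) -> set[tuple[str, str, str]]:
        return set(self.edges)

    def copy(self) -> "GWGEN":
        return GWGEN(dict(self.nodes), dict(self.edges))


# role aliases used throughout the package; all three share the container
CandidateGWGEN = GWGEN
RealGWGEN = GWGEN
CoreGWGEN = GWGEN
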