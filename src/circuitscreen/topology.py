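"""Signed regulatory-network topologies.

A :class:`RegulatoryNetwork` is a list of named nodes plus signed directed
edges (activation or inhibition).  Networks are read and written in the
community topology dialect: a ``Source Target Type`` header followed by one
whitespace-delimited edge per line, with Type ``1`` for activation and ``2``
for inhibition.  Comment lines starting with ``#`` are ignored.

The built-in :func:`twist1_emt_cin_network` constructs the six-node
TWIST1–EMT–CIN circuit used throughout this package: TWIST1 represses
E-cadherin (CDH1), BubR1 (BUB1B, here named BUBR1) and p53 (TP53), activates
Vimentin (VIM); BubR1 co-varies positively with p53 and the DNA
double-strand-break marker gammaH2AX (H2AX), encoded as two activation edges
from BUBR1; and p53 represses H2AX.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

ACTIVATION = "activation"
INHIBITION = "inhibition"

_SIGN_TO_CODE = {ACTIVATION: 1, INHIBITION: 2}
_CODE_TO_SIGN = {1: ACTIVATION, 2: INHIBITION}

_HEADER = ("source", "target", "type")


class TopologyError(ValueError):
    """Raised for malformed topology files or invalid networks."""


@dataclass(frozen=True)
class Edge:
    """One signed directed interaction ``source -> target``."""

    source: str
    target: str
    sign: str

    def __post_init__(self) -> None:
        if self.sign not in _SIGN_TO_CODE:
            raise TopologyError(
                f"edge sign must be {ACTIVATION!r} or {INHIBITION!r}, got {self.sign!r}"
            )


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Named nodes plus signed directed edges.

    Invariants enforced at construction: node names are unique, non-empty
    and whitespace-free; every edge endpoint is a declared node; at most one
    edge exists per ordered (source, target) pair.  Self-loops are permitted.
    """

    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]

    def __init__(self, nodes: Sequence[str], edges: Iterable[Edge | tuple]) -> None:
        norm_edges = tuple(e if isinstance(e, Edge) else Edge(*e) for e in edges)
        object.__setattr__(self, "nodes", tuple(nodes))
        object.__setattr__(self, "edges", norm_edges)
        self._validate()

    def _validate(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise TopologyError("duplicate node names")
        for name in self.nodes:
            if not name or any(c.isspace() for c in name):
                raise TopologyError(f"invalid node name {name!r}")
        declared = set(self.nodes)
        seen_pairs: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.source not in declared or e.target not in declared:
                raise TopologyError(f"edge {e.source}->{e.target} has undeclared endpoint")
            pair = (e.source, e.target)
            if pair in seen_pairs:
                raise TopologyError(f"duplicate edge for pair {pair}")
            seen_pairs.add(pair)

    # -- convenience accessors -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self, name: str) -> int:
        try:
            return self.nodes.index(name)
        except ValueError:
            raise KeyError(f"unknown node {name!r}; nodes are {list(self.nodes)}") from None

    def in_edges(self, node: str) -> tuple[Edge, ...]:
        """Edges whose target is ``node``, in declaration order."""
        return tuple(e for e in self.edges if e.target == node)

    def out_edges(self, node: str) -> tuple[Edge, ...]:
        return tuple(e for e in self.edges if e.source == node)

    def same_topology(self, other: "RegulatoryNetwork") -> bool:
        """Equality up to node order and edge order."""
        return set(self.nodes) == set(other.nodes) and set(self.edges) == set(other.edges)


def read_topology(path: str | Path) -> RegulatoryNetwork:
    """Parse a ``Source Target Type`` topology file.

    The node list is the union of all edge endpoints in first-appearance
    order.  Blank lines and ``#`` comments are skipped.
    """
    path = Path(path)
    nodes: list[str] = []
    seen: set[str] = set()
    edges: list[Edge] = []
    header_seen = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if not header_seen:
                if tuple(f.lower() for f in fields) != _HEADER:
                    raise TopologyError(
                        f"{path}:{lineno}: expected header 'Source Target Type', got {line!r}"
                    )
                header_seen = True
                continue
            if len(fields) != 3:
                raise TopologyError(
                    f"{path}:{lineno}: expected 3 columns (Source Target Type), got {len(fields)}"
                )
            src, tgt, code_str = fields
            try:
                code = int(code_str)
            except ValueError:
                raise TopologyError(f"{path}:{lineno}: Type must be an integer, got {code_str!r}")
            if code not in _CODE_TO_SIGN:
                raise TopologyError(f"{path}:{lineno}: Type must be 1 or 2, got {code}")
            for name in (src, tgt):
                if name not in seen:
                    seen.add(name)
                    nodes.append(name)
            edges.append(Edge(src, tgt, _CODE_TO_SIGN[code]))
    if not header_seen:
        raise TopologyError(f"{path}: missing 'Source Target Type' header")
    return RegulatoryNetwork(nodes, edges)


def write_topology(network: RegulatoryNetwork, path: str | Path) -> None:
    """Write a network in the ``Source Target Type`` dialect (tab-delimited)."""
    path = Path(path)
    lines = ["Source\tTarget\tType"]
    for e in network.edges:
        lines.append(f"{e.source}\t{e.target}\t{_SIGN_TO_CODE[e.sign]}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def twist1_emt_cin_network() -> RegulatoryNetwork:
    """The six-node TWIST1–EMT–CIN circuit.

    The positive BubR1/p53 and BubR1/gammaH2AX co-variation is encoded as two
    activation edges out of BUBR1 (a single common upstream node yields the
    positive co-variation); supply a custom topology file to test other
    orientations.
    """
    nodes = ["TWIST1", "CDH1", "VIM", "BUBR1", "TP53", "H2AX"]
    edges = [
        Edge("TWIST1", "CDH1", INHIBITION),
        Edge("TWIST1", "VIM", ACTIVATION),
        Edge("TWIST1", "BUBR1", INHIBITION),
        Edge("TWIST1", "TP53", INHIBITION),
        Edge("BUBR1", "TP53", ACTIVATION),
        Edge("BUBR1", "H2AX", ACTIVATION),
        Edge("TP53", "H2AX", INHIBITION),
    ]
    return RegulatoryNetwork(nodes, edges)
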