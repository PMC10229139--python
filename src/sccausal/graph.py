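"""Graph containers for constraint-based causal discovery.

A :class:`Skeleton` is the undirected outcome of the PC edge-deletion stage,
with separating sets and the weakest surviving p-value per retained pair.  A
:class:`CausalNetwork` is a CPDAG: a mix of directed and undirected edges
with per-adjacency annotations (Pearson-correlation sign, p-value, weight).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = ["Skeleton", "CausalNetwork", "pair_key"]


class ValidationError(ValueError):
    pass


def pair_key(u: str, v: str) -> tuple[str, str]:
    """Canonical unordered key for an adjacency."""
    return (u, v) if u <= v else (v, u)


@dataclasses.dataclass
class Skeleton:
    """Undirected adjacency structure with separating sets.

    ``sepsets`` maps every removed pair to the first separating set found;
    ``pair_max_p`` records, for retained pairs, the largest p-value among all
    CI tests executed on the pair (the weakest evidence the edge survived).
    """

    nodes: tuple[str, ...]
    edges: set[tuple[str, str]]
    sepsets: dict[tuple[str, str], frozenset[str]]
    pair_max_p: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        self.edges = {pair_key(*e) for e in self.edges}
        for u, v in self.edges:
            if u == v:
                raise ValidationError("self-loop in skeleton")

    def neighbors(self, node: str) -> set[str]:
        out = set()
        for u, v in self.edges:
            if u == node:
                out.add(v)
            elif v == node:
                out.add(u)
        return out


@dataclasses.dataclass
class CausalNetwork:
    """CPDAG over gene ids with per-adjacency annotations.

    ``directed`` holds ordered pairs (u, v) meaning u → v; ``undirected``
    holds canonical unordered pairs.  ``sign`` ∈ {+1, −1, 0} encodes
    activation/repression from the Pearson correlation of the endpoint
    expression profiles, ``p_value`` the weakest CI-test p on the pair and
    ``weight`` = −log10(p) the edge thickness.
    """

    nodes: tuple[str, ...]
    directed: set[tuple[str, str]] = dataclasses.field(default_factory=set)
    undirected: set[tuple[str, str]] = dataclasses.field(default_factory=set)
    sign: dict[tuple[str, str], int] = dataclasses.field(default_factory=dict)
    p_value: dict[tuple[str, str], float] = dataclasses.field(default_factory=dict)
    weight: dict[tuple[str, str], float] = dataclasses.field(default_factory=dict)
    conflicts: set[tuple[str, str]] = dataclasses.field(default_factory=set)

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValidationError("duplicate node ids")
        self.undirected = {pair_key(*e) for e in self.undirected}
        for u, v in list(self.directed) + list(self.undirected):
            if u == v:
                raise ValidationError("self-loop")
            if u not in node_set or v not in node_set:
                raise ValidationError(f"edge endpoint {u!r}/{v!r} not among nodes")
        for u, v in self.directed:
            if (v, u) in self.directed:
                raise ValidationError(f"2-cycle between {u!r} and {v!r}")
            if pair_key(u, v) in self.undirected:
                raise ValidationError(f"pair {u!r}-{v!r} both directed and undirected")

    # -- queries ---------------------------------------------------------
    def adjacencies(self) -> set[tuple[str, str]]:
        """All adjacencies as canonical unordered pairs."""
        return {pair_key(u, v) for u, v in self.directed} | set(self.undirected)

    def mark(self, u: str, v: str) -> str | None:
        """Edge mark for the unordered pair: '-->', '<--', '---' or None."""
        if (u, v) in self.directed:
            return "-->"
        if (v, u) in self.directed:
            return "<--"
        if pair_key(u, v) in self.undirected:
            return "---"
        return None

    def n_edges(self) -> int:
        return len(self.directed) + len(self.undirected)

    def is_acyclic(self) -> bool:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed)
        return nx.is_directed_acyclic_graph(g)

    def copy(self) -> "CausalNetwork":
        return CausalNetwork(
            self.nodes,
            set(self.directed),
            set(self.undirected),
            dict(self.sign),
            dict(self.p_value),
            dict(self.weight),
            set(self.conflicts),
        )

    # -- serialization ---------------------------------------------------
    def to_edge_frame(self) -> pd.DataFrame:
        """Edge list with columns source, target, directed, sign, p_value, weight."""
        rows = []
        for u, v in sorted(self.directed):
            key = pair_key(u, v)
            rows.append((u, v, 1, self.sign.get(key, 0), self.p_value.get(key, float("nan")),
                         self.weight.get(key, float("nan"))))
        for u, v in sorted(self.undirected):
            key = (u, v)
            rows.append((u, v, 0, self.sign.get(key, 0), self.p_value.get(key, float("nan")),
                         self.weight.get(key, float("nan"))))
        return pd.DataFrame(rows, columns=["source", "target", "directed", "sign", "p_value", "weight"])

    def write_edge_list(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_edge_frame().to_csv(fh, sep="\t", index=False)

    def to_networkx(self) -> nx.DiGraph:
        """Export as a DiGraph; undirected edges become reciprocal arc pairs."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for u, v in self.directed:
            key = pair_key(u, v)
            g.add_edge(u, v, directed=True, sign=self.sign.get(key, 0),
                       p_value=self.p_value.get(key), weight=self.weight.get(key))
        for u, v in self.undirected:
            for a, b in ((u, v), (v, u)):
                g.add_edge(a, b, directed=False, sign=self.sign.get((u, v), 0),
                           p_value=self.p_value.get((u, v)), weight=self.weight.get((u, v)))
        return g

    def write_gml(self, path) -> None:
        nx.write_gml(self.to_networkx(), str(path))

    @classmethod
    def from_edges(
        cls,
        nodes: Iterable[str],
        directed: Iterable[tuple[str, str]] = (),
        undirected: Iterable[tuple[str, str]] = (),
        annotations: Mapping[tuple[str, str], Mapping[str, float]] | None = None,
    ) -> "CausalNetwork":
        net = cls(tuple(nodes), set(directed), set(undirected))
        for key, ann in (annotations or {}).items():
            key = pair_key(*key)
            if "sign" in ann:
                net.sign[key] = int(ann["sign"])
            if "p_value" in ann:
                net.p_value[key] = float(ann["p_value"])
            if "weight" in ann:
                net.weight[key] = float(ann["weight"])
        return net
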