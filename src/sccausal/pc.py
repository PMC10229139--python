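"""PC-stable structure learning with pluggable conditional-independence tests.

Constraint-based discovery proceeds in two steps: skeleton estimation
(deleting edges whose endpoints test conditionally independent) and
orientation (v-structures from separating sets, then Meek-rule propagation
to a CPDAG).  The order-independent PC-stable variant is used: within each
conditioning-set size the neighborhoods consulted for conditioning sets are
frozen at the start of the level, so results do not depend on variable
order.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Protocol, Sequence

import networkx as nx
import numpy as np

from .citests import CITestResult, CITester
from .graph import CausalNetwork, Skeleton, pair_key

__all__ = ["pc_skeleton", "orient_cpdag", "pc_infer", "orient_pdag", "DSeparationTester"]

P_FLOOR = 1e-300


class ValidationError(ValueError):
    pass


class Tester(Protocol):
    def test(self, data: np.ndarray, i: int, j: int, S: Sequence[int]) -> CITestResult: ...


class DSeparationTester:
    """Oracle tester answering CI queries by d-separation on a known DAG.

    Returns p = 1 when i and j are d-separated by S in the generating DAG and
    p = 0 otherwise, so the PC algorithm recovers exactly the structure the
    oracle encodes (useful for correctness tests and for computing true
    CPDAGs).
    """

    def __init__(self, dag: nx.DiGraph, node_order: Sequence | None = None):
        self.dag = dag
        self.order = list(node_order) if node_order is not None else sorted(dag.nodes)

    def test(self, data: np.ndarray, i: int, j: int, S: Sequence[int] = ()) -> CITestResult:
        sep = nx.is_d_separator(
            self.dag, {self.order[i]}, {self.order[j]}, {self.order[s] for s in S}
        )
        return CITestResult(0.0, 1.0 if sep else 0.0, "oracle", len(S), max(len(self.order), 1))


def pc_skeleton(
    data: np.ndarray,
    node_ids: Sequence[str],
    tester: Tester,
    alpha: float = 0.1,
    max_cond_size: int = 3,
) -> Skeleton:
    """Estimate the undirected skeleton with the PC-stable deletion schedule.

    Starting from the complete graph, for each conditioning-set size
    ℓ = 0..max_cond_size every retained pair (i, j) is tested against all
    size-ℓ subsets of the level-ℓ-frozen neighborhoods of i and of j; the
    edge is removed (and the subset recorded as the separating set) at the
    first p > alpha.  For retained pairs the largest p seen is kept as the
    edge's weakest surviving evidence.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must lie in (0, 1)")
    if max_cond_size < 0:
        raise ValidationError("max_cond_size must be non-negative")
    node_ids = [str(n) for n in node_ids]
    p = len(node_ids)
    if p < 2:
        raise ValidationError("need at least two variables")
    adj: dict[int, set[int]] = {i: set(range(p)) - {i} for i in range(p)}
    sepsets: dict[tuple[str, str], frozenset[str]] = {}
    pair_max_p: dict[tuple[str, str], float] = {}

    for level in range(max_cond_size + 1):
        frozen = {i: frozenset(adj[i]) for i in range(p)}
        if all(len(frozen[i]) - 1 < level for i in range(p)):
            break
        for i, j in itertools.combinations(range(p), 2):
            if j not in adj[i]:
                continue
            candidates: list[tuple[int, ...]] = []
            seen: set[tuple[int, ...]] = set()
            for anchor in (i, j):
                other = j if anchor == i else i
                nbrs = sorted(frozen[anchor] - {other})
                if len(nbrs) < level:
                    continue
                for S in itertools.combinations(nbrs, level):
                    if S not in seen:
                        seen.add(S)
                        candidates.append(S)
            removed = False
            for S in candidates:
                res = tester.test(data, i, j, S)
                key = pair_key(node_ids[i], node_ids[j])
                pair_max_p[key] = max(pair_max_p.get(key, 0.0), res.p_value)
                if res.p_value > alpha:
                    adj[i].discard(j)
                    adj[j].discard(i)
                    sepsets[key] = frozenset(node_ids[s] for s in S)
                    removed = True
                    break
            if removed:
                continue

    edges = {pair_key(node_ids[i], node_ids[j]) for i in range(p) for j in adj[i] if i < j}
    pair_max_p = {k: v for k, v in pair_max_p.items() if k in edges}
    return Skeleton(tuple(node_ids), edges, sepsets, pair_max_p)


def orient_pdag(
    nodes: Sequence[str],
    adjacencies: Iterable[tuple[str, str]],
    v_structures: Iterable[tuple[str, str, str]],
) -> CausalNetwork:
    """Build a CPDAG from adjacencies and collider triples (a, c, b) = a→c←b.

    Conflicting collider demands (an edge pushed both ways) are resolved to
    an undirected edge with a conflict flag, then Meek rules 1–4 are applied
    to a fixpoint.
    """
    nodes = tuple(str(n) for n in nodes)
    adj = {pair_key(u, v) for u, v in adjacencies}
    neighbors: dict[str, set[str]] = {n: set() for n in nodes}
    for u, v in adj:
        neighbors[u].add(v)
        neighbors[v].add(u)

    demands: set[tuple[str, str]] = set()
    for a, c, b in v_structures:
        demands.add((a, c))
        demands.add((b, c))
    conflicts = {pair_key(u, v) for u, v in demands if (v, u) in demands}
    directed = {(u, v) for u, v in demands if pair_key(u, v) not in conflicts}
    undirected = adj - {pair_key(u, v) for u, v in directed}

    def adjacent(u: str, v: str) -> bool:
        return pair_key(u, v) in adj

    def orient(u: str, v: str) -> bool:
        """Try to orient u−v as u→v; returns True if the graph changed."""
        key = pair_key(u, v)
        # collider-conflicted edges stay undirected: their orientation
        # evidence is unreliable, so Meek propagation must not re-orient them
        if key not in undirected or key in conflicts:
            return False
        undirected.discard(key)
        directed.add((u, v))
        return True

    changed = True
    while changed:
        changed = False
        for key in sorted(undirected):
            for a, b in (key, key[::-1]):
                # Meek R1: c→a, a−b, c and b non-adjacent  ⇒  a→b
                if any((c, a) in directed and not adjacent(c, b) for c in neighbors[a] - {b}):
                    changed |= orient(a, b)
                    break
                # Meek R2: a→c→b with a−b  ⇒  a→b
                if any((a, c) in directed and (c, b) in directed for c in neighbors[a] & neighbors[b]):
                    changed |= orient(a, b)
                    break
                # Meek R3: a−c→b, a−d→b, c,d non-adjacent  ⇒  a→b
                cands = [c for c in neighbors[a] & neighbors[b]
                         if pair_key(a, c) in undirected and (c, b) in directed]
                if any(not adjacent(c, d) for c, d in itertools.combinations(sorted(cands), 2)):
                    changed |= orient(a, b)
                    break
                # Meek R4: a−d, d→c, c→b, b,d non-adjacent  ⇒  a→b
                r4 = False
                for d in neighbors[a] - {b}:
                    if pair_key(a, d) not in undirected or adjacent(d, b):
                        continue
                    if any((d, c) in directed and (c, b) in directed
                           for c in neighbors[d] & neighbors[b]):
                        r4 = True
                        break
                if r4:
                    changed |= orient(a, b)
                    break
            if changed:
                break

    net = CausalNetwork(nodes, directed, undirected)
    net.conflicts = conflicts
    return net


def orient_cpdag(sk: Skeleton) -> CausalNetwork:
    """Orient a skeleton into a CPDAG using its separating sets.

    Every unshielded triple a−c−b with a, b non-adjacent becomes the collider
    a→c←b iff c is absent from sepset(a, b); Meek rules then propagate.  Edge
    annotations are initialized with sign 0, the pair's weakest surviving
    p-value, and weight −log10(p).
    """
    vstructs: list[tuple[str, str, str]] = []
    for c in sk.nodes:
        nbrs = sorted(sk.neighbors(c))
        for a, b in itertools.combinations(nbrs, 2):
            if pair_key(a, b) in sk.edges:
                continue
            sep = sk.sepsets.get(pair_key(a, b))
            if sep is None:
                continue  # pair never separated (e.g. level cap); no collider call
            if c not in sep:
                vstructs.append((a, c, b))
    net = orient_pdag(sk.nodes, sk.edges, vstructs)
    for key in net.adjacencies():
        pval = sk.pair_max_p.get(key, 0.0)
        net.sign[key] = 0
        net.p_value[key] = pval
        net.weight[key] = float(-np.log10(max(pval, P_FLOOR)))
    return net


def pc_infer(
    data: np.ndarray,
    node_ids: Sequence[str],
    tester: Tester | CITester,
    alpha: float = 0.1,
    max_cond_size: int = 3,
) -> CausalNetwork:
    """Full PC run: skeleton estimation followed by CPDAG orientation."""
    sk = pc_skeleton(data, node_ids, tester, alpha, max_cond_size)
    return orient_cpdag(sk)
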