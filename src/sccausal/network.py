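"""Network post-processing and reliability scoring.

Inferred CPDAGs are compared by structural Hamming distance (SHD), turned
into similarities via exp(−d/2σ²) with σ = 5, intersected into consensus
networks, scored by true-positive rate against the consensus, and profiled
for stability across repeated runs.  "Interaction" here always means an
adjacency; edge direction enters only through the unanimity rule of the
consensus and the mark term of the SHD.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Sequence

import numpy as np
import scipy.cluster.hierarchy
import scipy.spatial.distance

from .graph import CausalNetwork, pair_key

__all__ = [
    "annotate_edge_signs",
    "shd",
    "similarity_matrix",
    "consensus_network",
    "tpr_vs_consensus",
    "edge_stability",
    "select_consensus_members",
    "build_consensus_report",
    "ConsensusReport",
    "StabilityProfile",
]

DEFAULT_SIGMA = 5.0


class ValidationError(ValueError):
    pass


@dataclasses.dataclass
class ConsensusReport:
    """Pairwise distances, similarities, consensus membership and TPRs."""

    labels: tuple[str, ...]
    shd_matrix: np.ndarray
    similarity: np.ndarray
    members: tuple[str, ...]
    consensus: CausalNetwork | None
    tpr: dict[str, float]

    def to_json(self, path=None) -> str:
        payload = {
            "labels": list(self.labels),
            "shd_matrix": self.shd_matrix.astype(int).tolist(),
            "similarity": self.similarity.tolist(),
            "members": list(self.members),
            "consensus_edges": sorted(self.consensus.adjacencies()) if self.consensus else None,
            "tpr": self.tpr,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclasses.dataclass
class StabilityProfile:
    """Occurrence of union adjacencies across m repeated runs."""

    m: int
    counts: dict[tuple[str, str], int]
    exact_fraction: dict[int, float]
    cumulative_fraction: dict[int, float]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "k": list(range(1, self.m + 1)),
                "exact_fraction": [self.exact_fraction[k] for k in range(1, self.m + 1)],
                "cumulative_fraction": [self.cumulative_fraction[k] for k in range(1, self.m + 1)],
            }
        )


def annotate_edge_signs(net: CausalNetwork, data: np.ndarray, node_ids: Sequence[str]) -> CausalNetwork:
    """Set each edge's sign from the Pearson correlation of its endpoints.

    Positive correlation reads as activation (+1), negative as repression
    (−1); a zero or undefined correlation (constant gene) gives sign 0 with
    a warning.
    """
    node_ids = [str(n) for n in node_ids]
    idx = {n: k for k, n in enumerate(node_ids)}
    missing = [n for n in net.nodes if n not in idx]
    if missing:
        raise ValidationError(f"no data column for nodes {missing[:5]}")
    out = net.copy()
    X = np.asarray(data, dtype=float)
    for key in sorted(out.adjacencies()):
        u, v = key
        x, y = X[:, idx[u]], X[:, idx[v]]
        if x.std() == 0 or y.std() == 0:
            warnings.warn(f"constant expression for edge {u}-{v}; sign set to 0")
            out.sign[key] = 0
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        out.sign[key] = 0 if r == 0 or not np.isfinite(r) else (1 if r > 0 else -1)
    return out


def _check_same_nodes(g1: CausalNetwork, g2: CausalNetwork) -> None:
    if set(g1.nodes) != set(g2.nodes):
        raise ValidationError("networks must share the same node set")


def shd(g1: CausalNetwork, g2: CausalNetwork) -> int:
    """Structural Hamming distance between two (partially) directed graphs.

    One point per adjacency present in exactly one graph, plus one point per
    shared adjacency whose mark differs (directed vs undirected, or opposite
    direction).  A direction flip counts 1.
    """
    _check_same_nodes(g1, g2)
    a1, a2 = g1.adjacencies(), g2.adjacencies()
    d = len(a1 ^ a2)
    for u, v in a1 & a2:
        if g1.mark(u, v) != g2.mark(u, v):
            d += 1
    return d


def similarity_matrix(
    networks: Sequence[CausalNetwork],
    labels: Sequence[str] | None = None,
    sigma: float = DEFAULT_SIGMA,
) -> ConsensusReport:
    """Pairwise SHD and Similarity = exp(−Distance/2σ²) matrices (σ = 5 default)."""
    if len(networks) < 2:
        raise ValidationError("need at least two networks")
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    labels = tuple(labels) if labels is not None else tuple(f"net{k}" for k in range(len(networks)))
    if len(labels) != len(networks):
        raise ValidationError("one label per network required")
    m = len(networks)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = shd(networks[i], networks[j])
    sim = np.exp(-D / (2.0 * sigma**2))
    return ConsensusReport(labels, D, sim, members=(), consensus=None, tpr={})


def select_consensus_members(
    report: ConsensusReport, height: float = 0.1, min_size: int = 2
) -> tuple[str, ...]:
    """Pick consensus members as the largest average-linkage cluster of networks.

    Clustering runs on 1 − similarity; ``height`` is the dendrogram cut.  A
    reproducible stand-in for choosing the most mutually similar networks off
    a cluster map by eye.
    """
    dist = 1.0 - report.similarity
    np.fill_diagonal(dist, 0.0)
    condensed = scipy.spatial.distance.squareform(dist, checks=False)
    Z = scipy.cluster.hierarchy.linkage(condensed, method="average")
    assign = scipy.cluster.hierarchy.fcluster(Z, t=height, criterion="distance")
    sizes = {c: int((assign == c).sum()) for c in set(assign)}
    best = max(sizes, key=lambda c: (sizes[c], -c))
    members = tuple(l for l, c in zip(report.labels, assign) if c == best)
    if len(members) < min_size:
        members = report.labels  # no tight cluster: fall back to all networks
    return members


def consensus_network(
    networks: Sequence[CausalNetwork],
    labels: Sequence[str] | None = None,
    members: Sequence[str] | None = None,
) -> CausalNetwork:
    """Intersection of the member networks.

    An adjacency is kept iff present in every member; its direction is kept
    iff all members orient it identically, otherwise it stays undirected;
    its sign is kept iff unanimous, otherwise 0.
    """
    labels = list(labels) if labels is not None else [f"net{k}" for k in range(len(networks))]
    by_label = dict(zip(labels, networks))
    if members is None:
        members = labels
    unknown = [m for m in members if m not in by_label]
    if unknown:
        raise ValidationError(f"unknown network labels {unknown}")
    if len(members) < 2:
        raise ValidationError("consensus requires at least two member networks")
    nets = [by_label[m] for m in members]
    for g in nets[1:]:
        _check_same_nodes(nets[0], g)
    common = set.intersection(*(g.adjacencies() for g in nets))
    out = CausalNetwork(nets[0].nodes)
    for key in sorted(common):
        u, v = key
        marks = {g.mark(u, v) for g in nets}
        if len(marks) == 1 and marks != {"---"}:
            mark = marks.pop()
            out.directed.add((u, v) if mark == "-->" else (v, u))
        else:
            out.undirected.add(key)
        signs = {g.sign.get(key, 0) for g in nets}
        out.sign[key] = signs.pop() if len(signs) == 1 else 0
        pvals = [g.p_value[key] for g in nets if key in g.p_value]
        if pvals:
            out.p_value[key] = max(pvals)
            out.weight[key] = float(-np.log10(max(out.p_value[key], 1e-300)))
    return out


def tpr_vs_consensus(net: CausalNetwork, consensus: CausalNetwork) -> float:
    """TPR = overlap / (overlap + specific) of adjacencies against the consensus.

    ``overlap`` counts interactions shared with the consensus network and
    ``specific`` those found only by ``net`` (73 shared and 33 specific give
    73/106 = 68.9 %).  A network with no interactions scores 1 vacuously.
    """
    _check_same_nodes(net, consensus)
    a, c = net.adjacencies(), consensus.adjacencies()
    if not a:
        warnings.warn("network has no adjacencies; TPR defined as 1")
        return 1.0
    overlap = len(a & c)
    specific = len(a - c)
    return overlap / (overlap + specific)


def edge_stability(networks: Sequence[CausalNetwork]) -> StabilityProfile:
    """Occurrence profile of union adjacencies over m repeated runs."""
    m = len(networks)
    if m < 2:
        raise ValidationError("stability analysis needs at least two runs")
    for g in networks[1:]:
        _check_same_nodes(networks[0], g)
    counts: dict[tuple[str, str], int] = {}
    for g in networks:
        for key in g.adjacencies():
            counts[key] = counts.get(key, 0) + 1
    total = len(counts)
    exact = {k: 0 for k in range(1, m + 1)}
    for c in counts.values():
        exact[c] += 1
    exact_frac = {k: (exact[k] / total if total else 0.0) for k in range(1, m + 1)}
    cum_frac = {k: sum(exact_frac[j] for j in range(k, m + 1)) for k in range(1, m + 1)}
    return StabilityProfile(m, counts, exact_frac, cum_frac)


def build_consensus_report(
    networks: Sequence[CausalNetwork],
    labels: Sequence[str] | None = None,
    sigma: float = DEFAULT_SIGMA,
    members: Sequence[str] | None = None,
    cluster_height: float = 0.1,
) -> ConsensusReport:
    """Full reliability report: similarity matrices, consensus, per-network TPR."""
    report = similarity_matrix(networks, labels, sigma)
    if members is None:
        members = select_consensus_members(report, height=cluster_height)
    cons = consensus_network(networks, report.labels, members)
    tpr = {l: tpr_vs_consensus(g, cons) for l, g in zip(report.labels, networks)}
    report.members = tuple(members)
    report.consensus = cons
    report.tpr = tpr
    return report
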