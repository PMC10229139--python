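"""Spike-in reliability QC.

A spike-in dataset contains genes with well-known interactions.  Stacking it
onto a case dataset — after randomly pairing spike-in cells with case cells,
which destroys any cross-dataset dependence by construction — and running
causal discovery on the combined matrix provides a built-in control: the
known block should be recovered and essentially no edges should cross
between the spike-in and case blocks.  Cross-block edges estimate the false
positive behavior of the chosen CI test on the data at hand.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from .expression import ExpressionMatrix
from .graph import CausalNetwork, pair_key

__all__ = ["SpikeInSet", "SeparationReport", "integrate_spike_in", "spike_separation_report"]

SPIKE_PREFIX = "SPIKE_"
DEFAULT_CROSS_THRESHOLD = 0.05


class ValidationError(ValueError):
    pass


@dataclasses.dataclass
class SpikeInSet:
    """Spike-in expression block and its expected interactions.

    ``expected_edges`` are (gene_a, gene_b, directed) triples on the original
    (unprefixed) spike-in gene ids; ``prefix`` is applied at integration time
    to keep spike-in ids disjoint from case ids.
    """

    expression: ExpressionMatrix
    expected_edges: tuple[tuple[str, str, bool], ...] = ()
    prefix: str = SPIKE_PREFIX

    def __post_init__(self) -> None:
        if self.expression.n_genes < 1:
            raise ValidationError("spike-in set needs at least one gene")
        genes = set(self.expression.gene_ids)
        for a, b, _ in self.expected_edges:
            if a not in genes or b not in genes:
                raise ValidationError(f"expected edge {a}-{b} references unknown spike-in genes")

    def prefixed_genes(self) -> tuple[str, ...]:
        return tuple(self.prefix + g for g in self.expression.gene_ids)


@dataclasses.dataclass(frozen=True)
class SeparationReport:
    """Edge counts by block plus the separation verdict."""

    within_spike: int
    within_case: int
    cross: int
    recovered_expected: int
    n_expected: int
    cross_fraction: float
    separated: bool | None
    threshold: float

    @property
    def recovered_fraction(self) -> float:
        return self.recovered_expected / self.n_expected if self.n_expected else 1.0


def integrate_spike_in(
    case: ExpressionMatrix, spike: SpikeInSet, seed: int = 0
) -> ExpressionMatrix:
    """Stack prefixed spike-in rows under the case rows on a shared cell set.

    Cell counts are equalized to min(case, spike) by seeded subsampling of
    the larger matrix, and spike-in cells are paired with case cells by a
    seeded random permutation — so any dependence between the two blocks in
    the combined matrix is spurious by construction.  Case values are never
    modified.
    """
    sp = spike.expression
    if case.transform != sp.transform:
        raise ValidationError(
            f"transform mismatch: case={case.transform!r}, spike-in={sp.transform!r}"
        )
    overlap = set(case.gene_ids) & set(spike.prefixed_genes())
    if overlap:
        raise ValidationError(f"prefixed spike-in genes collide with case genes: {sorted(overlap)[:5]}")
    rng = np.random.default_rng(seed)
    n = min(case.n_cells, sp.n_cells)
    case_cols = np.sort(rng.choice(case.n_cells, size=n, replace=False))
    spike_cols = np.sort(rng.choice(sp.n_cells, size=n, replace=False))
    pairing = rng.permutation(n)  # spike cell pairing[k] sits under case cell k
    values = np.vstack([case.values[:, case_cols], sp.values[:, spike_cols][:, pairing]])
    genes = case.gene_ids + spike.prefixed_genes()
    cells = tuple(case.cell_ids[c] for c in case_cols)
    return ExpressionMatrix(values, genes, cells, case.transform)


def spike_separation_report(
    net: CausalNetwork,
    spike_genes: Iterable[str],
    expected_edges: Sequence[tuple[str, str, bool]] = (),
    prefix: str = SPIKE_PREFIX,
    threshold: float = DEFAULT_CROSS_THRESHOLD,
) -> SeparationReport:
    """Count within-spike, within-case and crossing edges of an inferred network.

    The separation flag is true when the crossing fraction of all edges is at
    most ``threshold`` (default 5 %); an empty network leaves it undefined.
    ``expected_edges`` (unprefixed ids) are checked at the adjacency level
    against the within-spike edges.
    """
    spike_set = {str(g) for g in spike_genes}
    missing = spike_set - set(net.nodes)
    if missing:
        raise ValidationError(f"spike genes absent from network: {sorted(missing)[:5]}")
    within_spike = within_case = cross = 0
    for u, v in net.adjacencies():
        k = (u in spike_set) + (v in spike_set)
        if k == 2:
            within_spike += 1
        elif k == 0:
            within_case += 1
        else:
            cross += 1
    total = within_spike + within_case + cross
    adjacencies = net.adjacencies()
    recovered = sum(
        1
        for a, b, _ in expected_edges
        if pair_key(prefix + a, prefix + b) in adjacencies
    )
    cross_fraction = cross / total if total else 0.0
    separated = None if total == 0 else cross_fraction <= threshold
    return SeparationReport(
        within_spike=within_spike,
        within_case=within_case,
        cross=cross,
        recovered_expected=recovered,
        n_expected=len(expected_edges),
        cross_fraction=cross_fraction,
        separated=separated,
        threshold=threshold,
    )
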