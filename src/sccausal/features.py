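"""Feature selection: rank candidate genes by dependence on response genes.

Causal discovery is only reliable on a few dozen genes, so a feature set is
first chosen by dependence on one or several response genes (the genes of
interest).  BAHSIC — backward elimination under the Hilbert–Schmidt
independence criterion — is the recommended method; an ensemble-tree
importance ranking is provided as the complementary method, and the two can
be combined by a capped union of their top-k lists.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from . import kernels
from .expression import ExpressionMatrix

__all__ = ["FeatureRanking", "bahsic_select", "tree_importance_select", "union_select", "merge_genes"]


class ValidationError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class FeatureRanking:
    """Ordered genes (most to least relevant) with their scores."""

    genes: tuple[str, ...]
    scores: tuple[float, ...]
    method: str
    response_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("ranking contains duplicate genes")
        if len(self.genes) != len(self.scores):
            raise ValidationError("one score per gene required")
        if any(not math.isfinite(s) for s in self.scores):
            raise ValidationError("scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.genes) + 1),
                "gene": list(self.genes),
                "score": list(self.scores),
                "method": self.method,
            }
        )


def _prepare(m: ExpressionMatrix, response_genes: Sequence[str], k: int):
    response_genes = [str(g) for g in response_genes]
    missing = [g for g in response_genes if g not in m.gene_ids]
    if missing:
        raise ValidationError(f"response genes not in matrix: {missing}")
    candidates = [g for g in m.gene_ids if g not in set(response_genes)]
    if k >= len(candidates):
        raise ValidationError(f"k={k} must be smaller than the candidate count {len(candidates)}")
    idx = {g: i for i, g in enumerate(m.gene_ids)}
    Y = m.values[[idx[g] for g in response_genes], :].T  # cells × responses
    X = {g: m.values[idx[g], :] for g in candidates}
    return candidates, X, Y


def bahsic_select(
    m: ExpressionMatrix,
    response_genes: Sequence[str],
    k: int = 50,
    elimination_fraction: float = 0.1,
    seed: int = 0,
) -> FeatureRanking:
    """Backward-elimination HSIC feature selection (BAHSIC).

    Starting from all candidates, each round scores every remaining gene by
    the HSIC between that gene and the (possibly multivariate) response and
    removes the lowest-scoring ⌈elimination_fraction × remaining⌉ genes; the
    final ranking is the reverse removal order.  Because each gene is scored
    against the fixed response, per-gene scores are constant across rounds
    and are computed once.  Ties break lexicographically, so the procedure
    is fully deterministic.
    """
    if not 0.0 < elimination_fraction < 1.0:
        raise ValidationError("elimination_fraction must lie in (0, 1)")
    candidates, X, Y = _prepare(m, response_genes, k)
    # the response kernel is shared by every per-gene score
    Lc = kernels.center_kernel(kernels.gaussian_kernel(Y, seed=seed))
    scores = {
        g: float(
            (kernels.center_kernel(kernels.gaussian_kernel(X[g], seed=seed)) * Lc).mean()
        )
        for g in candidates
    }
    remaining = sorted(candidates)
    removal_order: list[str] = []
    while remaining:
        n_drop = max(1, math.ceil(elimination_fraction * len(remaining)))
        n_drop = min(n_drop, len(remaining))
        # lowest scores go first; lexicographic gene id breaks ties
        order = sorted(remaining, key=lambda g: (scores[g], g))
        drop = order[:n_drop]
        removal_order.extend(drop)
        remaining = [g for g in remaining if g not in set(drop)]
    ranking = removal_order[::-1]
    top = ranking[:k]
    return FeatureRanking(
        tuple(top),
        tuple(scores[g] for g in top),
        "bahsic",
        tuple(str(g) for g in response_genes),
    )


def tree_importance_select(
    m: ExpressionMatrix,
    response_genes: Sequence[str],
    k: int = 50,
    n_trees: int = 500,
    seed: int = 0,
) -> FeatureRanking:
    """Random-forest impurity-importance ranking of candidate genes.

    One forest is fitted per response gene (candidates → response regression)
    and importances are averaged over fits.  The seed fixes the ensemble, so
    the ranking is reproducible; ties (e.g. all-constant candidates) break
    lexicographically.
    """
    if n_trees < 1:
        raise ValidationError("n_trees must be at least 1")
    candidates, X, Y = _prepare(m, response_genes, k)
    Xmat = np.column_stack([X[g] for g in candidates])
    importances = np.zeros(len(candidates))
    for r in range(Y.shape[1]):
        forest = RandomForestRegressor(n_estimators=n_trees, random_state=seed)
        forest.fit(Xmat, Y[:, r])
        importances += forest.feature_importances_
    importances /= Y.shape[1]
    order = sorted(range(len(candidates)), key=lambda q: (-importances[q], candidates[q]))
    top = order[:k]
    return FeatureRanking(
        tuple(candidates[q] for q in top),
        tuple(float(importances[q]) for q in top),
        "tree",
        tuple(str(g) for g in response_genes),
    )


def union_select(
    rankings: Sequence[FeatureRanking], k_total: int
) -> list[str]:
    """Deduplicated union of top-ranked genes across methods, capped at k_total.

    Genes are merged by interleaving the rankings (best ranks first), the
    recommended way of jointly using BAHSIC with a tree-based ranking.
    """
    if k_total < 1:
        raise ValidationError("k_total must be positive")
    out: list[str] = []
    for depth in range(max(len(r.genes) for r in rankings)):
        for r in rankings:
            if depth < len(r.genes) and r.genes[depth] not in out:
                out.append(r.genes[depth])
                if len(out) == k_total:
                    return out
    return out


def merge_genes(
    selected: Sequence[str],
    add: Sequence[str] = (),
    remove: Sequence[str] = (),
) -> list[str]:
    """Manually add or remove genes after selection, preserving order."""
    removed = set(remove)
    out = [g for g in selected if g not in removed]
    for g in add:
        if g not in out and g not in removed:
            out.append(g)
    return out
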