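"""Chromosome-length scaling models and dendrogram comparison.

Two complementary views of whether mutation load simply tracks
chromosome size:

* an ordinary-least-squares fit of per-chromosome SNP count on
  chromosome length (Mb), reported as slope / intercept / R-squared and
  the two-sided p-value of the slope t-statistic (n-2 df);
* a tanglegram comparison of the chromosome dendrogram clustered by
  length against the one clustered by SNP count, scored by entanglement
  (0 = identical leaf orders, 1 = exactly reversed), with an optional
  greedy subtree-rotation untangling pass.

Hierarchical clustering uses absolute differences of the scalar values
with average linkage; ties are broken deterministically by sorting labels
first.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "RegressionFit",
    "Dendrogram",
    "EntanglementScore",
    "fit_count_vs_length",
    "build_dendrogram",
    "entanglement",
    "untangle",
]


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of count ~ length."""

    slope: float        # SNPs per Mb
    intercept: float    # SNPs
    r_squared: float
    p_value: float      # two-sided, slope t-test, n-2 df
    n: int

    def __str__(self) -> str:
        return (f"count = {self.intercept:.2f} + {self.slope:.3f} x length_Mb "
                f"(R^2={self.r_squared:.2f}, p={self.p_value:.3g}, n={self.n})")


def fit_count_vs_length(
    counts: Sequence[float] | Mapping[str, float],
    lengths_mb: Sequence[float] | Mapping[str, float],
) -> RegressionFit:
    """OLS of per-chromosome SNP count on chromosome length (Mb).

    Mappings are aligned on their shared keys (sorted); sequences must be
    parallel. Requires n >= 3 and non-degenerate lengths.
    """
    if isinstance(counts, Mapping) and isinstance(lengths_mb, Mapping):
        keys = sorted(set(counts) & set(lengths_mb))
        y = np.array([counts[k] for k in keys], dtype=float)
        x = np.array([lengths_mb[k] for k in keys], dtype=float)
    else:
        y = np.asarray(list(counts), dtype=float)
        x = np.asarray(list(lengths_mb), dtype=float)
    if len(x) != len(y):
        raise ValueError("counts and lengths differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 chromosomes to fit")
    if np.ptp(x) == 0:
        raise ValueError("zero length variance; slope undefined")
    if np.ptp(y) == 0:
        # constant response: the mean explains everything, the slope nothing
        return RegressionFit(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                             p_value=1.0, n=len(x))
    model = sm.OLS(y, sm.add_constant(x)).fit()
    p_value = float(model.pvalues[1])
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=1.0 if np.isnan(p_value) else p_value,
        n=len(x),
    )


@dataclass
class Dendrogram:
    """An agglomerative clustering of labelled scalar values.

    ``labels`` is the observation order handed to the linkage (sorted
    label order, the deterministic tie-break); ``leaf_order`` the induced
    left-to-right leaf sequence, which untangling may rotate without
    changing the merge structure.
    """

    labels: list[str]
    linkage: np.ndarray
    leaf_order: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        return rec(tree) + ";"


def build_dendrogram(values: Mapping[str, float]) -> Dendrogram:
    """Average-linkage clustering on absolute value differences."""
    if len(values) < 2:
        raise ValueError("need at least 2 labels to cluster")
    labels = sorted(values)
    x = np.array([[values[l]] for l in labels], dtype=float)
    Z = hierarchy.linkage(pdist(x, metric="cityblock"), method="average")
    order = [labels[i] for i in hierarchy.leaves_list(Z)]
    return Dendrogram(labels=labels, linkage=Z, leaf_order=order)


@dataclass(frozen=True)
class EntanglementScore:
    """Normalized leaf-order disagreement between two dendrograms."""

    value: float
    L: float
    untangled: bool = False


def _entanglement_value(order1: Sequence[str], order2: Sequence[str], L: float) -> float:
    if set(order1) != set(order2):
        raise ValueError("dendrograms must share the same label set")
    n = len(order1)
    if n < 2:
        return 0.0
    rank2 = {label: i for i, label in enumerate(order2)}
    diffs = np.array([abs(i - rank2[label]) for i, label in enumerate(order1)], dtype=float)
    worst = np.abs(np.arange(n) - np.arange(n)[::-1]).astype(float)
    denom = float(np.sum(worst ** L))
    return float(np.sum(diffs ** L) / denom)


def entanglement(d1: Dendrogram, d2: Dendrogram, L: float = 1.5) -> EntanglementScore:
    """Entanglement of two dendrograms over the same labels.

    Sum of |rank difference|^L across labels, normalized by the value an
    exactly reversed ordering would give; L defaults to 1.5, the usual
    tanglegram convention.
    """
    return EntanglementScore(value=_entanglement_value(d1.leaf_order, d2.leaf_order, L), L=L)


# ---------------------------------------------------------------------------
# greedy untangling
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("left", "right", "label")

    def __init__(self, label=None, left=None, right=None):
        self.label = label
        self.left = left
        self.right = right

    def leaves(self) -> list[str]:
        if self.label is not None:
            return [self.label]
        return self.left.leaves() + self.right.leaves()

    def internal_nodes(self) -> list["_Node"]:
        if self.label is not None:
            return []
        return [self] + self.left.internal_nodes() + self.right.internal_nodes()


def _build_tree(d: Dendrogram) -> _Node:
    root = hierarchy.to_tree(d.linkage)
    # rotate children to reproduce d.leaf_order (it may differ from the raw
    # scipy order after a previous untangling pass)
    position = {label: i for i, label in enumerate(d.leaf_order)}

    def rec(node) -> _Node:
        if node.is_leaf():
            return _Node(label=d.labels[node.id])
        left, right = rec(node.left), rec(node.right)
        if min(position[l] for l in left.leaves()) > min(position[l] for l in right.leaves()):
            left, right = right, left
        return _Node(left=left, right=right)

    return rec(root)


def untangle(
    d1: Dendrogram, d2: Dendrogram, L: float = 1.5, max_passes: int = 10
) -> tuple[Dendrogram, Dendrogram, EntanglementScore]:
    """Greedy subtree rotations that never increase entanglement.

    Repeatedly tries flipping each internal node of either tree, keeping a
    flip only when the entanglement strictly decreases; stops at a fixed
    point (idempotent on an optimum). Returns rotated copies plus the
    resulting score.
    """
    t1, t2 = _build_tree(d1), _build_tree(d2)
    best = _entanglement_value(t1.leaves(), t2.leaves(), L)
    for _ in range(max_passes):
        improved = False
        for tree in (t1, t2):
            for node in tree.internal_nodes():
                node.left, node.right = node.right, node.left
                score = _entanglement_value(t1.leaves(), t2.leaves(), L)
                if score < best:
                    best = score
                    improved = True
                else:
                    node.left, node.right = node.right, node.left
        if not improved:
            break
    out1 = replace(d1, leaf_order=t1.leaves())
    out2 = replace(d2, leaf_order=t2.leaves())
    return out1, out2, EntanglementScore(value=best, L=L, untangled=True)
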