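"""Phylogenetic independent contrasts and contrasts-based PLS.

Felsenstein's contrasts provide an independent route to the same
evolutionary covariance structure as the GLS estimator: on a fully
bifurcating tree the N-1 standardized contrasts X satisfy
``X'X / (N-1) = R`` exactly, so a two-block PLS of the contrast
cross-products must return the same r_PLS as the GLS-based analysis.
This module implements that route, both as a method in its own right and
as the cross-check for the GLS implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .pls import (
    DegenerateBlockError,
    PLSResult,
    _p_value,
    _permutation_indices,
    decompose_cross_block,
    partition,
)
from .tree import BlockSpec, PhyloError, PhyloTree, TraitMatrix

__all__ = ["ContrastSet", "PolytomyError", "compute_contrasts", "pic_pls"]


class PolytomyError(PhyloError):
    """Independent contrasts require a strictly bifurcating tree."""


@dataclass(frozen=True)
class ContrastSet:
    """(N-1) x p matrix of standardized contrasts, one row per internal node."""

    X: np.ndarray
    node_ids: tuple[str, ...]


def compute_contrasts(tree: PhyloTree, traits: TraitMatrix) -> ContrastSet:
    """Felsenstein's pruning algorithm.

    At each internal node with child values x1, x2 on (adjusted) branch
    lengths v1, v2 the standardized contrast is ``(x1 - x2) / sqrt(v1 + v2)``,
    the ancestral value is the precision-weighted mean
    ``(x1/v1 + x2/v2) / (1/v1 + 1/v2)``, and the node's own branch is
    extended by ``v1 v2 / (v1 + v2)``.  Rows of the trait matrix are matched
    to tips by label; contrast order is the tree's post-order.
    """
    tips = set(tree.tip_labels)
    rows = set(traits.row_labels)
    if tips != rows:
        raise PhyloError(
            f"tree tips and trait rows differ: only in tree "
            f"{sorted(tips - rows)}, only in traits {sorted(rows - tips)}"
        )
    row_of = {label: i for i, label in enumerate(traits.row_labels)}
    Y = traits.values

    values: dict[int, np.ndarray] = {}
    vlen: dict[int, float] = {}
    contrasts: list[np.ndarray] = []
    node_ids: list[str] = []
    k = 0
    for node in tree.dtree.postorder_node_iter():
        if node.is_leaf():
            values[id(node)] = Y[row_of[node.taxon.label]]
            vlen[id(node)] = float(node.edge.length)
            continue
        children = node.child_nodes()
        if len(children) != 2:
            names = ", ".join(
                PhyloTree._node_name(c) for c in children
            )
            raise PolytomyError(
                f"node with {len(children)} children (subtending: {names}); "
                "independent contrasts require a strictly bifurcating tree"
            )
        c1, c2 = children
        x1, x2 = values.pop(id(c1)), values.pop(id(c2))
        v1, v2 = vlen.pop(id(c1)), vlen.pop(id(c2))
        if v1 + v2 <= 0:
            raise PhyloError(
                "non-positive contrast variance at an internal node "
                "(zero-length sister branches)"
            )
        contrasts.append((x1 - x2) / np.sqrt(v1 + v2))
        node_ids.append(node.label or f"node{k}")
        k += 1
        values[id(node)] = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2)
        edge = node.edge.length if node.edge.length is not None else 0.0
        vlen[id(node)] = edge + v1 * v2 / (v1 + v2)
    return ContrastSet(X=np.vstack(contrasts), node_ids=tuple(node_ids))


def _contrast_rpls(
    X: np.ndarray, i1: np.ndarray, i2: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """r_PLS from a contrast matrix: cross-products about zero, N-1 denominator."""
    m = X.shape[0]  # N - 1 contrasts
    R12 = X[:, i1].T @ X[:, i2] / m
    axes, sing = decompose_cross_block(R12)
    s1 = X[:, i1] @ axes.U[:, 0]
    s2 = X[:, i2] @ axes.V[:, 0]
    den = np.sqrt((s1 @ s1) * (s2 @ s2))
    if den == 0 or sing.d[0] <= 0:
        raise DegenerateBlockError("degenerate contrast block: r_PLS undefined")
    return float(s1 @ s2 / den), s1, s2, sing.d


def pic_pls(
    tree: PhyloTree,
    traits: TraitMatrix,
    blocks: BlockSpec,
    n_permutations: int = 999,
    seed: int = 0,
) -> PLSResult:
    """Two-block PLS on independent contrasts with a tip-permutation test.

    Contrast cross-products are taken about zero (contrasts have
    expectation zero under Brownian motion) with the N-1 denominator, so
    the covariance blocks equal the GLS evolutionary covariance exactly and
    the observed r_PLS matches the GLS-based analysis to machine precision.
    The permutation test mirrors the GLS-based one in spirit: under the
    Brownian null the standardized contrasts are the exchangeable units, so
    each iteration shuffles the block-2 contrast rows and recomputes the
    cross-products, SVD, scores and correlation.
    """
    blocks.validate_for(traits.p)
    if n_permutations < 1:
        raise PhyloError("n_permutations must be >= 1")
    if not tree.is_bifurcating():
        raise PolytomyError(
            "independent contrasts require a strictly bifurcating tree"
        )
    order = tuple(sorted(tree.tip_labels))
    traits = traits.reordered(order)
    i1 = np.asarray(blocks.block1)
    i2 = np.asarray(blocks.block2)

    # a rooted bifurcating N-tip tree yields exactly N-1 contrasts, so the
    # N-1 denominator below is the contrast count as well
    X = compute_contrasts(tree, traits).X
    r_obs, s1, s2, _ = _contrast_rpls(X, i1, i2)

    idx = _permutation_indices(X.shape[0], n_permutations, seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        Xp = X.copy()
        Xp[:, i2] = X[idx[b]][:, i2]
        try:
            null[b], *_ = _contrast_rpls(Xp, i1, i2)
        except DegenerateBlockError:
            null[b] = np.nan
    axes, sing = decompose_cross_block(X[:, i1].T @ X[:, i2] / (traits.n - 1))
    return PLSResult(
        axes=axes,
        singular_values=sing,
        scores1=s1,
        scores2=s2,
        r_pls=r_obs,
        p_value=_p_value(null, r_obs),
        null_distribution=null,
        n_permutations=n_permutations,
        seed=seed,
        method="contrasts",
        taxon_order=order,
    )
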