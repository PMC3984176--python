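"""Trees, trait tables, and the phylogenetic covariance matrix.

This module handles the inputs of a phylogenetic partial-least-squares
analysis: a rooted phylogeny with branch lengths (Newick), a species-by-trait
table of continuous values (delimited text), and the assignment of trait
columns to the two blocks being compared.  It also builds the N x N
phylogenetic covariance matrix ``C`` whose entries are shared root-to-MRCA
path lengths — the expected among-species trait covariance structure under
Brownian motion.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloTree",
    "PhyloCovariance",
    "TraitMatrix",
    "BlockSpec",
    "read_newick",
    "tree_to_C",
    "read_trait_table",
    "write_trait_table",
    "align",
    "PhyloError",
    "NewickError",
    "MissingBranchLengthError",
    "DuplicateTipError",
    "TaxonMismatchError",
]


class PhyloError(ValueError):
    """Base class for input-validation failures."""


class NewickError(PhyloError):
    """The Newick source could not be parsed into a valid tree."""


class MissingBranchLengthError(NewickError):
    """The tree contains edges without branch lengths."""


class DuplicateTipError(NewickError):
    """Two or more tips share the same label."""


class TaxonMismatchError(PhyloError):
    """Tree tips and trait-table rows do not describe the same taxa."""


@dataclass(frozen=True)
class PhyloTree:
    """A rooted phylogeny with branch lengths.

    Thin wrapper around a :class:`dendropy.Tree` that guarantees the
    invariants the downstream estimators rely on: a single root, unique
    non-empty tip labels, and a branch length on every non-root edge.
    Polytomies are allowed (the GLS machinery does not require a
    bifurcating tree; only the independent-contrasts oracle does).
    """

    dtree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = []
        for leaf in self.dtree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon is not None else None
            if not label:
                raise NewickError("tree contains an unlabeled tip")
            labels.append(label)
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        if dupes:
            raise DuplicateTipError(f"duplicate tip labels: {dupes}")
        root = self.dtree.seed_node
        missing = []
        nonneg_zero = False
        for node in self.dtree.preorder_node_iter():
            if node is root:
                continue
            length = node.edge.length
            if length is None:
                missing.append(self._node_name(node))
            elif length < 0:
                raise NewickError(
                    f"negative branch length {length} on edge to {self._node_name(node)}"
                )
            elif length == 0:
                nonneg_zero = True
        if missing:
            raise MissingBranchLengthError(
                f"edges without branch lengths above: {missing}"
            )
        if nonneg_zero:
            warnings.warn(
                "tree contains zero-length branches; the phylogenetic "
                "covariance matrix may be singular",
                UserWarning,
                stacklevel=2,
            )

    @staticmethod
    def _node_name(node: dendropy.Node) -> str:
        if node.taxon is not None and node.taxon.label:
            return node.taxon.label
        if node.label:
            return node.label
        return "<internal node>"

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(
            leaf.taxon.label for leaf in self.dtree.leaf_node_iter()
        )

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.dtree.leaf_node_iter())

    def is_bifurcating(self) -> bool:
        """True when every internal node (including the root) has exactly
        two children."""
        for node in self.dtree.preorder_internal_node_iter():
            if len(node.child_nodes()) != 2:
                return False
        return True

    def newick(self) -> str:
        return self.dtree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


def read_newick(path_or_text: str) -> PhyloTree:
    """Parse a Newick tree from a file path or a literal Newick string.

    A string containing ``(`` is treated as Newick text; anything else is
    taken to be a path.  Quoted labels and square-bracket comments are
    tolerated; internal node labels are ignored; polytomies are preserved.
    """
    if "(" in path_or_text:
        source = {"data": path_or_text}
    else:
        if not os.path.exists(path_or_text):
            raise NewickError(f"no such tree file: {path_or_text}")
        source = {"path": path_or_text}
    try:
        dtree = dendropy.Tree.get(
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            **source,
        )
    except Exception as exc:  # dendropy raises schema-specific error types
        msg = str(exc)
        if "Multiple occurrences" in msg or "duplicate" in msg.lower():
            raise DuplicateTipError(f"malformed Newick: {msg}") from exc
        raise NewickError(f"malformed Newick: {msg}") from exc
    return PhyloTree(dtree)


@dataclass(frozen=True)
class PhyloCovariance:
    """The N x N phylogenetic covariance matrix C.

    ``C[i, i]`` is the root-to-tip path length of taxon *i*;
    ``C[i, j]`` is the path length from the root to the most recent common
    ancestor of taxa *i* and *j*.  Under Brownian motion, trait values at
    the tips are distributed with among-species covariance proportional
    to C.
    """

    C: np.ndarray
    taxon_order: tuple[str, ...]

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise PhyloError("C must be square")
        if C.shape[0] != len(self.taxon_order):
            raise PhyloError("taxon_order length must match C")
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "taxon_order", tuple(self.taxon_order))

    @property
    def n(self) -> int:
        return self.C.shape[0]


def tree_to_C(
    tree: PhyloTree, taxon_order: Sequence[str] | None = None
) -> PhyloCovariance:
    """Build the phylogenetic covariance matrix from a tree.

    Rows/columns follow ``taxon_order`` when given (must be a permutation
    of the tip labels), otherwise the tree's own leaf order.
    """
    tips = tree.tip_labels
    if taxon_order is None:
        taxon_order = tips
    else:
        unknown = sorted(set(taxon_order) - set(tips))
        if unknown:
            raise TaxonMismatchError(f"taxa not in tree: {unknown}")
        if len(taxon_order) != len(tips) or set(taxon_order) != set(tips):
            raise TaxonMismatchError(
                "taxon_order must be a permutation of the tip labels"
            )
    index = {label: i for i, label in enumerate(taxon_order)}
    n = len(taxon_order)
    C = np.zeros((n, n))

    # Depth of every node from the root (the root's own edge, if any, is
    # ignored: a shared root edge would only add a constant to C).
    depth: dict[int, float] = {id(tree.dtree.seed_node): 0.0}
    for node in tree.dtree.preorder_node_iter():
        if node is tree.dtree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + node.edge.length

    # Post-order sweep: tips under each internal node; every cross-child
    # tip pair has that node as its MRCA.
    tips_below: dict[int, list[int]] = {}
    for node in tree.dtree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            C[i, i] = depth[id(node)]
            tips_below[id(node)] = [i]
            continue
        children = node.child_nodes()
        groups = [tips_below.pop(id(c)) for c in children]
        d = depth[id(node)]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for i in groups[gi]:
                    for j in groups[gj]:
                        C[i, j] = C[j, i] = d
        tips_below[id(node)] = [i for g in groups for i in g]
    return PhyloCovariance(C=C, taxon_order=tuple(taxon_order))


@dataclass(frozen=True)
class TraitMatrix:
    """An N x p table of continuous trait values, row-labeled by species."""

    values: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise PhyloError("trait values must be a 2-D matrix")
        n, p = values.shape
        if n < 2 or p < 1:
            raise PhyloError(f"need at least 2 species and 1 trait, got {n}x{p}")
        if not np.all(np.isfinite(values)):
            raise PhyloError("trait matrix contains missing/non-finite values")
        if len(self.row_labels) != n or len(self.col_labels) != p:
            raise PhyloError("label lengths must match value shape")
        if len(set(self.row_labels)) != n:
            raise PhyloError("duplicate species labels in trait matrix")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "row_labels", tuple(str(r) for r in self.row_labels))
        object.__setattr__(self, "col_labels", tuple(str(c) for c in self.col_labels))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TraitMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            row_labels=tuple(str(i) for i in df.index),
            col_labels=tuple(str(c) for c in df.columns),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.row_labels), columns=list(self.col_labels)
        )

    def reordered(self, row_order: Sequence[str]) -> "TraitMatrix":
        index = {label: i for i, label in enumerate(self.row_labels)}
        unknown = sorted(set(row_order) - set(self.row_labels))
        if unknown or len(row_order) != self.n:
            raise TaxonMismatchError(f"unknown or incomplete row order: {unknown}")
        idx = [index[label] for label in row_order]
        return TraitMatrix(
            values=self.values[idx], row_labels=tuple(row_order),
            col_labels=self.col_labels,
        )


def read_trait_table(path: str, delimiter: str = ",") -> TraitMatrix:
    """Read a delimited trait table: header row, first column = species."""
    df = pd.read_csv(path, sep=delimiter, index_col=0, float_precision="round_trip")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise PhyloError(f"empty trait table: {path}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise PhyloError(f"non-numeric cell in trait table {path}: {exc}") from exc
    if np.isnan(values).any():
        bad = df.index[np.isnan(values).any(axis=1)].tolist()
        raise PhyloError(f"missing trait values for species: {bad}")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise PhyloError(f"duplicate species in trait table: {dupes}")
    return TraitMatrix.from_dataframe(df)


def write_trait_table(traits: TraitMatrix, path: str, delimiter: str = ",") -> None:
    traits.to_dataframe().to_csv(path, sep=delimiter, index_label="species")


@dataclass(frozen=True)
class BlockSpec:
    """Assignment of trait columns to the two PLS blocks.

    Blocks are disjoint, non-empty ordered sets of 0-based column indices.
    The union need not exhaust all columns, but leaving columns out is
    unusual for an integration analysis and triggers a warning at
    validation time.
    """

    block1: tuple[int, ...]
    block2: tuple[int, ...]

    def __post_init__(self) -> None:
        b1 = tuple(int(i) for i in self.block1)
        b2 = tuple(int(i) for i in self.block2)
        if not b1 or not b2:
            raise PhyloError("both blocks must be non-empty")
        if len(set(b1)) != len(b1) or len(set(b2)) != len(b2):
            raise PhyloError("repeated column index within a block")
        if set(b1) & set(b2):
            raise PhyloError(f"blocks overlap: columns {sorted(set(b1) & set(b2))}")
        if min(b1 + b2) < 0:
            raise PhyloError("negative column index")
        object.__setattr__(self, "block1", b1)
        object.__setattr__(self, "block2", b2)

    def validate_for(self, p: int) -> None:
        out = sorted(i for i in self.block1 + self.block2 if i >= p)
        if out:
            raise PhyloError(f"block column indices out of range (p={p}): {out}")
        if len(self.block1) + len(self.block2) < p:
            warnings.warn(
                "block specification does not cover all trait columns",
                UserWarning,
                stacklevel=2,
            )

    def swapped(self) -> "BlockSpec":
        return BlockSpec(block1=self.block2, block2=self.block1)

    @classmethod
    def halves(cls, p: int) -> "BlockSpec":
        """First half of the columns vs the second half (p must be even)."""
        if p % 2:
            raise PhyloError(f"cannot split {p} columns into equal halves")
        return cls(block1=tuple(range(p // 2)), block2=tuple(range(p // 2, p)))

    @classmethod
    def from_names(
        cls,
        names1: Iterable[str],
        names2: Iterable[str],
        col_labels: Sequence[str],
    ) -> "BlockSpec":
        index = {label: i for i, label in enumerate(col_labels)}
        def look(names: Iterable[str]) -> tuple[int, ...]:
            missing = [n for n in names if n not in index]
            if missing:
                raise PhyloError(f"unknown trait columns: {missing}")
            return tuple(index[n] for n in names)
        return cls(block1=look(list(names1)), block2=look(list(names2)))

    @staticmethod
    def _parse_one(text: str, col_labels: Sequence[str] | None) -> tuple[int, ...]:
        cols: list[int] = []
        for token in text.split(","):
            token = token.strip()
            if not token:
                continue
            if "-" in token and all(
                part.strip().isdigit() for part in token.split("-", 1)
            ):
                lo, hi = (int(part) for part in token.split("-", 1))
                cols.extend(range(lo, hi + 1))
            elif token.isdigit():
                cols.append(int(token))
            else:
                if col_labels is None or token not in col_labels:
                    raise PhyloError(f"unknown trait column: {token!r}")
                cols.append(list(col_labels).index(token))
        return tuple(cols)

    @classmethod
    def parse(
        cls, spec1: str, spec2: str, col_labels: Sequence[str] | None = None
    ) -> "BlockSpec":
        """Parse block specs like ``"0-2"``, ``"0,1,2"`` or ``"snoutX,snoutY"``."""
        return cls(
            block1=cls._parse_one(spec1, col_labels),
            block2=cls._parse_one(spec2, col_labels),
        )


def align(tree: PhyloTree, traits: TraitMatrix) -> tuple[PhyloCovariance, TraitMatrix]:
    """Match tree tips with trait rows and fix one canonical taxon order.

    The canonical order is the lexicographic sort of the labels, so every
    downstream statistic is independent of the order in which species
    appear in the input files.
    """
    tips = set(tree.tip_labels)
    rows = set(traits.row_labels)
    missing_traits = sorted(tips - rows)
    missing_tips = sorted(rows - tips)
    if missing_traits or missing_tips:
        parts = []
        if missing_traits:
            parts.append(f"tips without trait rows: {missing_traits}")
        if missing_tips:
            parts.append(f"trait rows without tips: {missing_tips}")
        raise TaxonMismatchError("; ".join(parts))
    order = tuple(sorted(tips))
    return tree_to_C(tree, order), traits.reordered(order)
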