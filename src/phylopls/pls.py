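"""Two-block partial least squares on (evolutionary) covariance matrices.

The statistic of interest is r_PLS: the correlation between the first pair
of PLS score vectors obtained from the singular-value decomposition of the
cross-block covariance matrix.  In the phylogenetic version the covariance
matrix is the GLS evolutionary rate matrix R and the scores are projections
of the phylogenetically transformed data Y_phy; in the ordinary
(ahistorical) version it is the sample covariance matrix S of column-mean
centered data.

Scores are deviations from the fitted mean (the GLS root state in the
phylogenetic case, the column mean in the ordinary case), so r_PLS is the
correlation of the score vectors about the origin:
``r = s1's2 / sqrt(s1's1 * s2's2)``.  Because ``s1's2/(N-1)`` equals the
leading singular value of the cross block, r_PLS is non-negative whenever
the blocks covary at all; for ordinary PLS the scores are mean-zero and
this coincides with the Pearson correlation.  Defining the correlation
about the origin also makes the method agree exactly with its
independent-contrasts counterpart, whose contrast scores likewise have
expectation zero under Brownian motion.

Significance is assessed by phylogenetic permutation.  Under the Brownian
null the exchangeable units are not the raw tip values — those are
correlated through the phylogenetic covariance matrix C — but the rows of
the transformed data Y_phy, which are independent and identically
distributed when the null of no between-block covariation holds.  Each
iteration therefore shuffles the species rows of the transformed block-2
data, then recomputes the cross-block covariance, its SVD, the scores and
their correlation.  (Shuffling raw values across the tips instead would
destroy the phylogenetic correlation structure in the permuted datasets
and grossly inflate the Type I error of the test.)  The observed value is
included in the null (add-one rule), so
``p = (#{r_perm >= r_obs} + 1) / (n_permutations + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evolcov import (
    EvolCovariance,
    gls_weights,
    phylo_transform_matrix,
)
from .tree import (
    BlockSpec,
    PhyloCovariance,
    PhyloError,
    PhyloTree,
    TraitMatrix,
    align,
)

__all__ = [
    "SingularValues",
    "PLSAxes",
    "PLSResult",
    "DegenerateBlockError",
    "ordinary_pls",
    "partition",
    "decompose_cross_block",
    "phylo_pls",
    "permutation_test",
]


class DegenerateBlockError(PhyloError):
    """A block carries no (cross-)variance, so r_PLS is undefined."""


@dataclass(frozen=True)
class SingularValues:
    """Singular values of the cross block: covariances between paired PLS axes."""

    d: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "d", np.asarray(self.d, dtype=float))


@dataclass(frozen=True)
class PLSAxes:
    """Left/right singular vectors: per-block loadings of the PLS axes."""

    U: np.ndarray  # p1 x k
    V: np.ndarray  # p2 x k


@dataclass(frozen=True)
class PLSResult:
    """Outcome of a two-block PLS analysis with a permutation test."""

    axes: PLSAxes
    singular_values: SingularValues
    scores1: np.ndarray
    scores2: np.ndarray
    r_pls: float
    p_value: float
    null_distribution: np.ndarray
    n_permutations: int
    seed: int
    method: str
    taxon_order: tuple[str, ...] = ()

    def summary(self) -> str:
        lines = [
            f"two-block PLS ({self.method})",
            f"r_PLS   = {self.r_pls:.6f}",
            f"P_rand  = {self.p_value:.6f}  "
            f"({self.n_permutations} permutations, seed {self.seed})",
            "singular values: "
            + " ".join(f"{v:.6g}" for v in self.singular_values.d),
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Per-observation first-axis scores as a data frame."""
        index = list(self.taxon_order) if self.taxon_order else None
        return pd.DataFrame(
            {"scores1": self.scores1, "scores2": self.scores2}, index=index
        )


def partition(
    R: EvolCovariance | np.ndarray, blocks: BlockSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a covariance matrix into within- and cross-block parts.

    Returns ``(R11, R12, R22)`` where R12 has shape p1 x p2.
    """
    M = R.R if isinstance(R, EvolCovariance) else np.asarray(R, dtype=float)
    blocks.validate_for(M.shape[0])
    i1 = np.asarray(blocks.block1)
    i2 = np.asarray(blocks.block2)
    return M[np.ix_(i1, i1)], M[np.ix_(i1, i2)], M[np.ix_(i2, i2)]


def decompose_cross_block(R12: np.ndarray) -> tuple[PLSAxes, SingularValues]:
    """SVD of the cross-block covariance, with a deterministic sign convention.

    Within each left singular vector the entry of largest magnitude is made
    positive (ties broken by lowest index) and the paired right vector is
    flipped with it, so axes are reproducible across platforms while every
    product U diag(d) V' is untouched.
    """
    R12 = np.asarray(R12, dtype=float)
    if not np.all(np.isfinite(R12)):
        raise PhyloError("cross-block matrix contains non-finite entries")
    U, d, Vt = np.linalg.svd(R12, full_matrices=False)
    V = Vt.T
    for k in range(U.shape[1]):
        j = int(np.argmax(np.abs(U[:, k])))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
            V[:, k] = -V[:, k]
    return PLSAxes(U=U, V=V), SingularValues(d=d)


# ---------------------------------------------------------------------------
# statistic engine (shared by the ordinary and phylogenetic variants)

def _permutation_indices(n: int, n_permutations: int, seed: int) -> np.ndarray:
    """The permutation stream: (n_permutations, n) row indices for block 2."""
    rng = np.random.default_rng(seed)
    return np.stack([rng.permutation(n) for _ in range(n_permutations)])


def _null_rpls(
    Z1: np.ndarray, Z2: np.ndarray, n_permutations: int, seed: int
) -> np.ndarray:
    """Null r_PLS values: block-2 rows of the transformed data shuffled.

    For each permutation the cross-block covariance, its SVD, the scores
    and their correlation are recomputed from scratch (vectorized over
    permutations).
    """
    n = Z1.shape[0]
    idx = _permutation_indices(n, n_permutations, seed)
    Z2p = Z2[idx]                                      # (B, n, p2)
    R12 = np.einsum("ni,bnj->bij", Z1, Z2p) / (n - 1)  # (B, p1, p2)
    U, _, Vt = np.linalg.svd(R12)
    s1 = Z1 @ U[:, :, 0].T                             # (n, B)
    s2 = np.einsum("bnj,bj->bn", Z2p, Vt[:, 0, :])     # (B, n)
    num = np.einsum("nb,bn->b", s1, s2)
    den = np.sqrt(np.einsum("nb,nb->b", s1, s1) * np.einsum("bn,bn->b", s2, s2))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)


def _p_value(null: np.ndarray, observed: float) -> float:
    return (int(np.sum(null >= observed)) + 1) / (null.size + 1)


def _observed_rpls(
    Z1: np.ndarray, Z2: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, PLSAxes, SingularValues]:
    n = Z1.shape[0]
    axes, sing = decompose_cross_block(Z1.T @ Z2 / (n - 1))
    if sing.d[0] <= 0:
        raise DegenerateBlockError(
            "cross-block covariance is zero; r_PLS is undefined"
        )
    s1 = Z1 @ axes.U[:, 0]
    s2 = Z2 @ axes.V[:, 0]
    den = np.sqrt((s1 @ s1) * (s2 @ s2))
    if den == 0:
        raise DegenerateBlockError("a block has zero variance after centering")
    return float(s1 @ s2 / den), s1, s2, axes, sing


def _single_pls(
    Z: np.ndarray,
    blocks: BlockSpec,
    n_permutations: int,
    seed: int,
    method: str,
    taxon_order: tuple[str, ...],
) -> PLSResult:
    Z1 = Z[:, np.asarray(blocks.block1)]
    Z2 = Z[:, np.asarray(blocks.block2)]
    r_obs, s1, s2, axes, sing = _observed_rpls(Z1, Z2)
    null = _null_rpls(Z1, Z2, n_permutations, seed)
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
        method=method,
        taxon_order=taxon_order,
    )


# ---------------------------------------------------------------------------
# public operations

def ordinary_pls(
    traits: TraitMatrix,
    blocks: BlockSpec,
    n_permutations: int = 999,
    seed: int = 0,
) -> PLSResult:
    """Ahistorical two-block PLS on the ordinary sample covariance matrix.

    Columns are mean-centered; S uses the N-1 denominator.  The permutation
    test shuffles the species rows of the centered block-2 data (with no
    phylogeny the centered rows are the exchangeable units; shuffling raw
    rows and re-centering would give the same null, as column means are
    permutation-invariant).
    """
    blocks.validate_for(traits.p)
    if traits.n < 3:
        raise PhyloError("need at least 3 observations")
    if n_permutations < 1:
        raise PhyloError("n_permutations must be >= 1")
    Yc = traits.values - traits.values.mean(axis=0)
    return _single_pls(
        Yc, blocks, n_permutations, seed, "ordinary", traits.row_labels
    )


def phylo_pls(
    traits: TraitMatrix,
    tree: PhyloTree,
    blocks: BlockSpec,
    n_permutations: int = 999,
    seed: int = 0,
) -> PLSResult:
    """Phylogenetic two-block PLS with a phylogenetic permutation test.

    Pipeline: C from the tree -> GLS root mean -> evolutionary covariance R
    -> partition -> SVD of R12 -> projection of Y_phy onto the first axis
    pair -> r_PLS -> permutation p-value (block-2 rows of Y_phy shuffled).
    Taxa are aligned (and sorted) internally, so input row order never
    matters.  Deterministic given ``seed``.
    """
    blocks.validate_for(traits.p)
    if traits.n < 3:
        raise PhyloError("need at least 3 species")
    if n_permutations < 1:
        raise PhyloError("n_permutations must be >= 1")
    C, traits = align(tree, traits)
    w = gls_weights(C)
    D = phylo_transform_matrix(C).D
    Z = D @ (traits.values - w @ traits.values)
    return _single_pls(
        Z, blocks, n_permutations, seed, "phylogenetic", traits.row_labels
    )


def permutation_test(
    traits: TraitMatrix,
    C: PhyloCovariance,
    blocks: BlockSpec,
    observed: float,
    n_permutations: int,
    seed: int,
) -> tuple[float, np.ndarray]:
    """Phylogenetic permutation test for a precomputed observed r_PLS.

    The data are root-centered and projected onto D; each iteration
    shuffles the block-2 rows of the transformed data among species and
    recomputes the cross-block covariance, SVD, scores and correlation.
    Returns ``(p_value, null_distribution)`` with the add-one rule
    ``p = (#{r_perm >= observed} + 1) / (n_permutations + 1)``.
    """
    if n_permutations < 1:
        raise PhyloError("n_permutations must be >= 1")
    blocks.validate_for(traits.p)
    if traits.row_labels != C.taxon_order:
        raise PhyloError("traits and C are not aligned; use phylopls.align first")
    w = gls_weights(C)
    D = phylo_transform_matrix(C).D
    Z = D @ (traits.values - w @ traits.values)
    null = _null_rpls(
        Z[:, np.asarray(blocks.block1)],
        Z[:, np.asarray(blocks.block2)],
        n_permutations,
        seed,
    )
    return _p_value(null, observed), null
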