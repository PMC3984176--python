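"""GLS estimation of the evolutionary covariance matrix under Brownian motion.

Given aligned trait data Y (N species x p traits) and the phylogenetic
covariance matrix C, this module estimates

* the multivariate phylogenetic mean at the root,
  ``a = (1' C^-1 1)^-1 1' C^-1 Y``;
* the unbiased evolutionary (rate) covariance matrix,
  ``R = (Y - 1 a')' C^-1 (Y - 1 a') / (N - 1)``, whose diagonal holds the
  per-dimension Brownian rates and whose off-diagonal entries hold the
  evolutionary covariances between trait dimensions;
* the phylogenetic transformation ``Y_phy = D (Y - 1 a')`` with D the
  symmetric inverse square root of C, which renders species values
  exchangeable under the Brownian model and satisfies
  ``Y_phy' Y_phy / (N - 1) = R`` exactly.

C^-1 is always applied through factorized solves; the only explicitly
formed matrix is D, which is needed for projecting data onto PLS axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .tree import PhyloCovariance, PhyloError, TraitMatrix

__all__ = [
    "PhyloMean",
    "EvolCovariance",
    "PhyloTransform",
    "TransformedTraits",
    "SingularCovarianceError",
    "phylo_mean",
    "evolutionary_covariance",
    "phylo_transform_matrix",
    "phylo_transform",
    "EIGEN_FLOOR",
]

# Relative eigenvalue below which C is declared numerically singular.  No
# automatic regularization: a silent ridge term would change R.
EIGEN_FLOOR = 1e-12


class SingularCovarianceError(PhyloError):
    """C is numerically singular (relative eigenvalue below the floor)."""


@dataclass(frozen=True)
class PhyloMean:
    """Multivariate root-state estimate (length-p vector)."""

    a: np.ndarray


@dataclass(frozen=True)
class EvolCovariance:
    """The p x p evolutionary covariance matrix R (unbiased GLS estimate)."""

    R: np.ndarray

    @property
    def p(self) -> int:
        return self.R.shape[0]


@dataclass(frozen=True)
class PhyloTransform:
    """Symmetric inverse square root of C: D @ D == C^-1."""

    D: np.ndarray
    taxon_order: tuple[str, ...]


@dataclass(frozen=True)
class TransformedTraits:
    """Root-centered, phylogenetically transformed trait values Y_phy."""

    Y_phy: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]


def _check_alignment(traits: TraitMatrix, C: PhyloCovariance) -> None:
    if traits.row_labels != C.taxon_order:
        raise PhyloError(
            "traits and C are not aligned to the same taxon order; "
            "use phylopls.align first"
        )


def _spectral(C: PhyloCovariance) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of C with the singularity guard applied."""
    lam, E = np.linalg.eigh(C.C)
    if lam[0] <= EIGEN_FLOOR * lam[-1] or lam[-1] <= 0:
        raise SingularCovarianceError(
            f"phylogenetic covariance matrix is numerically singular "
            f"(eigenvalue range [{lam[0]:.3e}, {lam[-1]:.3e}])"
        )
    return lam, E


def gls_weights(C: PhyloCovariance) -> np.ndarray:
    """Row-weight vector w with w' Y = phylogenetic mean; w = C^-1 1 / (1' C^-1 1)."""
    lam, E = _spectral(C)
    ones = np.ones(C.n)
    cinv_one = E @ ((E.T @ ones) / lam)
    return cinv_one / (ones @ cinv_one)


def phylo_mean(traits: TraitMatrix, C: PhyloCovariance) -> PhyloMean:
    """GLS estimate of the multivariate trait value at the root."""
    _check_alignment(traits, C)
    return PhyloMean(a=gls_weights(C) @ traits.values)


def evolutionary_covariance(
    traits: TraitMatrix,
    C: PhyloCovariance,
    mean: PhyloMean | None = None,
) -> EvolCovariance:
    """Unbiased estimate of the Brownian-motion rate matrix R.

    ``R = (Y - 1 a')' C^-1 (Y - 1 a') / (N - 1)``.  On a star tree
    (C proportional to the identity) this reduces to the ordinary sample
    covariance matrix.
    """
    _check_alignment(traits, C)
    if traits.n < 3:
        raise PhyloError(f"need at least 3 species to estimate R, got {traits.n}")
    lam, E = _spectral(C)
    if mean is None:
        mean = phylo_mean(traits, C)
    Yc = traits.values - mean.a
    W = E.T @ Yc                      # rotate into the eigenbasis of C
    R = (W.T / lam) @ W / (traits.n - 1)
    return EvolCovariance(R=(R + R.T) / 2.0)


def phylo_transform_matrix(C: PhyloCovariance) -> PhyloTransform:
    """Symmetric inverse square root D = E diag(lambda^-1/2) E' of C = E diag(lambda) E'."""
    lam, E = _spectral(C)
    D = (E / np.sqrt(lam)) @ E.T
    return PhyloTransform(D=(D + D.T) / 2.0, taxon_order=C.taxon_order)


def phylo_transform(
    traits: TraitMatrix,
    C: PhyloCovariance,
    mean: PhyloMean | None = None,
) -> TransformedTraits:
    """Project root-centered data onto D: Y_phy = D (Y - 1 a')."""
    _check_alignment(traits, C)
    if mean is None:
        mean = phylo_mean(traits, C)
    D = phylo_transform_matrix(C).D
    return TransformedTraits(
        Y_phy=D @ (traits.values - mean.a),
        row_labels=traits.row_labels,
        col_labels=traits.col_labels,
    )
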