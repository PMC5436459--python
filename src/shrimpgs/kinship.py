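"""Marker-based relationship matrices.

``grm_vanraden`` builds the additive genomic relationship matrix (VanRaden
method 1) used for REML heritability and GBLUP; ``ibs_matrix`` builds the
identity-by-state kinship used for the stratification assessment. Both are
n x n over individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import GenotypeMatrix


@dataclass
class GRM:
    """Additive genomic relationship matrix with its scaling metadata."""

    individual_ids: list[str]
    values: np.ndarray
    allele_frequencies: np.ndarray
    denominator: float

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class IBSMatrix:
    """Proportion of alleles shared identical by state, in [0, 1]."""

    individual_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("IBS matrix must be symmetric")
        if v.min() < -1e-10 or v.max() > 1 + 1e-10:
            raise ValueError("IBS entries must lie in [0, 1]")


def grm_vanraden(genotypes: GenotypeMatrix) -> GRM:
    """VanRaden method-1 GRM with sample-estimated allele frequencies.

    Z is the dosage matrix with column j centred by 2 p_j; the matrix is
    Z Z' / (2 sum_j p_j (1 - p_j)). Fractional (imputed) dosages are
    accepted; monomorphic markers contribute nothing to either term.
    """
    genotypes.require_complete("GRM")
    X = genotypes.dosages
    p = X.mean(axis=0) / 2.0
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all markers monomorphic: GRM denominator is zero")
    Z = X - 2.0 * p
    G = (Z @ Z.T) / denom
    G = (G + G.T) / 2.0  # enforce exact symmetry against rounding
    return GRM(
        individual_ids=list(genotypes.individual_ids),
        values=G,
        allele_frequencies=p,
        denominator=denom,
    )


def ibs_matrix(genotypes: GenotypeMatrix) -> IBSMatrix:
    """Mean allele-sharing 1 - |d_i - d_k| / 2 over pairwise-complete markers.

    Dosages must be integral (compute before fractional imputation, or round
    first); markers missing in either member of a pair are skipped for that
    pair.
    """
    d = genotypes.dosages
    vals = d[~np.isnan(d)]
    if vals.size and not np.allclose(vals, np.round(vals)):
        raise ValueError("IBS requires integral dosages (use pre-imputation calls)")
    # indicator matmuls: sum_j |d_i - d_k| decomposes over genotype classes
    A = [((d == c) & ~np.isnan(d)).astype(float) for c in (0.0, 1.0, 2.0)]
    called = (~np.isnan(d)).astype(float)
    pairs = called @ called.T  # pairwise-complete marker counts
    absdiff = (
        2.0 * (A[0] @ A[2].T + A[2] @ A[0].T)
        + (A[0] @ A[1].T + A[1] @ A[0].T)
        + (A[1] @ A[2].T + A[2] @ A[1].T)
    )
    if (pairs == 0).any():
        raise ValueError("some individual pairs share no called markers")
    S = 1.0 - absdiff / (2.0 * pairs)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return IBSMatrix(individual_ids=list(genotypes.individual_ids), values=S)
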