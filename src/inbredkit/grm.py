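"""SNP-by-SNP genomic inbreeding: F_HOM, VanRaden's G and the hybrid H.

* ``f_hom`` is the method-of-moments excess-homozygosity coefficient
  (observed minus expected homozygote count over markers an individual
  was called at, with the small-sample n/(n-1) correction on expected
  heterozygosity).
* ``vanraden_G`` builds G = Z Z' / (2 sum p(1-p)) with Z centred at twice
  the in-sample allele frequency; the diagonal minus one is F_G.
* ``hybrid_H`` blends G into the pedigree numerator relationship matrix
  via the single-step construction, with tau/omega weighting of the
  genotyped block; the diagonal minus one for genotyped individuals is
  F_H.

No MAF or LD pruning is applied anywhere: allele frequencies are always
the in-sample frequencies over non-missing calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenotypeMatrix

__all__ = ["f_hom", "vanraden_G", "f_g", "HybridMatrixParams", "hybrid_H", "f_h"]


def f_hom(gm: GenotypeMatrix) -> pd.Series:
    """Excess-homozygosity inbreeding, one value per individual.

    F_HOM_i = (O_i - E_i) / (L_i - E_i) where O_i counts observed
    homozygous markers among i's non-missing calls, E_i sums the expected
    homozygote probability 1 - 2 p_j (1-p_j) n_j/(n_j-1) over the same
    markers, and L_i is the number of such markers.  Markers informative
    for nobody (fewer than two called individuals) are skipped.  An
    individual whose markers are all monomorphic has L = E; the value is
    then undefined and reported as NaN with a warning.
    """
    if gm.n_individuals < 2:
        raise ValueError("f_hom needs at least two individuals for sample frequencies")
    g = gm.geno
    p = gm.allele_freq
    n = gm.n_called
    valid = n >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        exp_het = 2.0 * p * (1.0 - p) * n / np.maximum(n - 1, 1)
    exp_hom = 1.0 - exp_het
    use = (g >= 0) & valid[None, :]
    O = (use & ((g == 0) | (g == 2))).sum(axis=1).astype(float)
    E = use @ np.where(valid, exp_hom, 0.0)
    L = use.sum(axis=1).astype(float)
    denom = L - E
    out = np.full(gm.n_individuals, np.nan)
    ok = np.abs(denom) > 1e-12
    out[ok] = (O[ok] - E[ok]) / denom[ok]
    if not ok.all():
        warnings.warn("f_hom undefined for individuals with only monomorphic markers; "
                      "reported as NaN")
    return pd.Series(out, index=gm.ids, name="F_HOM")


def vanraden_G(gm: GenotypeMatrix) -> np.ndarray:
    """VanRaden's first genomic relationship matrix.

    Z_ij = x_ij - 2 p_j with missing calls imputed at 2 p_j (zero
    contribution); the denominator 2 sum p_j(1-p_j) runs over polymorphic
    markers only.
    """
    g = gm.geno.astype(float)
    p = gm.allele_freq
    poly = (p > 0) & (p < 1)
    if not np.any(poly):
        raise ValueError("all markers monomorphic: G undefined")
    x = np.where(g >= 0, g, 2.0 * p[None, :])
    Z = (x - 2.0 * p[None, :])[:, poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    return (Z @ Z.T) / denom


def f_g(gm: GenotypeMatrix) -> pd.Series:
    """Genomic inbreeding from the diagonal of G: F_G = G_ii - 1."""
    G = vanraden_G(gm)
    return pd.Series(np.diag(G) - 1.0, index=gm.ids, name="F_G")


@dataclass
class HybridMatrixParams:
    """Weights for the single-step H construction.

    ``blend_alpha`` regularises G toward the pedigree block,
    G* = (1 - alpha) G + alpha A22; ``tau`` and ``omega`` weight the
    genomic and pedigree information of the genotyped block through
    G(tau, omega) = inv(tau inv(G*) + (1 - omega) inv(A22)).
    """

    tau: float = 1.0
    omega: float = 1.0
    blend_alpha: float = 0.05

    def __post_init__(self):
        if self.tau <= 0 or self.omega <= 0:
            raise ValueError("tau and omega must be positive")
        if not (0.0 <= self.blend_alpha < 1.0):
            raise ValueError("blend_alpha must be in [0, 1)")


def _inv(M: np.ndarray, name: str) -> np.ndarray:
    try:
        return np.linalg.inv(M)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular {name} block in hybrid H") from exc


def hybrid_H(A: np.ndarray, G: np.ndarray, genotyped: np.ndarray,
             params: HybridMatrixParams | None = None) -> np.ndarray:
    """Single-step relationship matrix combining pedigree A and genomic G.

    ``genotyped`` holds the indices (into A) of genotyped individuals, in
    the row order of G.  With Delta = G(tau, omega) - A22:

        H = A + [ A12 A22^-1 Delta A22^-1 A21   A12 A22^-1 Delta ]
                [ Delta A22^-1 A21              Delta            ]

    so H = A exactly when G(tau, omega) = A22.
    """
    params = params or HybridMatrixParams()
    genotyped = np.asarray(genotyped, dtype=np.int64)
    n = A.shape[0]
    if A.shape != (n, n):
        raise ValueError("A must be square")
    if G.shape != (len(genotyped), len(genotyped)):
        raise ValueError("G dimension must match the genotyped index set")
    A22 = A[np.ix_(genotyped, genotyped)]
    Gstar = (1.0 - params.blend_alpha) * G + params.blend_alpha * A22
    A22inv = _inv(A22, "A22")
    if params.tau == 1.0 and params.omega == 1.0:
        Gtw = Gstar
    else:
        Gtw = _inv(params.tau * _inv(Gstar, "G*") + (1.0 - params.omega) * A22inv,
                   "tau/omega-weighted G")
    delta = Gtw - A22
    rest = np.setdiff1d(np.arange(n), genotyped)
    H = A.copy()
    A12 = A[np.ix_(rest, genotyped)]
    B = A12 @ A22inv          # (n-m) x m
    H[np.ix_(rest, rest)] += B @ delta @ B.T
    cross = B @ delta
    H[np.ix_(rest, genotyped)] += cross
    H[np.ix_(genotyped, rest)] += cross.T
    H[np.ix_(genotyped, genotyped)] += delta
    return H


def f_h(A: np.ndarray, G: np.ndarray, genotyped: np.ndarray, ids,
        params: HybridMatrixParams | None = None) -> pd.Series:
    """F_H = H_ii - 1 for the genotyped individuals."""
    H = hybrid_H(A, G, genotyped, params)
    genotyped = np.asarray(genotyped, dtype=np.int64)
    vals = np.diag(H)[genotyped] - 1.0
    idx = [ids[i] for i in genotyped]
    return pd.Series(vals, index=idx, name="F_H")
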