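"""Genome-wide unified additive relationships (UAR), their principal
components, and Horn's parallel analysis for component retention.

The UAR matrix is the SNP-based relationship estimator of Yang et al.'s
unified additive model: for animals j != k,

    A_jk = (1/N) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

and on the diagonal

    A_jj = 1 + (1/N) sum_i (x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2)
                              / (2 p_i (1 - p_i)),

with x in {0,1,2} copies of the reference allele and p_i the sample allele
frequency unless supplied.  Its leading principal components enter the
mapping model as fixed covariates to absorb population stratification; the
number retained is chosen by Horn's parallel analysis on the eigenvalue
spectrum of UAR matrices rebuilt from column-permuted genotypes (or set
explicitly via configuration).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_qc import MISSING

logger = logging.getLogger(__name__)


@dataclass
class UARMatrix:
    values: np.ndarray
    animals: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries in UAR matrix")


@dataclass
class PcSet:
    eigenvalues: np.ndarray   # descending
    components: np.ndarray    # n x k, unit-norm eigenvectors
    k_retained: int | None = None


def _prep(genotypes, allele_freqs):
    x = np.asarray(genotypes, dtype=float)
    miss = x == MISSING
    if allele_freqs is None:
        nonmiss = (~miss).sum(axis=0)
        if np.any(nonmiss == 0):
            raise ValueError("SNP with no observed genotypes")
        p = np.where(miss, 0.0, x).sum(axis=0) / (2 * nonmiss)
    else:
        p = np.asarray(allele_freqs, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic SNP (p in {0,1}); pre-filter the input")
    x = np.where(miss, 2 * p, x)  # mean imputation for relationship building
    return x, p


def uar_matrix(genotypes, allele_freqs=None, animals=None) -> UARMatrix:
    """Unified additive relationship matrix from 0/1/2 genotype dosages.

    Missing genotypes are imputed to ``2 p_i`` for this computation only.
    """
    x, p = _prep(genotypes, allele_freqs)
    n, m = x.shape
    denom = 2 * p * (1 - p)
    w = (x - 2 * p) / np.sqrt(denom)
    a = (w @ w.T) / m
    diag = 1 + ((x ** 2 - (1 + 2 * p) * x + 2 * p ** 2) / denom).mean(axis=1)
    a[np.diag_indices(n)] = diag
    return UARMatrix(a, animals)


def pca(uar: UARMatrix, tol: float = 1e-8) -> PcSet:
    """Eigendecomposition of the UAR matrix, eigenvalues descending."""
    a = uar.values if isinstance(uar, UARMatrix) else np.asarray(uar, float)
    if not np.allclose(a, a.T, atol=tol):
        raise ValueError("input matrix is not symmetric")
    vals, vecs = np.linalg.eigh(a)
    order = np.argsort(vals)[::-1]
    return PcSet(vals[order], vecs[:, order])


def horn_retain(genotypes, n_perm: int, percentile: float = 95.0,
                seed=None) -> int:
    """Horn's parallel analysis on the UAR eigenvalue spectrum.

    Each SNP's genotype column is permuted independently across animals
    ``n_perm`` times; the UAR matrix and its spectrum are rebuilt for each
    replicate.  A component is retained when its observed eigenvalue
    exceeds the given percentile of the permuted eigenvalues at the same
    rank; the retained count is returned.
    """
    if n_perm < 30:
        raise ValueError("n_perm must be at least 30 for stable percentiles")
    x = np.asarray(genotypes)
    n = x.shape[0]
    if n < 3:
        raise ValueError("parallel analysis needs at least 3 animals")
    rng = np.random.default_rng(seed)
    observed = np.sort(np.linalg.eigvalsh(uar_matrix(x).values))[::-1]
    null = np.empty((n_perm, n))
    for r in range(n_perm):
        perm = np.argsort(rng.random(x.shape), axis=0)
        xp = np.take_along_axis(x, perm, axis=0)
        null[r] = np.sort(np.linalg.eigvalsh(uar_matrix(xp).values))[::-1]
    cutoff = np.percentile(null, percentile, axis=0)
    retained = int(np.sum(observed > cutoff))
    logger.info("parallel analysis: %d of %d components retained "
                "(%d permutations, %gth percentile)", retained, n,
                n_perm, percentile)
    return retained
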