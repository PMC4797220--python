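"""Sliding-window locus-IBD probabilities and diplotype relationship
matrices.

At the midpoint of every window of 40 consecutive SNPs, the probability
that two haplotypes are identical by descent (*LocIBD*) is estimated from
the identity-by-state (IBS) of the flanking markers with a two-hypothesis
closed form.  Let phi = 1 - (1 - 1/(2 Ne))^T be the prior IBD probability
for two haplotypes T generations from a base population of effective size
Ne.  For a pair of haplotypes, let L and R be the lengths of the maximal
runs of IBS markers immediately left and right of the midpoint, d the
genetic length (Morgans) spanned by those runs on both sides combined,
and c the probability of the observed IBS run arising by chance, i.e. the
product of the population homozygosities h_i = f_i^2 + (1 - f_i)^2 over
the run markers.  Then

    p = phi * s / (phi * s + (1 - phi) * c),      s = exp(-2 T d),

which equals phi with no IBS evidence and approaches 1 as an unbroken IBS
run extends over a dense map.  This estimator is a documented, pluggable
stand-in for published multi-marker IBD recursions: it reproduces their
qualitative behaviour from the same ingredients (prior, recombination
survival, chance IBS).

LocIBD matrices are converted to diplotype relationship matrices (DRM):
for animals j != k with haplotypes (j1, j2), (k1, k2),

    D_jk = (M[j1,k1] + M[j1,k2] + M[j2,k1] + M[j2,k2]) / 2,
    D_jj = 1 + M[j1,j2],

the per-locus analogue of an additive genomic relationship matrix, which
enters the mixed model as the covariance of the random QTL effect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io_qc import HaplotypePanel, MarkerMap, MISSING

logger = logging.getLogger(__name__)


@dataclass
class IbdParams:
    """Base-population parameters of the IBD prior.

    Defaults (Ne=100, T=10) give phi ~ 0.049, typical for a livestock
    population mapped a few generations from an admixed base.
    """

    ne: float = 100.0
    t: float = 10.0

    def __post_init__(self):
        if self.ne <= 0 or self.t <= 0:
            raise ValueError("Ne and T must be positive")

    @property
    def phi(self) -> float:
        return 1.0 - (1.0 - 1.0 / (2.0 * self.ne)) ** self.t


@dataclass
class Window:
    index: int
    snp_span: tuple          # (first_snp_idx, last_snp_idx), inclusive
    midpoint_bp: int
    midpoint_morgans: float

    @property
    def size(self) -> int:
        return self.snp_span[1] - self.snp_span[0] + 1


def make_windows(marker_map: MarkerMap, size: int = 40,
                 step: int = 1) -> list[Window]:
    """All sliding windows of ``size`` consecutive SNPs.

    The midpoint sits between the two central SNPs of the span (SNPs 20
    and 21 of a 40-SNP window): floor of the mean of their bp positions,
    arithmetic mean of their genetic positions.
    """
    m = marker_map.n_snps
    if m < size:
        raise ValueError(f"map has {m} SNPs, fewer than window size {size}")
    half = size // 2
    out = []
    for w, start in enumerate(range(0, m - size + 1, step)):
        left, right = start + half - 1, start + half
        out.append(Window(
            index=w, snp_span=(start, start + size - 1),
            midpoint_bp=int((int(marker_map.bp[left])
                             + int(marker_map.bp[right])) // 2),
            midpoint_morgans=(marker_map.morgans[left]
                              + marker_map.morgans[right]) / 2.0))
    return out


def locibd_pair(hap_a, hap_b, window: Window, marker_map: MarkerMap,
                freqs, params: IbdParams) -> float:
    """Locus-IBD probability for one haplotype pair at a window midpoint.

    Reference scalar implementation of the closed form; the matrix builder
    vectorises the same computation.  Haplotypes must be non-missing
    within the window (impute upstream).
    """
    s0, s1 = window.snp_span
    a = np.asarray(hap_a)[s0:s1 + 1]
    b = np.asarray(hap_b)[s0:s1 + 1]
    if np.any(a == MISSING) or np.any(b == MISSING):
        raise ValueError("missing allele inside window; impute first")
    f = np.asarray(freqs)[s0:s1 + 1]
    h = f ** 2 + (1 - f) ** 2
    half = window.size // 2
    eq = a == b
    # run immediately left of the midpoint (markers half-1 .. 0)
    L = 0
    while L < half and eq[half - 1 - L]:
        L += 1
    R = 0
    while R < half and eq[half + R]:
        R += 1
    d = 0.0
    c = 1.0
    mid = window.midpoint_morgans
    if L > 0:
        d += mid - marker_map.morgans[s0 + half - L]
        c *= float(np.prod(h[half - L:half]))
    if R > 0:
        d += marker_map.morgans[s0 + half - 1 + R] - mid
        c *= float(np.prod(h[half:half + R]))
    s = math.exp(-2.0 * params.t * d)
    phi = params.phi
    return phi * s / (phi * s + (1 - phi) * c)


@dataclass
class LocIBDMatrix:
    values: np.ndarray   # 2n x 2n, unit diagonal

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] % 2:
            raise ValueError("LocIBD matrix must be square with even size")
        self.values = v


def locibd_matrix(panel: HaplotypePanel, window: Window,
                  marker_map: MarkerMap, params: IbdParams,
                  freqs=None) -> LocIBDMatrix:
    """Locus-IBD probabilities for all haplotype pairs of a phased panel."""
    if not panel.phased:
        raise ValueError("panel must be phased")
    s0, s1 = window.snp_span
    hap = panel.alleles[:, s0:s1 + 1]
    if np.any(hap == MISSING):
        raise ValueError("missing alleles inside window; impute first")
    if freqs is None:
        freqs_w = panel.alleles[:, s0:s1 + 1].mean(axis=0)
        freqs_w = np.clip(freqs_w, 1e-6, 1 - 1e-6)
    else:
        freqs_w = np.asarray(freqs)[s0:s1 + 1]
    h = freqs_w ** 2 + (1 - freqs_w) ** 2
    half = window.size // 2
    if half > 62:
        raise ValueError("window size above 124 SNPs not supported")
    H = hap.shape[0]
    mid = window.midpoint_morgans
    mo = marker_map.morgans

    # IBS run length outward from the midpoint = index of the lowest set
    # bit of the XOR of bit-packed half-window haplotypes (bit 0 nearest
    # the midpoint)
    def runs(order):
        weights = np.int64(1) << np.arange(len(order), dtype=np.int64)
        packed = hap[:, order].astype(np.int64) @ weights
        x = packed[:, None] ^ packed[None, :]
        run = np.full((H, H), half, dtype=np.int64)
        nz = x != 0
        low = (x & -x)[nz].astype(np.float64)
        run[nz] = np.log2(low).astype(np.int64)
        return run

    L = runs(np.arange(half - 1, -1, -1))
    R = runs(np.arange(half, 2 * half))
    # distance and chance-IBS lookups indexed by run length
    dl = np.concatenate(([0.0], [mid - mo[s0 + half - k]
                                 for k in range(1, half + 1)]))
    dr = np.concatenate(([0.0], [mo[s0 + half - 1 + k] - mid
                                 for k in range(1, half + 1)]))
    cl = np.concatenate(([1.0], np.cumprod(h[half - 1::-1])))
    cr = np.concatenate(([1.0], np.cumprod(h[half:])))
    d = dl[L] + dr[R]
    c = cl[L] * cr[R]
    s = np.exp(-2.0 * params.t * d)
    phi = params.phi
    p = phi * s / (phi * s + (1 - phi) * c)
    np.fill_diagonal(p, 1.0)
    return LocIBDMatrix(p)


@dataclass
class DRM:
    """Diplotype relationship matrix at one window midpoint."""

    values: np.ndarray
    ridge: float = 0.0   # diagonal ridge added for positive definiteness


def drm_from_locibd(m: LocIBDMatrix, repair: bool = True,
                    min_eig: float = 1e-6) -> DRM:
    """Convert a LocIBD matrix into a diplotype relationship matrix.

    If ``repair`` and the smallest eigenvalue is below ``min_eig``, a
    minimal diagonal ridge is added (and logged) so the matrix can serve
    as a covariance in REML.
    """
    v = m.values if isinstance(m, LocIBDMatrix) else np.asarray(m, float)
    if v.shape[0] % 2:
        raise ValueError("odd row count")
    n = v.shape[0] // 2
    blocks = v.reshape(n, 2, n, 2)
    d = blocks.sum(axis=(1, 3)) / 2.0
    diag = 1.0 + v[np.arange(0, 2 * n, 2), np.arange(1, 2 * n, 2)]
    d[np.diag_indices(n)] = diag
    ridge = 0.0
    if repair:
        lam_min = float(np.linalg.eigvalsh(d)[0])
        if lam_min < min_eig:
            ridge = min_eig - lam_min
            d[np.diag_indices(n)] += ridge
            logger.debug("DRM ridge %.3e added (lambda_min=%.3e)",
                         ridge, lam_min)
    return DRM(d, ridge)
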