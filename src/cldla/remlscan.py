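"""REML variance-component scan: mixed-model fits at window midpoints,
likelihood-ratio test profile, Bonferroni threshold and LOD support
intervals.

Model at each tested position p:

    y = X beta + Z q + e,     q ~ N(0, D_p sigma_q^2),  e ~ N(0, I sigma_e^2)

with y the encoded phenotypes, X the fixed-effects design (overall mean
plus retained principal components), Z the identity (one record per
animal) and D_p the diplotype relationship matrix at p.  Writing
gamma = sigma_q^2 / sigma_e^2, the restricted log-likelihood profiles to

    l_R(gamma) = -1/2 [ (n - p) log sigmahat_e^2(gamma) + log|I + gamma D|
                        + log|X' (I + gamma D)^{-1} X| + (n - p) ],

where sigmahat_e^2(gamma) is the generalised residual sum of squares
divided by n - p.  The same constant convention is used under the null
(gamma = 0), so constants cancel in

    LRT = -2 (l_H0 - l_H1) = 2 (l_H1 - l_H0) >= 0.

The LRT is referred to a chi-square distribution with one degree of
freedom, the convention used for this scan; because sigma_q^2 is
boundary-constrained the true null is a 50:50 mixture of chi2_0 and
chi2_1, so thresholds on the chi2_1 scale are conservative.  Support
intervals around peaks use the LOD drop-off rule with 1 LOD = 2 ln 10 =
4.60517 LRT units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_qc import HaplotypePanel, MarkerMap
from .locibd import DRM, IbdParams, drm_from_locibd, locibd_matrix, make_windows

logger = logging.getLogger(__name__)

LOD_UNIT = 2.0 * np.log(10.0)  # 4.60517... LRT units per LOD


@dataclass
class RemlFit:
    sigma_q2: float
    sigma_e2: float
    loglik: float
    converged: bool = True

    def __post_init__(self):
        if not (np.isfinite(self.loglik) and np.isfinite(self.sigma_e2)):
            raise ValueError("non-finite REML fit")
        if self.sigma_q2 < 0:
            raise ValueError("negative sigma_q2")


def _design(y, x):
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    if n != y.size:
        raise ValueError("X and y dimensions disagree")
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("X is singular (rank-deficient fixed effects)")
    return y, x, n, p


def _profile_loglik(gamma, lam, yt, xt, n, p):
    """Restricted log-likelihood at gamma on the eigenbasis of D."""
    w = 1.0 / (1.0 + gamma * lam)
    xw = xt * w[:, None]
    a = xt.T @ xw                       # X' V^-1 X
    b = xw.T @ yt
    try:
        beta = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular GLS system: {e}") from e
    rss = float(yt @ (w * yt) - b @ beta)
    if rss <= 0:
        raise ValueError("zero generalised residual variance "
                         "(y in the span of X)")
    sigma_e2 = rss / (n - p)
    logdet_v = float(np.sum(np.log1p(gamma * lam)))
    sign, logdet_a = np.linalg.slogdet(a)
    if sign <= 0:
        raise ValueError("non-positive-definite GLS normal equations")
    ll = -0.5 * ((n - p) * np.log(sigma_e2) + logdet_v + logdet_a + (n - p))
    return ll, sigma_e2


def _profile_loglik_batch(gammas, lam, yt, xt, n, p):
    """Vectorised l_R over a gamma grid (same arithmetic as the scalar path)."""
    w = 1.0 / (1.0 + gammas[:, None] * lam[None, :])       # G x n
    xw = xt[None, :, :] * w[:, :, None]                    # G x n x p
    a = np.swapaxes(xw, 1, 2) @ xt[None, :, :]             # X' W X per gamma
    b = (w * yt) @ xt                                      # G x p
    beta = np.linalg.solve(a, b[..., None])[..., 0]
    rss = (w * yt ** 2).sum(axis=1) - (b * beta).sum(axis=1)
    sign, logdet_a = np.linalg.slogdet(a)
    logdet_v = np.log1p(gammas[:, None] * lam[None, :]).sum(axis=1)
    out = np.full(gammas.size, -np.inf)
    ok = (rss > 0) & (sign > 0)
    out[ok] = -0.5 * ((n - p) * np.log(rss[ok] / (n - p)) + logdet_v[ok]
                      + logdet_a[ok] + (n - p))
    if not ok.any():
        raise ValueError("restricted likelihood undefined on the whole grid")
    return out


def restricted_loglik(y, x, d, gamma: float) -> float:
    """Evaluate l_R at a given variance ratio gamma = sigma_q^2/sigma_e^2."""
    y, x, n, p = _design(y, x)
    lam, u = np.linalg.eigh(np.asarray(d, dtype=float))
    ll, _ = _profile_loglik(gamma, lam, u.T @ y, u.T @ x, n, p)
    return ll


def null_fit(y, x) -> RemlFit:
    """Closed-form null model (no QTL): ordinary least squares."""
    y, x, n, p = _design(y, x)
    if n <= p:
        raise ValueError("need n > rank(X)")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    rss = float(resid @ resid)
    if rss <= max(1e-12, 1e-12 * float(y @ y)):
        raise ValueError("zero residual variance (y in the span of X)")
    sigma_e2 = rss / (n - p)
    sign, logdet_a = np.linalg.slogdet(x.T @ x)
    ll = -0.5 * ((n - p) * np.log(sigma_e2) + logdet_a + (n - p))
    return RemlFit(0.0, sigma_e2, ll)


def reml_fit(y, x, d, gamma_grid=None, tol: float = 1e-6,
             min_eig: float = 1e-6) -> RemlFit:
    """Maximise the restricted log-likelihood over gamma >= 0.

    A log-spaced grid over gamma in [1e-6, 1e3] (boundary gamma=0 always
    evaluated) is refined by golden-section search to relative tolerance
    ``tol``.  ``d`` may be a DRM or a raw covariance matrix; eigenvalues
    below ``min_eig`` are lifted, the per-window analogue of the DRM
    diagonal ridge.
    """
    y, x, n, p = _design(y, x)
    if n <= p:
        raise ValueError("need n > rank(X)")
    dm = d.values if isinstance(d, DRM) else np.asarray(d, dtype=float)
    lam, u = np.linalg.eigh(dm)
    if lam[0] < min_eig:
        lam = lam + (min_eig - lam[0])
    yt, xt = u.T @ y, u.T @ x

    if gamma_grid is None:
        gamma_grid = np.concatenate(([0.0], np.logspace(-6, 3, 46)))
    lls = _profile_loglik_batch(np.asarray(gamma_grid), lam, yt, xt, n, p)
    best = int(np.argmax(lls))

    if best == 0:
        gamma_hat = 0.0
    else:
        lo = gamma_grid[max(best - 1, 1)]
        hi = gamma_grid[min(best + 1, len(gamma_grid) - 1)]
        if hi <= lo:
            gamma_hat = gamma_grid[best]
        else:
            # golden-section on log(gamma)
            a, b = np.log(lo), np.log(hi)
            invphi = (np.sqrt(5) - 1) / 2
            c, dd = b - invphi * (b - a), a + invphi * (b - a)
            fc = _profile_loglik(np.exp(c), lam, yt, xt, n, p)[0]
            fd = _profile_loglik(np.exp(dd), lam, yt, xt, n, p)[0]
            while (b - a) > tol:
                if fc > fd:
                    b, dd, fd = dd, c, fc
                    c = b - invphi * (b - a)
                    fc = _profile_loglik(np.exp(c), lam, yt, xt, n, p)[0]
                else:
                    a, c, fc = c, dd, fd
                    dd = a + invphi * (b - a)
                    fd = _profile_loglik(np.exp(dd), lam, yt, xt, n, p)[0]
            gamma_hat = float(np.exp((a + b) / 2))
            # keep the grid optimum if refinement did not help
            if _profile_loglik(gamma_hat, lam, yt, xt, n, p)[0] < lls[best]:
                gamma_hat = float(gamma_grid[best])
    ll, sigma_e2 = _profile_loglik(gamma_hat, lam, yt, xt, n, p)
    return RemlFit(gamma_hat * sigma_e2, sigma_e2, ll)


@dataclass
class ScanResult:
    table: pd.DataFrame   # window_index, midpoint_bp, LRT, sigma_q2, sigma_e2,
    #                       loglik_H1, loglik_H0
    windows: list = field(default_factory=list)

    def peak(self):
        t = self.table.dropna(subset=["LRT"])
        row = t.loc[t["LRT"].idxmax()]
        return int(row["midpoint_bp"]), float(row["LRT"])


def lrt_scan(panel: HaplotypePanel, marker_map: MarkerMap, y, x,
             params: IbdParams | None = None, size: int = 40, step: int = 1,
             freqs=None, windows=None) -> ScanResult:
    """LRT profile over all sliding-window midpoints.

    The null fit does not depend on the window and is computed once.
    Windows whose fit fails are recorded with missing LRT and the scan
    continues.
    """
    params = params or IbdParams()
    if windows is None:
        windows = make_windows(marker_map, size=size, step=step)
    h0 = null_fit(y, x)
    if freqs is None:
        freqs = np.clip(panel.alleles.mean(axis=0), 1e-6, 1 - 1e-6)
    rows = []
    for w in windows:
        try:
            m = locibd_matrix(panel, w, marker_map, params, freqs=freqs)
            d = drm_from_locibd(m, repair=False)
            fit = reml_fit(y, x, d)
            lrt = max(0.0, 2.0 * (fit.loglik - h0.loglik))
            rows.append((w.index, w.midpoint_bp, lrt, fit.sigma_q2,
                         fit.sigma_e2, fit.loglik, h0.loglik))
        except ValueError as e:
            logger.warning("window %d (midpoint %d bp) failed: %s",
                           w.index, w.midpoint_bp, e)
            rows.append((w.index, w.midpoint_bp, np.nan, np.nan, np.nan,
                         np.nan, h0.loglik))
    table = pd.DataFrame(rows, columns=["window_index", "midpoint_bp", "LRT",
                                        "sigma_q2", "sigma_e2", "loglik_H1",
                                        "loglik_H0"])
    return ScanResult(table, list(windows))


def significance_threshold(alpha_total: float, n_tests: int) -> float:
    """Bonferroni-corrected chi2(1 df) LRT threshold."""
    if not (0 < alpha_total < 1):
        raise ValueError("alpha_total must be in (0,1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(stats.chi2.isf(alpha_total / n_tests, df=1))


@dataclass
class SupportInterval:
    peak_bp: int
    peak_lrt: float
    lower_bp: int
    upper_bp: int
    drop_lod: float = 2.0

    def __post_init__(self):
        if not (self.lower_bp <= self.peak_bp <= self.upper_bp):
            raise ValueError("peak outside its support interval")

    @property
    def width_bp(self) -> int:
        return self.upper_bp - self.lower_bp


def lod_ci(scan: ScanResult, threshold: float,
           drop_lod: float = 2.0) -> list[SupportInterval]:
    """LOD drop-off support intervals around scan peaks above threshold.

    For each local maximum above ``threshold`` (highest first), the
    interval extends outward through consecutive windows with LRT above
    peak_LRT - drop_lod * 4.60517; one contiguous exceedance region yields
    a single interval around its highest peak, and secondary peaks outside
    any primary interval get their own.  Boundaries are window midpoints.
    """
    t = scan.table.dropna(subset=["LRT"]).reset_index(drop=True)
    if t.empty:
        return []
    lrt = t["LRT"].to_numpy()
    bp = t["midpoint_bp"].to_numpy()
    order = np.argsort(lrt)[::-1]
    claimed = np.zeros(len(t), dtype=bool)
    out = []
    for i in order:
        if lrt[i] <= threshold or claimed[i]:
            continue
        drop_line = lrt[i] - drop_lod * LOD_UNIT
        lo = i
        while lo - 1 >= 0 and lrt[lo - 1] > drop_line:
            lo -= 1
        hi = i
        while hi + 1 < len(t) and lrt[hi + 1] > drop_line:
            hi += 1
        claimed[lo:hi + 1] = True
        out.append(SupportInterval(int(bp[i]), float(lrt[i]),
                                   int(bp[lo]), int(bp[hi]),
                                   drop_lod))
    out.sort(key=lambda s: -s.peak_lrt)
    return out
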