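"""Tail probabilities for quadratic forms in standard normal variables.

The gene-level association statistic is a sum of per-SNP chi-square values
whose null distribution, under LD, is ``Q = sum_i lambda_i * chi2_1`` with
``lambda_i`` the eigenvalues of the SNP correlation matrix R.  P(Q > t) is
evaluated by Imhof's inversion integral

    P(Q > t) = 1/2 + (1/pi) * Int_0^inf sin(theta(u)) / (u * rho(u)) du,
    theta(u) = (1/2) * [sum_i arctan(lambda_i u) - t u],
    rho(u)   = prod_i (1 + lambda_i^2 u^2)^(1/4),

computed with composite Gauss-Legendre panels sized to the oscillation phase,
plus a first-order integration-by-parts correction for the truncated tail.
A three-moment chi-square approximation serves as fallback in the regimes
where the inversion integral is numerically uninformative (near-central t and
p-values beyond the cancellation limit of the 1/2 + integral form).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

EIGEN_TOL = 1e-12
P_FLOOR = 1e-300
P_CEIL = 1.0 - 1e-16

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(12)
_MAX_PANELS = 120_000


def _three_moment_sf(t: float, lam: np.ndarray) -> float:
    """Match the first three cumulants of Q to a scaled, shifted chi-square."""
    c1 = float(np.sum(lam))
    c2 = float(np.sum(lam**2))
    c3 = float(np.sum(lam**3))
    if c3 <= 0.0:
        k = lam.size
        return float(stats.chi2.sf(t / (c1 / k), k))
    nu = c2**3 / c3**2
    x = nu + math.sqrt(2.0 * nu) * (t - c1) / math.sqrt(2.0 * c2)
    return float(stats.chi2.sf(max(x, 0.0), nu))


def _imhof_panels(t: float, lam: np.ndarray, upper: float) -> float:
    """Composite Gauss-Legendre integral of the Imhof integrand on (0, upper]."""
    n_osc = int(0.5 * t * upper / math.pi) + 1
    bp_osc = np.linspace(0.0, upper, min(2 * n_osc, _MAX_PANELS) + 1)
    # log-spaced refinement near the origin where the arctan terms curve
    bp_log = np.geomspace(upper * 1e-8, upper, 120)
    bp = np.unique(np.concatenate([[0.0], bp_osc, bp_log]))
    a, b = bp[:-1], bp[1:]
    mid, half = 0.5 * (a + b), 0.5 * (b - a)
    u = (mid[:, None] + half[:, None] * _GL_NODES[None, :]).ravel()
    lu = u[:, None] * lam[None, :]
    theta = 0.5 * (np.arctan(lu).sum(axis=1) - t * u)
    log_rho = 0.25 * np.log1p(lu * lu).sum(axis=1)
    f = (np.sin(theta) * np.exp(-log_rho) / u).reshape(-1, _GL_NODES.size)
    return float(((f * _GL_WEIGHTS[None, :]).sum(axis=1) * half).sum())


def _imhof_sf(t: float, lam: np.ndarray, epsabs: float = 5e-10) -> float:
    k = lam.size
    log_plam = 0.5 * float(np.sum(np.log(lam)))
    # Truncation point: beyond `upper` the envelope 1/(u^{1+k/2} prod sqrt(lam))
    # times the residual of one integration by parts must be below epsabs.
    # envelope * (2/t)^2 * (1 + k/2) / u  <  epsabs   =>  solve for u.
    c = (2.0 / t) ** 2 * (1.0 + 0.5 * k) / (epsabs * math.exp(log_plam))
    upper = c ** (1.0 / (2.0 + 0.5 * k))
    upper = max(upper, 20.0 / lam.min(), 1.0)

    val = _imhof_panels(t, lam, upper)

    # First-order tail: Int_U^inf g sin(theta) du ~= g(U) cos(theta(U)) / theta'(U)
    lu = lam * upper
    theta_u = 0.5 * (float(np.sum(np.arctan(lu))) - t * upper)
    dtheta_u = 0.5 * (float(np.sum(lam / (1.0 + lu * lu))) - t)
    g_u = math.exp(-0.25 * float(np.sum(np.log1p(lu * lu)))) / upper
    val += g_u * math.cos(theta_u) / dtheta_u

    return 0.5 + val / math.pi


def weighted_chi2_sf(t: float, eigenvalues: np.ndarray) -> tuple[float, str]:
    """P(sum_i lambda_i chi2_1 > t) and the method used ('exact'|'imhof'|'moment').

    Eigenvalues that are negative or negligibly small relative to the largest
    are dropped; a correlation matrix failing positive semidefiniteness beyond
    tolerance must be rejected by the caller.
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))
    lam = lam[lam > EIGEN_TOL * max(lam[-1], 1.0)]
    if lam.size == 0:
        raise ValueError("no positive eigenvalues: degenerate null distribution")
    if t <= 0.0:
        return 1.0, "exact"

    # Equal eigenvalues (R = I up to scale): Q / lambda is exactly chi2_k.
    if np.ptp(lam) <= 1e-10 * lam[-1]:
        p = float(stats.chi2.sf(t / lam.mean(), lam.size))
        return float(np.clip(p, P_FLOOR, P_CEIL)), "exact"

    p = _imhof_sf(t, lam)
    # Below ~1e-8 the 1/2 + integral form loses all relative precision to
    # cancellation; hand the deep tail to the moment approximation.
    if not np.isfinite(p) or p < 1e-8:
        return float(np.clip(_three_moment_sf(t, lam), P_FLOOR, P_CEIL)), "moment"
    return float(np.clip(p, P_FLOOR, P_CEIL)), "imhof"
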