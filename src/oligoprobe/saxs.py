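"""Small-angle X-ray scattering shape analysis.

Implements the standard monodisperse-particle chain: Guinier regression in
the low-q regime (ln I linear in q^2, Rg from the slope), the Kratky
transform q^2*I(q) as a globularity diagnostic, and a Tikhonov-regularized
indirect Fourier transform (IFT) recovering the pair-distance distribution
P(r) together with the real-space radius of gyration.

The IFT solves, on a uniform r-grid with P(0) = P(dmax) = 0 imposed by
basis construction,

    min_p ||(K p - I)/sigma||^2 + alpha ||D2 p||^2,   p >= 0,

where K is the Debye kernel K_ij = 4*pi*dr*sinc(q_i r_j) and D2 the second
difference operator (smoothness prior).  The regularization weight alpha can
be chosen automatically at the corner of the L-curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import nnls

from .datatypes import GuinierFit, PairDistribution, ScatteringCurve

__all__ = [
    "guinier_fit",
    "kratky_transform",
    "ift_pr",
    "dmax_scan",
    "sphere_form_factor",
    "sphere_pair_distribution",
]


def sphere_form_factor(q: np.ndarray, radius: float, i0: float = 1.0) -> np.ndarray:
    """Scattering intensity of a homogeneous sphere of the given radius.

    I(q) = i0 * [3 (sin qR - qR cos qR) / (qR)^3]^2, normalized to i0 at q=0.
    """
    q = np.asarray(q, dtype=float)
    x = q * radius
    with np.errstate(invalid="ignore", divide="ignore"):
        amp = 3.0 * (np.sin(x) - x * np.cos(x)) / x**3
    amp = np.where(x < 1e-6, 1.0 - x**2 / 10.0, amp)
    return i0 * amp**2


def sphere_pair_distribution(r: np.ndarray, radius: float) -> np.ndarray:
    """Analytic (unnormalized) pair-distance distribution of a homogeneous
    sphere: p(r) propto r^2 (1 - 3r/4R + r^3/16R^3) for r <= 2R, else 0."""
    r = np.asarray(r, dtype=float)
    x = r / radius
    p = r**2 * (1.0 - 0.75 * x + x**3 / 16.0)
    return np.where(r <= 2.0 * radius, np.maximum(p, 0.0), 0.0)


def guinier_fit(curve: ScatteringCurve, qrg_limit: float = 1.3) -> GuinierFit:
    """Weighted linear regression of ln I on q^2 over the low-q window.

    The window always starts at the lowest measured q; its upper end is the
    largest index for which the fitted Rg satisfies qmax*Rg <= qrg_limit,
    iterated to self-consistency.  Returns Rg = sqrt(-3*slope), the
    extrapolated forward scattering I(0), and regression diagnostics.
    """
    min_points = 5
    q, i = curve.q, curve.intensity
    sigma = curve.sigma

    best = None
    for end in range(min_points, len(q) + 1):
        qw, iw = q[:end], i[:end]
        if np.any(iw <= 0):
            break
        y = np.log(iw)
        x = qw**2
        if sigma is not None:
            w = (iw / sigma[:end]) ** 2  # ln-transform error propagation
        else:
            w = np.ones_like(x)
        coeffs, cov = np.polyfit(x, y, 1, w=np.sqrt(w), cov=True)
        slope, intercept = coeffs
        if slope >= 0:
            break
        rg = np.sqrt(-3.0 * slope)
        if qw[-1] * rg > qrg_limit:
            continue_ok = False
        else:
            continue_ok = True
        if continue_ok:
            yhat = slope * x + intercept
            ss_res = float(np.sum(w * (y - yhat) ** 2))
            ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
            rg_sd = (
                1.5 / rg * np.sqrt(cov[0, 0]) if np.isfinite(cov[0, 0]) else np.nan
            )
            best = GuinierFit(
                rg=float(rg),
                i0=float(np.exp(intercept)),
                q_range=(float(qw[0]), float(qw[-1])),
                r_squared=float(min(max(r2, 0.0), 1.0)),
                qrg_max=float(qw[-1] * rg),
                n_points=end,
                rg_sd=float(rg_sd),
            )
    if best is None:
        # diagnose: what qmin*Rg does the smallest admissible window give?
        qw, iw = q[:min_points], i[:min_points]
        detail = ""
        if np.all(iw > 0):
            slope = np.polyfit(qw**2, np.log(iw), 1)[0]
            if slope < 0:
                rg = np.sqrt(-3.0 * slope)
                detail = (
                    f"; smallest attainable qmin*Rg = {q[0] * rg:.2f}"
                    f" exceeds the limit {qrg_limit}"
                )
        raise ValueError("no valid Guinier window" + detail)
    return best


def kratky_transform(curve: ScatteringCurve):
    """Kratky transform q^2*I(q) with a globularity verdict.

    Verdict is "bell-shaped" when the transform attains an interior maximum
    and decays below 50% of that maximum at the high-q end (compact
    globule); otherwise "extended" (coil-like plateau or rise).
    Returns (q, q2i, verdict).
    """
    q = curve.q
    q2i = q**2 * curve.intensity
    imax = int(np.argmax(q2i))
    interior = 0 < imax < len(q2i) - 1
    tail = float(np.mean(q2i[max(imax + 1, len(q2i) - max(3, len(q2i) // 10)):]))
    bell = interior and tail < 0.5 * q2i[imax]
    verdict = "bell-shaped" if bell else "extended"
    return q, q2i, verdict


def _ift_design(q: np.ndarray, dmax: float, n_bins: int):
    """Debye kernel on interior r-nodes (endpoints excluded => p(0)=p(dmax)=0)
    and the full second-difference operator including the zero endpoints."""
    r_full = np.linspace(0.0, dmax, n_bins + 1)
    dr = r_full[1] - r_full[0]
    r = r_full[1:-1]
    qr = np.outer(q, r)
    with np.errstate(invalid="ignore", divide="ignore"):
        kernel = 4.0 * np.pi * dr * np.sin(qr) / qr
    kernel = np.where(qr < 1e-12, 4.0 * np.pi * dr, kernel)
    # second differences over [0, p_1 ... p_{n-1}, 0]
    m = r.size
    d2 = np.zeros((m + 2, m))
    for k in range(m + 2):
        for j, off in ((k - 2, 1.0), (k - 1, -2.0), (k, 1.0)):
            if 0 <= j < m:
                d2[k, j] += off
    return r, dr, kernel, d2


def _solve_ift(a_data, b_data, d2, alpha):
    a = np.vstack([a_data, np.sqrt(alpha) * d2])
    b = np.concatenate([b_data, np.zeros(d2.shape[0])])
    p, _ = nnls(a, b)
    resid = a_data @ p - b_data
    return p, float(resid @ resid), float(np.sum((d2 @ p) ** 2))


def ift_pr(
    curve: ScatteringCurve,
    dmax: float,
    n_bins: int = 100,
    alpha: Union[float, str] = "auto",
) -> PairDistribution:
    """Regularized indirect Fourier transform to the pair-distance
    distribution.

    With alpha="auto" the weight is picked at the corner (maximum distance
    from the end-to-end chord in log-log coordinates) of the L-curve traced
    over a log-spaced alpha grid.  rg_real is the second moment
    sqrt(int r^2 p dr / (2 int p dr)); i0 is 4*pi*int p dr.
    """
    if dmax <= 0:
        raise ValueError("dmax must be positive")
    if len(curve) < n_bins // 2:
        raise ValueError("curve has too few points for the requested n_bins")
    q, i = curve.q, curve.intensity
    sigma = curve.sigma if curve.sigma is not None else np.full_like(i, np.max(np.abs(i)) * 0.01)
    r, dr, kernel, d2 = _ift_design(q, dmax, n_bins)
    a_data = kernel / sigma[:, None]
    b_data = i / sigma

    if alpha == "auto":
        alphas = np.logspace(-8, 4, 25) * np.linalg.norm(a_data.T @ a_data) / n_bins
        rho, eta = [], []
        sols = []
        for al in alphas:
            p, rss, pen = _solve_ift(a_data, b_data, d2, al)
            rho.append(max(rss, 1e-300))
            eta.append(max(pen, 1e-300))
            sols.append((al, p, rss))
        lr, le = np.log(rho), np.log(eta)
        # distance from the chord joining the L-curve's endpoints
        v = np.array([lr[-1] - lr[0], le[-1] - le[0]])
        v /= np.linalg.norm(v)
        pts = np.stack([lr - lr[0], le - le[0]], axis=1)
        dist = np.abs(pts[:, 0] * v[1] - pts[:, 1] * v[0])
        best = int(np.argmax(dist))
        alpha_used, p, rss = sols[best]
    else:
        alpha_used = float(alpha)
        p, rss, _ = _solve_ift(a_data, b_data, d2, alpha_used)

    ndof = max(len(q) - 1, 1)
    chi2_red = rss / ndof
    mass = np.sum(p) * dr
    if mass <= 0:
        raise ValueError("IFT produced an identically zero distribution")
    rg_real = float(np.sqrt(np.sum(r**2 * p) / (2.0 * np.sum(p))))
    i0 = float(4.0 * np.pi * mass)

    r_out = np.concatenate([[0.0], r, [dmax]])
    p_out = np.concatenate([[0.0], p, [0.0]])
    return PairDistribution(
        r=r_out,
        p=p_out,
        dmax=float(dmax),
        rg_real=rg_real,
        alpha=float(alpha_used),
        i0=i0,
        chi2_reduced=float(chi2_red),
    )


def dmax_scan(
    curve: ScatteringCurve,
    dmax_grid: Sequence[float],
    n_bins: int = 80,
    alpha: Union[float, str] = "auto",
):
    """One IFT solve per candidate dmax; recommends the smallest dmax whose
    reduced chi^2 lies within 5% of the minimum over the grid.

    Returns (rows, recommended_dmax) where rows is a list of
    (dmax, chi2_reduced, rg_real) tuples.
    """
    grid = list(dmax_grid)
    if any(np.diff(grid) <= 0):
        raise ValueError("dmax grid must be ascending")
    rows = []
    for dm in grid:
        sol = ift_pr(curve, dm, n_bins=n_bins, alpha=alpha)
        rows.append((float(dm), sol.chi2_reduced, sol.rg_real))
    chi2 = np.array([row[1] for row in rows])
    ok = chi2 <= 1.05 * chi2.min()
    recommended = float(np.array(grid)[ok][0])
    # flag solutions whose misfit is grossly above the best one
    return rows, recommended
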