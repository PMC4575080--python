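"""Extended Lipari-Szabo (model-free) backbone 15N relaxation.

Forward computation of R1, R2 and the steady-state 15N{1H}-NOE from an
extended model-free motional model (fast and slow internal motions under
isotropic overall tumbling), solving for the fast/slow order-parameter
split given a total S^2, and extraction of rates from mono-exponential
peak-height decays.

Spectral density (three Lorentzian terms, effective correlation times
tau'_x = tau_x tau_m / (tau_x + tau_m)):

    J(w) = (2/5) [ S2 tau_m /(1+(w tau_m)^2)
                 + (S2f - S2) tau'_s /(1+(w tau'_s)^2)
                 + (1 - S2f)  tau'_f /(1+(w tau'_f)^2) ]

Rates use the standard dipolar + CSA expressions with
d = mu0 hbar gamma_H gamma_N / (4 pi r_NH^3) and c = w_N * dSigma / sqrt(3).
Chemical-exchange (Rex) contributions are deliberately excluded.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

from .constants import ANGSTROM, HBAR, MU0
from .datatypes import (
    DecaySeries,
    MotionModel,
    RelaxationObservables,
    SpinSystemConstants,
)

__all__ = [
    "spectral_density",
    "forward_observables",
    "solve_order_split",
    "fit_decay",
    "noe_from_intensities",
]


def spectral_density(motion: MotionModel, omega: float | np.ndarray) -> np.ndarray:
    """Extended model-free spectral density J(omega) in s/rad."""
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValueError("omega must be nonnegative")
    s2 = motion.s2
    tm = motion.tau_m
    ts_eff = motion.tau_s * tm / (motion.tau_s + tm)
    tf_eff = motion.tau_f * tm / (motion.tau_f + tm)

    def lorentz(tau):
        return tau / (1.0 + (omega * tau) ** 2)

    j = 0.4 * (
        s2 * lorentz(tm)
        + (motion.s2f - s2) * lorentz(ts_eff)
        + (1.0 - motion.s2f) * lorentz(tf_eff)
    )
    return j if j.shape else float(j)


def forward_observables(
    motion: MotionModel, constants: SpinSystemConstants | None = None
) -> RelaxationObservables:
    """R1, R2 (s^-1) and steady-state 15N{1H}-NOE from the motional model."""
    c0 = constants if constants is not None else SpinSystemConstants()
    wh, wn = c0.omega_h, c0.omega_n
    d = MU0 * HBAR * abs(c0.gamma_h * c0.gamma_n) / (4.0 * np.pi * (c0.r_nh * ANGSTROM) ** 3)
    c = wn * c0.csa * 1e-6 / np.sqrt(3.0)

    def j(w):
        return spectral_density(motion, w)

    j0 = j(0.0)
    jn = j(wn)
    jh = j(wh)
    jhmn = j(wh - wn)
    jhpn = j(wh + wn)

    r1 = (d**2 / 4.0) * (jhmn + 3.0 * jn + 6.0 * jhpn) + c**2 * jn
    r2 = (d**2 / 8.0) * (4.0 * j0 + jhmn + 3.0 * jn + 6.0 * jh + 6.0 * jhpn) + (
        c**2 / 6.0
    ) * (4.0 * j0 + 3.0 * jn)
    # gamma_H/gamma_N is negative for 15N, which is what makes large-amplitude
    # fast motion drive the NOE to zero and below
    noe = 1.0 + (c0.gamma_h / c0.gamma_n) * (d**2 / 4.0) * (6.0 * jhpn - jhmn) / r1
    return RelaxationObservables(r1=float(r1), r2=float(r2), noe=float(noe))


def solve_order_split(
    s2_total: float,
    tau_f: float,
    tau_s: float,
    tau_m: float,
    constants: SpinSystemConstants | None = None,
    objective: str = "zero_noe",
    r2_over_r1_target: float | None = None,
    max_abs_noe: float = 0.25,
) -> Tuple[MotionModel, RelaxationObservables]:
    """Factorize a total order parameter S^2 = S2f * S2s.

    The split is under-determined by S^2 alone, so it is solved against an
    observable: "zero_noe" minimizes |NOE|; "joint" minimizes
    |NOE| + |R2/R1 - target| (target required).  Grid search over
    s2f in [s2_total, 1] followed by local refinement.

    Raises if no split reaches |NOE| < max_abs_noe.
    """
    if not (0.0 < s2_total <= 1.0):
        raise ValueError("s2_total must be in (0, 1]")
    if objective not in ("zero_noe", "joint"):
        raise ValueError(f"unknown objective {objective!r}")
    if objective == "joint" and r2_over_r1_target is None:
        raise ValueError("joint objective requires r2_over_r1_target")

    def build(s2f: float) -> MotionModel:
        return MotionModel(
            s2f=s2f, s2s=s2_total / s2f, tau_f=tau_f, tau_s=tau_s, tau_m=tau_m
        )

    def cost(s2f: float) -> float:
        obs = forward_observables(build(s2f), constants)
        val = abs(obs.noe)
        if objective == "joint":
            val += abs(obs.r2_over_r1 - r2_over_r1_target)
        return val

    if s2_total >= 1.0:
        motion = build(1.0)
        return motion, forward_observables(motion, constants)

    grid = np.arange(s2_total, 1.0 + 1e-12, 1e-3)
    grid = np.clip(grid, s2_total, 1.0)
    costs = [cost(s) for s in grid]
    k = int(np.argmin(costs))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    if hi > lo:
        res = minimize_scalar(cost, bounds=(lo, hi), method="bounded")
        s2f_best = float(res.x) if res.fun <= costs[k] else float(grid[k])
    else:
        s2f_best = float(grid[k])

    motion = build(s2f_best)
    obs = forward_observables(motion, constants)
    if abs(obs.noe) >= max_abs_noe:
        raise ValueError(
            f"no order-parameter split reaches |NOE| < {max_abs_noe}; "
            f"best achievable NOE = {obs.noe:.3f} at S2f = {s2f_best:.3f}"
        )
    return motion, obs


def fit_decay(series: DecaySeries) -> Tuple[float, float, float]:
    """Single-exponential fit h(t) = h0 exp(-R t) to peak heights.

    Returns (rate, rate_sd, h0); rate_sd comes from the fit covariance.
    Raises on non-decaying data.
    """
    t, h = series.delays, series.heights
    # log-linear starting point, guarded against nonpositive heights
    pos = h > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(h[pos]), 1)
        p0 = (float(np.exp(intercept)), float(max(-slope, 1e-6)))
    else:
        p0 = (float(np.max(np.abs(h))), 1.0)

    def model(tt, h0, rate):
        return h0 * np.exp(-rate * tt)

    sigma = None
    if series.heights_sd and series.heights_sd > 0:
        sigma = np.full_like(h, series.heights_sd)
    popt, pcov = curve_fit(model, t, h, p0=p0, sigma=sigma, maxfev=10000)
    h0, rate = popt
    if rate <= 0:
        raise ValueError(f"data do not decay (fitted rate {rate:.4g} <= 0)")
    rate_sd = float(np.sqrt(pcov[1, 1]))
    return float(rate), rate_sd, float(h0)


def noe_from_intensities(
    i_sat: float, i_unsat: float, noise_rms: float = 0.0
) -> Tuple[float, float]:
    """Steady-state NOE as the saturated/unsaturated intensity ratio with
    first-order error propagation from the spectral background noise."""
    if i_unsat == 0:
        raise ValueError("unsaturated intensity must be nonzero")
    noe = i_sat / i_unsat
    # absolute-sigma convention so the error stays finite as i_sat -> 0
    sd = abs(1.0 / i_unsat) * np.sqrt(
        noise_rms**2 + (noe * noise_rms) ** 2
    )
    return float(noe), float(sd)
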