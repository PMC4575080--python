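"""1:1 Langmuir SPR kinetics: closed-form model and global fitting.

The association phase at analyte concentration C follows

    R(t) = Req (1 - exp(-(kon C + koff) t)),   Req = rmax C / (C + koff/kon)

and the dissociation phase decays as R_end exp(-koff (t - t_stop)).  A
global fit shares kon, koff and rmax across a concentration series; the
only nuisance parameter is a constant per-curve baseline offset.  The
apparent dissociation constant is Kd = koff/kon by definition.

Mass-transport limitation and bulk refractive-index jumps are deliberately
out of scope.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .datatypes import KineticFit, Sensorgram

__all__ = ["langmuir_response", "global_fit", "equilibrium_response"]

_KOFF_FLOOR = 1e-8


def langmuir_response(
    t: np.ndarray, conc: float, kon: float, koff: float, rmax: float, t_stop: float
) -> np.ndarray:
    """Closed-form 1:1 response over both phases (association up to t_stop,
    dissociation after)."""
    t = np.asarray(t, dtype=float)
    # exploratory multi-start parameters can be extreme; overflow saturates
    # harmlessly to inf/0 here and the fit discards those starts
    with np.errstate(over="ignore", invalid="ignore"):
        kobs = kon * conc + koff
        req = rmax * conc / (conc + koff / kon)
        assoc = req * (1.0 - np.exp(-kobs * np.clip(t, 0.0, t_stop)))
        r_end = req * (1.0 - np.exp(-kobs * t_stop))
        dissoc = r_end * np.exp(-koff * np.clip(t - t_stop, 0.0, None))
        return np.where(t < t_stop, assoc, dissoc)


def _residuals(params: np.ndarray, grams: Sequence[Sensorgram]) -> np.ndarray:
    log_kon, log_koff, rmax = params[:3]
    offsets = params[3:]
    with np.errstate(over="ignore"):
        kon, koff = 10.0**log_kon, 10.0**log_koff
    res = []
    for g, off in zip(grams, offsets):
        model = langmuir_response(g.time, g.analyte_conc, kon, koff, rmax, g.t_stop)
        res.append(g.response - (model + off))
    return np.concatenate(res)


def global_fit(sensorgrams: Sequence[Sensorgram]) -> KineticFit:
    """Joint nonlinear least squares of the 1:1 model over a concentration
    series.

    kon and koff are optimized in log space with multi-start initial values
    (the (kon, rmax) valley is shallow); the best converged start wins.
    Flags koff_at_bound when the dissociation rate runs into its floor
    (no measurable dissociation on the experiment's time scale).
    """
    if len(sensorgrams) < 2:
        raise ValueError("global fit needs at least two concentrations")
    concs = {g.analyte_conc for g in sensorgrams}
    if len(concs) < 2:
        raise ValueError("global fit needs at least two distinct concentrations")

    r_scale = max(float(np.max(np.abs(g.response))) for g in sensorgrams)
    c_mid = float(np.median([g.analyte_conc for g in sensorgrams]))
    t_char = float(np.median([g.t_stop for g in sensorgrams]))
    n_off = len(sensorgrams)

    starts = []
    for log_koff0 in np.log10([0.3 / t_char, 3.0 / t_char, 30.0 / t_char]):
        for kd0 in (c_mid / 10.0, c_mid, c_mid * 10.0):
            starts.append((np.log10(10.0**log_koff0 / kd0), log_koff0))

    best = None
    lb = [-np.inf, np.log10(_KOFF_FLOOR), 0.0] + [-np.inf] * n_off
    ub = [np.inf, np.inf, np.inf] + [np.inf] * n_off
    for log_kon0, log_koff0 in starts:
        p0 = np.array([log_kon0, log_koff0, r_scale] + [0.0] * n_off)
        try:
            sol = least_squares(
                _residuals, p0, args=(sensorgrams,), bounds=(lb, ub),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise RuntimeError("global 1:1 fit did not converge from any start")

    log_kon, log_koff, rmax = best.x[:3]
    kon, koff = 10.0**log_kon, 10.0**log_koff
    n_pts = sum(len(g.time) for g in sensorgrams)
    residual_sd = float(np.sqrt(2.0 * best.cost / max(n_pts - len(best.x), 1)))
    return KineticFit(
        kon=float(kon),
        koff=float(koff),
        rmax=float(rmax),
        kd_app=float(koff / kon),
        residual_sd=residual_sd,
        koff_at_bound=bool(koff <= _KOFF_FLOOR * 1.01),
        offsets=best.x[3:].copy(),
    )


def equilibrium_response(fit: KineticFit, conc: float) -> float:
    """Steady-state response Req = rmax C / (C + Kd) at a concentration."""
    if conc <= 0:
        raise ValueError("concentration must be positive")
    return float(fit.rmax * conc / (conc + fit.kd_app))
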