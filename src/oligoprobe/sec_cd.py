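"""SEC calibration and species decomposition; CD and fluorescence metrics.

Size-exclusion columns are calibrated against globular standards with the
base-10 exponential decay ve(rh) = a*10^(-rh/b) + c, inverted numerically
to estimate hydrodynamic radii from elution volumes.  Chromatograms are
decomposed into Gaussian peaks whose areas report species fractions.
Optical metrics: the theta222/theta208 CD ellipticity ratio (coiled-coil
diagnostic), the intensity-weighted center of spectral mass of fluorescence
emission, and endpoint min-max normalization of denaturation series with a
two-state sigmoid fit and a non-cooperativity flag.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import brentq, curve_fit
from scipy.signal import find_peaks

from .datatypes import CalibrationCurve, Chromatogram, DenaturationSeries, SpectrumSeries

__all__ = [
    "fit_calibration",
    "estimate_rh",
    "decompose_peaks",
    "cd_ratio",
    "center_of_mass",
    "normalize_denaturation",
    "fraction_native_at",
]


def fit_calibration(standards: Sequence[Tuple[float, float]]) -> CalibrationCurve:
    """Least-squares fit of ve = a*10^(-rh/b) + c to (rh, ve) standards.

    Requires at least three standards with distinct radii; rejects fits
    that are not strictly decreasing in rh over the standard range.
    """
    rh = np.array([s[0] for s in standards], dtype=float)
    ve = np.array([s[1] for s in standards], dtype=float)
    if rh.size < 3:
        raise ValueError("calibration needs at least three standards")
    if len(set(rh)) != rh.size:
        raise ValueError("standards must have distinct radii")

    def model(r, a, b, c):
        return a * 10.0 ** (-r / b) + c

    span = ve.max() - ve.min()
    p0 = (max(span, 1e-6) * 2.0, max(rh.max() / 2.0, 1.0), ve.min())
    popt, _ = curve_fit(model, rh, ve, p0=p0, maxfev=20000)
    a, b, c = popt
    if a <= 0 or b <= 0:
        raise ValueError("calibration fit is not monotone decreasing in rh")
    resid = float(np.sqrt(np.mean((model(rh, *popt) - ve) ** 2)))
    return CalibrationCurve(
        rh_standards=rh, ve_standards=ve, a=float(a), b=float(b), c=float(c),
        residual=resid,
    )


def estimate_rh(cal: CalibrationCurve, ve: float) -> Union[float, str]:
    """Invert the calibration model at an elution volume.

    Elution earlier than the largest standard is reported as a lower bound
    string ("> {rh} A") — the species runs outside the resolved range, as
    void-proximal peaks do.  Volumes later than the smallest standard's
    position return the smallest standard's rh (inclusion boundary).
    """
    rh_max = float(np.max(cal.rh_standards))
    rh_min = float(np.min(cal.rh_standards))
    ve_at_max = float(cal.predict_ve(rh_max))
    ve_at_min = float(cal.predict_ve(rh_min))
    if ve < ve_at_max:
        return f"> {rh_max:g} A"
    if ve > ve_at_min:
        return rh_min
    return float(
        brentq(lambda r: cal.predict_ve(r) - ve, rh_min, rh_max, xtol=1e-10)
    )


def _gauss_mix(v, *params):
    out = np.zeros_like(v)
    for k in range(0, len(params), 3):
        amp, cen, wid = params[k : k + 3]
        out = out + amp * np.exp(-0.5 * ((v - cen) / wid) ** 2)
    return out


def decompose_peaks(
    chrom: Chromatogram, n_peaks: Union[int, str] = "auto"
) -> List[Tuple[float, float, float]]:
    """Gaussian mixture decomposition of a baseline-subtracted chromatogram.

    Returns a list of (center_mL, width_mL, area_fraction) sorted by
    center; fractions sum to 1.  With n_peaks="auto" the count is chosen
    by BIC over 1-4 components.  Peaks closer than half their mean width
    are reported but the pair's parameters are weakly determined (the
    caller sees them as near-degenerate centers).
    """
    v, y = chrom.volume, chrom.absorbance
    if n_peaks == "auto":
        best = None
        for n in range(1, 5):
            try:
                res = _fit_mixture(v, y, n)
            except RuntimeError:
                continue
            popt, rss = res
            npts = v.size
            bic = npts * np.log(max(rss / npts, 1e-300)) + 3 * n * np.log(npts)
            if best is None or bic < best[0]:
                best = (bic, popt)
        if best is None:
            raise RuntimeError("no Gaussian mixture converged for any n in 1-4")
        popt = best[1]
    else:
        popt, _ = _fit_mixture(v, y, int(n_peaks))

    comps = []
    for k in range(0, len(popt), 3):
        amp, cen, wid = popt[k : k + 3]
        area = amp * abs(wid) * np.sqrt(2.0 * np.pi)
        comps.append((float(cen), float(abs(wid)), float(area)))
    comps.sort(key=lambda c: c[0])
    total = sum(c[2] for c in comps)
    if total <= 0:
        raise RuntimeError("decomposition produced zero total area")
    return [(c, w, a / total) for c, w, a in comps]


def _fit_mixture(v, y, n):
    span = v[-1] - v[0]
    # seed from the most prominent local maxima, fall back to even spacing
    idx, _ = find_peaks(y, prominence=0.02 * np.max(y))
    idx = list(idx[np.argsort(y[idx])[::-1][:n]])
    centers = [v[i] for i in idx]
    while len(centers) < n:
        centers.append(v[0] + span * (len(centers) + 0.5) / n)
    p0 = []
    floor = 1e-6 * float(np.max(y))
    for c in sorted(centers):
        # noise can make the seeded amplitude negative; keep it inside bounds
        p0 += [max(float(np.interp(c, v, y)), floor), float(c), span / (6.0 * n)]
    lb = [0.0, v[0] - span, 1e-6 * span] * n
    ub = [np.inf, v[-1] + span, span] * n
    popt, _ = curve_fit(
        _gauss_mix, v, y, p0=p0, bounds=(lb, ub), maxfev=40000
    )
    rss = float(np.sum((_gauss_mix(v, *popt) - y) ** 2))
    return popt, rss


def cd_ratio(spectrum: SpectrumSeries) -> float:
    """theta222/theta208 ellipticity ratio by local interpolation."""
    x = spectrum.x
    if not (x[0] <= 208.0 and x[-1] >= 222.0):
        raise ValueError("spectrum must cover 208-222 nm")
    t208 = float(np.interp(208.0, x, spectrum.y))
    t222 = float(np.interp(222.0, x, spectrum.y))
    if t208 == 0:
        raise ZeroDivisionError("theta at 208 nm is zero")
    return t222 / t208


def center_of_mass(spectrum: SpectrumSeries) -> float:
    """Intensity-weighted mean wavelength of an emission spectrum (nm)."""
    y = spectrum.y
    if np.any(y < 0):
        raise ValueError("emission intensities must be nonnegative")
    total = float(np.sum(y))
    if total == 0:
        raise ValueError("all-zero spectrum")
    return float(np.sum(spectrum.x * y) / total)


def normalize_denaturation(series: DenaturationSeries) -> DenaturationSeries:
    """Endpoint min-max normalization of a denaturation series to fraction
    native (1 at the lowest-denaturant point, 0 at the highest), plus a
    two-state sigmoid fit for (midpoint, slope).

    A non-cooperativity flag is set when the sigmoid does not beat a
    straight line by the stored small-sample information criterion (AICc);
    shallow quasi-linear unfolding is the hallmark of proteins without a
    compact cooperative core.
    """
    urea, obs = series.urea, series.observable
    if urea.size < 4:
        raise ValueError("need at least 4 denaturant points")
    s0, s1 = obs[0], obs[-1]
    if s0 == s1:
        raise ValueError("degenerate endpoints")
    inner = obs[1:-1]
    if np.any(inner > max(s0, s1)) or np.any(inner < min(s0, s1)):
        # tolerate noise-level excursions only
        tol = 0.05 * abs(s1 - s0)
        if np.any(inner > max(s0, s1) + tol) or np.any(inner < min(s0, s1) - tol):
            raise ValueError("endpoints are not the extremes of the series")
    frac = (obs - s1) / (s0 - s1)

    def sigmoid(x, mid, slope):
        return 1.0 / (1.0 + np.exp(slope * (x - mid)))

    try:
        popt, _ = curve_fit(
            sigmoid, urea, frac, p0=(float(np.median(urea)), 1.0), maxfev=20000
        )
        mid, slope = float(popt[0]), float(popt[1])
        rss_sig = float(np.sum((sigmoid(urea, *popt) - frac) ** 2))
    except RuntimeError:
        mid, slope = float("nan"), float("nan")
        rss_sig = np.inf

    lin = np.polyfit(urea, frac, 1)
    rss_lin = float(np.sum((np.polyval(lin, urea) - frac) ** 2))
    n = urea.size

    def aicc(rss, k):
        if n - k - 1 <= 0:
            return np.inf
        return n * np.log(max(rss / n, 1e-300)) + 2 * k + 2 * k * (k + 1) / (n - k - 1)

    non_coop = not (aicc(rss_sig, 2) < aicc(rss_lin, 2) - 2.0)

    return DenaturationSeries(
        urea=urea,
        observable=obs,
        normalized=frac,
        midpoint=mid,
        slope=slope,
        non_cooperative=bool(non_coop),
    )


def fraction_native_at(series: DenaturationSeries, urea: float) -> float:
    """Fraction native at an arbitrary denaturant concentration by linear
    interpolation of the normalized curve."""
    if series.normalized is None:
        series = normalize_denaturation(series)
    return float(np.interp(urea, series.urea, series.normalized))
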