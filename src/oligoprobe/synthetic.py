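"""Synthetic data generators with known ground truth.

Every input the analysis stages consume can be generated here: sphere-like
SAXS curves, mono-exponential relaxation decays from a motional model,
chemical-shift tables with known helix/strand segments, 1:1 Langmuir
sensorgrams, Gaussian-peak chromatograms on a calibrated column, and
two-state urea-denaturation curves.  Default grids mirror the experimental
settings of the study this package models: q from 0.008 to 0.208 1/A,
R1 delays 50-1200 ms and R2 delays 17-220 ms, 3-minute SPR contact times
at 0.2-0.8 uM analyte, urea from 0.5 to 7 M.

All generators are pure functions of (parameters, seed): the same call
returns bit-identical output.  Noise is additive Gaussian throughout (the
simplest model consistent with the least-squares fitting downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .binding import langmuir_response
from .datatypes import (
    Chromatogram,
    DecaySeries,
    DenaturationSeries,
    MotionModel,
    ScatteringCurve,
    Sensorgram,
    SpinSystemConstants,
)
from .relax import forward_observables
from .sec_cd import CalibrationCurve
from .shifts import FULL_STRUCTURE_SHIFTS, load_random_coil

__all__ = [
    "SyntheticSpec",
    "default_q_grid",
    "DEFAULT_R1_DELAYS",
    "DEFAULT_R2_DELAYS",
    "DEFAULT_SPR_CONCS",
    "DEFAULT_UREA_GRID",
    "gen_sphere_saxs",
    "gen_ellipsoid_saxs",
    "gen_relax_decay",
    "gen_shift_table",
    "gen_sensorgram",
    "gen_chromatogram",
    "gen_cd_denaturation",
]


@dataclass
class SyntheticSpec:
    """Declarative description of one synthetic dataset: what to generate,
    its ground-truth parameters, the noise level and the seed."""

    kind: str
    params: Dict[str, object] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    _KINDS = (
        "saxs_sphere",
        "relax_decay",
        "shift_table",
        "sensorgram",
        "chromatogram",
        "cd_denaturation",
        "sequence",
    )

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown synthetic kind {self.kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def default_q_grid(n: int = 200) -> np.ndarray:
    """q-grid spanning the instrument range 0.008-0.208 1/A."""
    return np.linspace(0.008, 0.208, n)


DEFAULT_R1_DELAYS = np.array([0.05, 0.1, 0.2, 0.35, 0.5, 0.7, 0.9, 1.2])
DEFAULT_R2_DELAYS = np.array([0.017, 0.034, 0.051, 0.085, 0.119, 0.153, 0.187, 0.22])
DEFAULT_SPR_CONCS = np.array([0.2e-6, 0.4e-6, 0.6e-6, 0.8e-6])
DEFAULT_UREA_GRID = np.arange(0.5, 7.01, 0.5)


def gen_sphere_saxs(
    radius: float,
    i0: float = 1.0,
    q_grid: Optional[Sequence[float]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ScatteringCurve:
    """Scattering of a homogeneous sphere with relative Gaussian noise.

    noise_sd is relative: each point gets sd = noise_sd * I(q), which also
    populates the sigma column (a small floor keeps sigma positive at
    form-factor zeros when noise_sd > 0).
    """
    from .saxs import sphere_form_factor

    if radius <= 0:
        raise ValueError("radius must be positive")
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    if q.size == 0:
        raise ValueError("empty q grid")
    intensity = sphere_form_factor(q, radius, i0)
    if noise_sd > 0:
        sigma = np.maximum(noise_sd * intensity, noise_sd * i0 * 1e-6)
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, sigma)
        return ScatteringCurve(q=q, intensity=intensity, sigma=sigma)
    return ScatteringCurve(q=q, intensity=intensity)


def gen_ellipsoid_saxs(
    semi_axis: float,
    axial_ratio: float,
    i0: float = 1.0,
    q_grid: Optional[Sequence[float]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_orient: int = 200,
) -> ScatteringCurve:
    """Orientation-averaged scattering of a prolate/oblate ellipsoid of
    revolution (semi-axes a, a, a*axial_ratio) — supports the "slightly
    elongated globule" scenario."""
    from .saxs import sphere_form_factor

    if semi_axis <= 0 or axial_ratio <= 0:
        raise ValueError("semi_axis and axial_ratio must be positive")
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    mu = np.linspace(0.0, 1.0, n_orient)
    r_eff = semi_axis * np.sqrt(1.0 + (axial_ratio**2 - 1.0) * mu**2)
    # orientation average of the sphere amplitude evaluated at q*r_eff(mu)
    intensity = np.array(
        [np.mean(_sphere_ff_scalar(qi * r_eff)) for qi in q]
    ) * i0
    if noise_sd > 0:
        sigma = np.maximum(noise_sd * intensity, noise_sd * i0 * 1e-6)
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, sigma)
        return ScatteringCurve(q=q, intensity=intensity, sigma=sigma)
    return ScatteringCurve(q=q, intensity=intensity)


def _sphere_ff_scalar(x: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        amp = 3.0 * (np.sin(x) - x * np.cos(x)) / x**3
    amp = np.where(x < 1e-6, 1.0 - x**2 / 10.0, amp)
    return amp**2


def gen_relax_decay(
    motion: MotionModel,
    constants: Optional[SpinSystemConstants] = None,
    delays_r1: Optional[Sequence[float]] = None,
    delays_r2: Optional[Sequence[float]] = None,
    h0: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Dict[str, object]:
    """R1/R2 decay series and a NOE intensity pair from a motional model.

    Peak heights follow h0*exp(-R t) with R from the forward model-free
    computation; the NOE pair is (saturated, unsaturated) with ratio equal
    to the computed NOE.  noise_sd is relative to h0.  Returns a dict with
    keys "r1_series", "r2_series", "noe_pair", "truth".
    """
    t1 = DEFAULT_R1_DELAYS if delays_r1 is None else np.asarray(delays_r1, float)
    t2 = DEFAULT_R2_DELAYS if delays_r2 is None else np.asarray(delays_r2, float)
    for t in (t1, t2):
        if t.size < 4 or np.any(t <= 0):
            raise ValueError("delay grids need >= 4 positive points")
    obs = forward_observables(motion, constants)
    rng = np.random.default_rng(seed)
    sd = noise_sd * h0

    def decay(rate, delays):
        h = h0 * np.exp(-rate * delays)
        if sd > 0:
            h = h + rng.normal(0.0, sd, size=delays.size)
        return DecaySeries(delays=delays, heights=h, heights_sd=sd)

    i_unsat = h0 + (rng.normal(0.0, sd) if sd > 0 else 0.0)
    i_sat = h0 * obs.noe + (rng.normal(0.0, sd) if sd > 0 else 0.0)
    return {
        "r1_series": decay(obs.r1, t1),
        "r2_series": decay(obs.r2, t2),
        "noe_pair": (float(i_sat), float(i_unsat)),
        "truth": obs,
    }


def gen_shift_table(
    n_residues: int,
    segments: Sequence[Tuple[int, int, str]],
    sequence: Optional[str] = None,
    jitter_sd: float = 0.0,
    seed: int = 0,
):
    """Shift table with known secondary-structure segments.

    Residues inside a (start, end, state) segment carry the canonical
    full-structure secondary shifts of that state on top of their
    random-coil reference; everything else sits exactly at random coil.
    jitter_sd (ppm, scaled down 10x for protons) adds seeded Gaussian
    noise.  Returns a pandas DataFrame indexed by residue with columns
    aa, CA, CB, HA.
    """
    import pandas as pd

    for (s1, e1, st) in segments:
        if st not in ("helix", "strand", "coil"):
            raise ValueError(f"unknown state {st!r}")
        if not (1 <= s1 <= e1 <= n_residues):
            raise ValueError("segment outside sequence")
    spans = sorted((s, e) for s, e, _ in segments)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError("overlapping segments")

    rc = load_random_coil()
    rng = np.random.default_rng(seed)
    if sequence is None:
        # alanine-rich default with no glycines, so all nuclei exist
        aas = [["A", "L", "K", "E", "S"][i % 5] for i in range(n_residues)]
    else:
        if len(sequence) != n_residues:
            raise ValueError("sequence length mismatch")
        aas = list(sequence)

    state_of = np.full(n_residues, "coil", dtype=object)
    for s1, e1, st in segments:
        state_of[s1 - 1 : e1] = st

    rows = []
    for i, aa in enumerate(aas):
        row = {"residue": i + 1, "aa": aa}
        for nuc in ("CA", "CB", "HA"):
            ref = rc.loc[aa, nuc]
            if np.isnan(ref):
                row[nuc] = np.nan
                continue
            delta = 0.0
            if state_of[i] != "coil":
                delta = FULL_STRUCTURE_SHIFTS[state_of[i]][nuc]
            jit = 0.0
            if jitter_sd > 0:
                scale = 0.1 if nuc == "HA" else 1.0
                jit = rng.normal(0.0, jitter_sd * scale)
            row[nuc] = ref + delta + jit
        rows.append(row)
    return pd.DataFrame(rows).set_index("residue")


def gen_sensorgram(
    kon: float,
    koff: float,
    rmax: float,
    conc: Optional[Sequence[float]] = None,
    t_assoc: float = 180.0,
    t_dissoc: float = 180.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> List[Sensorgram]:
    """1:1 Langmuir sensorgrams over a concentration series.

    noise_sd is absolute (response units).  Default contact times are the
    3-minute injections of the modeled experiment at 0.2-0.8 uM analyte.
    """
    if min(kon, rmax) <= 0 or koff < 0:
        raise ValueError("kon and rmax must be positive and koff nonnegative")
    concs = DEFAULT_SPR_CONCS if conc is None else np.asarray(conc, float)
    if concs.size == 0:
        raise ValueError("need at least one concentration")
    t = np.arange(0.0, t_assoc + t_dissoc + dt / 2.0, dt)
    rng = np.random.default_rng(seed)
    out = []
    for c in concs:
        r = langmuir_response(t, float(c), kon, koff, rmax, t_assoc)
        if noise_sd > 0:
            r = r + rng.normal(0.0, noise_sd, size=t.size)
        out.append(
            Sensorgram(time=t.copy(), response=r, analyte_conc=float(c), t_stop=t_assoc)
        )
    return out


def gen_chromatogram(
    peaks: Sequence[Tuple[float, float, float]],
    calibration: CalibrationCurve,
    v_grid: Optional[Sequence[float]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Tuple[Chromatogram, List[Tuple[float, float]]]:
    """Gaussian-peak chromatogram for species of known hydrodynamic radius.

    peaks is a list of (rh_A, area_fraction, width_mL); fractions must sum
    to 1.  Peak centers come from the calibration model; a species beyond
    the largest standard is flagged and parked at the void-side elution
    bound.  noise_sd is absolute in absorbance units.  Returns the
    chromatogram plus [(center_mL, flag)] ground truth.
    """
    fracs = np.array([p[1] for p in peaks], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("area fractions must sum to 1")
    rh_max = float(np.max(calibration.rh_standards))
    rh_min = float(np.min(calibration.rh_standards))
    centers = []
    for rh, _, _ in peaks:
        if rh > rh_max:
            centers.append((float(calibration.predict_ve(rh_max)), True))
        elif rh < rh_min:
            centers.append((float(calibration.predict_ve(rh_min)), True))
        else:
            centers.append((float(calibration.predict_ve(rh)), False))
    ve_lo = calibration.predict_ve(rh_max) - 2.0
    ve_hi = calibration.predict_ve(rh_min) + 2.0
    v = (
        np.linspace(ve_lo, ve_hi, 800)
        if v_grid is None
        else np.asarray(v_grid, float)
    )
    y = np.zeros_like(v)
    for (center, _), (rh, frac, width) in zip(centers, peaks):
        amp = frac / (width * np.sqrt(2.0 * np.pi))
        y = y + amp * np.exp(-0.5 * ((v - center) / width) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=v.size)
    chrom = Chromatogram(
        volume=v,
        absorbance=y,
        void_volume=float(ve_lo),
        inclusion_volume=float(ve_hi),
    )
    return chrom, centers


def gen_cd_denaturation(
    midpoint: float,
    m_value: float,
    native_signal: float,
    unfolded_signal: float,
    urea_grid: Optional[Sequence[float]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DenaturationSeries:
    """Two-state denaturation curve S(urea) = S_U + (S_N - S_U) * fN with
    fN = 1/(1 + exp(m (urea - midpoint))) on the 0.5-7 M default grid.

    m_value is in 1/M (the sigmoid steepness, an m-value already divided
    by RT); noise_sd is absolute in signal units.
    """
    urea = DEFAULT_UREA_GRID if urea_grid is None else np.asarray(urea_grid, float)
    if urea.size == 0:
        raise ValueError("empty urea grid")
    if np.any(urea < 0) or np.any(urea > 8):
        raise ValueError("urea grid must lie within 0-8 M")
    fn = 1.0 / (1.0 + np.exp(m_value * (urea - midpoint)))
    sig = unfolded_signal + (native_signal - unfolded_signal) * fn
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sig = sig + rng.normal(0.0, noise_sd, size=urea.size)
    return DenaturationSeries(urea=urea, observable=sig)
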