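"""Shared container types for the characterization pipeline.

Conventions: lengths in angstroms, times in seconds, concentrations in molar,
chemical shifts in ppm, magnetic field in tesla.  Residue numbering is
1-based inclusive.  Arrays are numpy float arrays; validation happens at
construction so downstream numerics can assume clean inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np


def _as_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class ScatteringCurve:
    """Small-angle scattering intensities on an ascending q-grid.

    q in inverse angstroms, intensity in arbitrary units; sigma, when
    present, holds per-point standard deviations in the intensity units.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.q = _as_array(self.q, "q")
        self.intensity = _as_array(self.intensity, "intensity")
        if self.q.size == 0:
            raise ValueError("empty q grid")
        if np.any(np.diff(self.q) <= 0) or self.q[0] <= 0:
            raise ValueError("q must be strictly increasing and positive")
        if self.intensity.size != self.q.size:
            raise ValueError("q and intensity length mismatch")
        if self.sigma is not None:
            self.sigma = _as_array(self.sigma, "sigma")
            if self.sigma.size != self.q.size:
                raise ValueError("sigma length mismatch")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive")

    def __len__(self) -> int:
        return int(self.q.size)


@dataclass
class GuinierFit:
    """Result of a weighted Guinier regression over an automatically chosen
    low-q window."""

    rg: float
    i0: float
    q_range: Tuple[float, float]
    r_squared: float
    qrg_max: float
    n_points: int
    rg_sd: float = float("nan")


@dataclass
class PairDistribution:
    """Real-space pair-distance distribution from a regularized indirect
    Fourier transform; p vanishes at r = 0 and r = dmax by construction."""

    r: np.ndarray
    p: np.ndarray
    dmax: float
    rg_real: float
    alpha: float
    i0: float
    chi2_reduced: float
    dmax_warning: bool = False


@dataclass
class MotionModel:
    """Extended model-free description of an N-H bond vector: fast (tau_f)
    and slow (tau_s) internal motions under isotropic tumbling (tau_m),
    with amplitudes s2f and s2s; the total order parameter is s2f*s2s."""

    s2f: float
    s2s: float
    tau_f: float
    tau_s: float
    tau_m: float

    def __post_init__(self) -> None:
        for name in ("s2f", "s2s"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not (0.0 < self.tau_f < self.tau_s < self.tau_m):
            raise ValueError(
                "correlation times must satisfy 0 < tau_f < tau_s < tau_m"
            )

    @property
    def s2(self) -> float:
        return self.s2f * self.s2s


@dataclass
class SpinSystemConstants:
    """Interaction constants for backbone amide 15N relaxation."""

    b0: float = 14.09508          # tesla
    r_nh: float = 1.02            # angstrom
    csa: float = -172.0           # ppm, signed delta-sigma
    gamma_h: float = 2.6752218744e8
    gamma_n: float = -2.7126189e7

    def __post_init__(self) -> None:
        if self.b0 <= 0:
            raise ValueError("b0 must be positive")
        if not (0.9 <= self.r_nh <= 1.1):
            raise ValueError("r_nh must be within 0.9-1.1 angstrom")

    @property
    def omega_h(self) -> float:
        """1H Larmor frequency, rad/s (magnitude)."""
        return abs(self.gamma_h) * self.b0

    @property
    def omega_n(self) -> float:
        """15N Larmor frequency, rad/s (magnitude)."""
        return abs(self.gamma_n) * self.b0


@dataclass
class RelaxationObservables:
    r1: float
    r2: float
    noe: float

    @property
    def r2_over_r1(self) -> float:
        return self.r2 / self.r1


@dataclass
class DecaySeries:
    """Peak-height decay for a single exponential relaxation measurement."""

    delays: np.ndarray
    heights: np.ndarray
    heights_sd: float = 0.0

    def __post_init__(self) -> None:
        self.delays = _as_array(self.delays, "delays")
        self.heights = _as_array(self.heights, "heights")
        if self.delays.size < 4:
            raise ValueError("decay series needs at least 4 points")
        if self.delays.size != self.heights.size:
            raise ValueError("delays/heights length mismatch")
        if np.any(self.delays <= 0) or len(set(self.delays)) != self.delays.size:
            raise ValueError("delays must be positive and distinct")


@dataclass
class Sensorgram:
    """SPR response trace at a single analyte concentration.  Association
    runs on [0, t_stop); dissociation from t_stop onward."""

    time: np.ndarray
    response: np.ndarray
    analyte_conc: float
    t_stop: float

    def __post_init__(self) -> None:
        self.time = _as_array(self.time, "time")
        self.response = _as_array(self.response, "response")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.analyte_conc <= 0:
            raise ValueError("analyte concentration must be positive")
        if self.time.size != self.response.size:
            raise ValueError("time/response length mismatch")


@dataclass
class KineticFit:
    """Globally fitted 1:1 Langmuir parameters; kd_app = koff/kon."""

    kon: float
    koff: float
    rmax: float
    kd_app: float
    residual_sd: float
    koff_at_bound: bool = False
    offsets: Optional[np.ndarray] = None


@dataclass
class CalibrationCurve:
    """SEC column calibration ve = a*10^(-rh/b) + c over globular standards."""

    rh_standards: np.ndarray
    ve_standards: np.ndarray
    a: float
    b: float
    c: float
    residual: float

    def predict_ve(self, rh: float) -> float:
        return self.a * 10.0 ** (-np.asarray(rh, dtype=float) / self.b) + self.c


@dataclass
class Chromatogram:
    volume: np.ndarray
    absorbance: np.ndarray
    void_volume: Optional[float] = None
    inclusion_volume: Optional[float] = None

    def __post_init__(self) -> None:
        self.volume = _as_array(self.volume, "volume")
        self.absorbance = _as_array(self.absorbance, "absorbance")
        if np.any(np.diff(self.volume) <= 0):
            raise ValueError("volume must be strictly increasing")
        if self.volume.size != self.absorbance.size:
            raise ValueError("volume/absorbance length mismatch")


@dataclass
class SpectrumSeries:
    """A single optical spectrum (CD ellipticity or fluorescence emission)."""

    x: np.ndarray
    y: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.x = _as_array(self.x, "x")
        self.y = _as_array(self.y, "y")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("wavelength axis must be strictly increasing")
        if self.x.size != self.y.size:
            raise ValueError("x/y length mismatch")


@dataclass
class DenaturationSeries:
    """Observable tracked against denaturant concentration."""

    urea: np.ndarray
    observable: np.ndarray
    normalized: Optional[np.ndarray] = None
    midpoint: float = float("nan")
    slope: float = float("nan")
    non_cooperative: bool = False

    def __post_init__(self) -> None:
        self.urea = _as_array(self.urea, "urea")
        self.observable = _as_array(self.observable, "observable")
        if np.any(np.diff(self.urea) <= 0):
            raise ValueError("urea grid must be strictly increasing")
        if self.urea.size != self.observable.size:
            raise ValueError("urea/observable length mismatch")


@dataclass
class StoichiometryBounds:
    """Subunit count bracket for an oligomer from volume ratios."""

    v_oligomer: float
    v_monomer_globular: float
    v_monomer_denatured: float
    n_min: int
    n_max: int


@dataclass
class SequenceRecord:
    """Protein sequence with solution conditions for exchange prediction."""

    id: str
    sequence: str
    ph: float = 7.0
    temperature: float = 286.15
    reference_condition: str = "poly-DL-alanine"

    def __post_init__(self) -> None:
        valid = set("ACDEFGHIKLMNPQRSTVWY")
        bad = [i + 1 for i, aa in enumerate(self.sequence) if aa not in valid]
        if bad:
            raise ValueError(
                f"non-canonical residues at positions {bad} in {self.id}"
            )
        if not (0.0 < self.ph < 14.0):
            raise ValueError("pH must lie in (0, 14)")
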