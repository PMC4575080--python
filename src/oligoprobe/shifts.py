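"""Chemical-shift secondary-structure analysis.

Secondary-structure propensity (SSP-style) scores from Ca/Cb/Ha secondary
shifts, aggregate helix/strand content, extrapolation of content measured
under partial denaturation to the native state, amide chemical-shift
perturbation profiles, and HN dispersion.

A shift table is a pandas DataFrame indexed by residue number with columns
"aa" plus any subset of the nuclei {"CA", "CB", "HA", "H", "N"} in ppm.
Random-coil references ship as a data file; full-structure secondary-shift
amplitudes (the score normalization) are state-level constants below.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "load_random_coil",
    "ssp_profile",
    "structure_content",
    "extrapolate_native",
    "csp_profile",
    "hn_dispersion",
    "FULL_STRUCTURE_SHIFTS",
    "NUCLEUS_WEIGHTS",
]

#: Canonical full-structure secondary shifts (ppm): the expected deviation
#: from random coil for 100% helix / 100% strand.  Sign pattern: helix moves
#: Ca downfield and Ha upfield; strand is opposite with a strong Cb term.
FULL_STRUCTURE_SHIFTS: Dict[str, Dict[str, float]] = {
    "helix": {"CA": 2.6, "CB": -0.4, "HA": -0.35},
    "strand": {"CA": -1.4, "CB": 2.2, "HA": 0.45},
}

#: Inverse-variance style weights per nucleus; proton shifts are an order of
#: magnitude smaller than carbon shifts, so HA is up-weighted accordingly.
NUCLEUS_WEIGHTS: Dict[str, float] = {"CA": 1.0, "CB": 1.0, "HA": 7.0}

_SSP_NUCLEI = ("CA", "CB", "HA")


def load_random_coil() -> pd.DataFrame:
    """Random-coil reference shifts, indexed by one-letter residue code."""
    with resources.files("oligoprobe.data").joinpath(
        "random_coil_shifts.csv"
    ).open() as fh:
        df = pd.read_csv(fh, comment="#")
    return df.set_index("aa")


def _secondary_shifts(table: pd.DataFrame) -> pd.DataFrame:
    rc = load_random_coil()
    out = {}
    for nuc in _SSP_NUCLEI:
        if nuc not in table.columns:
            continue
        ref = table["aa"].map(rc[nuc])
        out[nuc] = table[nuc] - ref
    return pd.DataFrame(out, index=table.index)


def ssp_profile(table: pd.DataFrame, window: int = 5) -> pd.DataFrame:
    """Per-residue secondary-structure propensity.

    For each residue a centered window (truncated at the termini) collects
    weighted observed secondary shifts over the available nuclei, with the
    sign flipped for nuclei whose helical secondary shift is negative so
    that helix always scores positive.  The score divides by the equally
    weighted magnitude of the canonical full-structure shifts of the state
    the numerator points to (helix when positive, strand when negative):
    +1 means fully formed helix, -1 fully extended.

    Residues with no usable nucleus in the window are reported as NaN, not
    zero.  Returns a DataFrame with columns "ssp" and "coverage".
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if table.empty:
        raise ValueError("empty shift table")
    if not table.index.is_unique or not table.index.is_monotonic_increasing:
        raise ValueError("residue indices must be unique and ascending")

    sec = _secondary_shifts(table)
    if sec.empty or sec.dropna(how="all").empty:
        raise ValueError("shift table contains none of the SSP nuclei")
    half = window // 2
    residues = table.index.to_numpy()
    scores = np.full(residues.size, np.nan)
    coverage = []

    for k, res in enumerate(residues):
        in_win = (residues >= res - half) & (residues <= res + half)
        num = 0.0
        den_h = 0.0
        den_s = 0.0
        used = set()
        for nuc in sec.columns:
            vals = sec.loc[residues[in_win], nuc]
            helix_amp = FULL_STRUCTURE_SHIFTS["helix"][nuc]
            strand_amp = FULL_STRUCTURE_SHIFTS["strand"][nuc]
            sign = 1.0 if helix_amp > 0 else -1.0
            w = NUCLEUS_WEIGHTS[nuc]
            for v in vals:
                if np.isnan(v):
                    continue
                num += w * sign * v
                den_h += w * abs(helix_amp)
                den_s += w * abs(strand_amp)
                used.add(nuc)
        if den_h == 0.0:
            coverage.append("")
            continue
        den = den_h if num >= 0 else den_s
        scores[k] = num / den
        coverage.append("+".join(sorted(used)))
    return pd.DataFrame(
        {"ssp": scores, "coverage": coverage}, index=table.index
    )


def structure_content(profile: pd.DataFrame) -> Tuple[float, float]:
    """Aggregate (helix_pct, strand_pct) over the scored residues.

    helix_pct = 100 * sum(max(ssp, 0)) / N_scored and symmetrically for
    strand; unscored (NaN) residues are excluded from both numerator and
    denominator.
    """
    ssp = profile["ssp"].dropna().to_numpy()
    if ssp.size == 0:
        raise ValueError("profile has no scored residues")
    helix = 100.0 * np.sum(np.clip(ssp, 0.0, None)) / ssp.size
    strand = 100.0 * np.sum(np.clip(-ssp, 0.0, None)) / ssp.size
    return float(helix), float(strand)


def extrapolate_native(content_pct: float, retained_fraction: float) -> float:
    """Scale content measured under partial denaturation to the native state
    given the fraction of native structure retained in that condition."""
    if not (0.0 < retained_fraction <= 1.0):
        raise ValueError("retained_fraction must be in (0, 1]")
    return content_pct / retained_fraction


def csp_profile(
    reference: pd.DataFrame, perturbed: pd.DataFrame
) -> pd.DataFrame:
    """Combined amide chemical-shift perturbation per residue.

    delta = sqrt(dH^2 + (dN/5)^2) when both HN and 15N shifts are present,
    |dH| otherwise (the conventional 1/5 nitrogen scaling).  Residues above
    the profile's arithmetic mean are flagged.
    """
    common = reference.index.intersection(perturbed.index)
    if common.empty:
        raise ValueError("shift tables share no residues")
    rows = []
    for res in common:
        dh = np.nan
        dn = np.nan
        if "H" in reference.columns and "H" in perturbed.columns:
            dh = perturbed.loc[res, "H"] - reference.loc[res, "H"]
        if "N" in reference.columns and "N" in perturbed.columns:
            dn = perturbed.loc[res, "N"] - reference.loc[res, "N"]
        if not np.isnan(dh) and not np.isnan(dn):
            delta = float(np.sqrt(dh**2 + (dn / 5.0) ** 2))
        elif not np.isnan(dh):
            delta = float(abs(dh))
        else:
            delta = np.nan
        rows.append(delta)
    out = pd.DataFrame({"delta": rows}, index=common)
    mean = out["delta"].mean()
    out["above_mean"] = out["delta"] > mean
    return out


def hn_dispersion(table: pd.DataFrame) -> float:
    """Spread max - min of the backbone HN shifts (ppm)."""
    if "H" not in table.columns:
        raise ValueError("table has no HN shifts")
    vals = table["H"].dropna()
    if vals.size < 2:
        raise ValueError("need at least two HN shifts")
    return float(vals.max() - vals.min())
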