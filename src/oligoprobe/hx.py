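"""Random-coil (intrinsic) backbone amide hydrogen-exchange prediction.

Implements the reference-rate + correction-factor scheme of Bai, Milne,
Mayne & Englander (1993) and Connelly et al. (1993) for exchange in H2O:

    k_ex = k_A * F_A * [H+]  +  k_B * F_B * [OH-]  +  k_W * F_B

where k_A/k_B/k_W are the poly-DL-alanine reference rate constants
(Arrhenius-corrected from the 20 C calibration with activation energies of
14, 17 and 19 kcal/mol), and F_A/F_B multiply the tabulated inductive
factors of the residue itself (lambda) and its left neighbor (rho), plus
chain-terminus terms.  Titratable side chains (Asp, Glu, His) blend their
protonated/deprotonated factors from the pH and the temperature-corrected
side-chain pKa.  The hydroxide concentration uses the fixed water ion
product pKw = 14.17 of the 20 C calibration; its temperature dependence is
carried inside the base-catalysis activation energy, which includes the
water-ionization enthalpy (the published convention).

The first residue has no amide proton track (free amine) and prolines have
none at all; both are absent from the output profile.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .constants import R_CAL
from .datatypes import SequenceRecord

__all__ = [
    "load_factor_table",
    "intrinsic_rates",
    "count_fast_exchangers",
    "protection_report",
]

#: log10 reference rates for poly-DL-alanine in H2O at 293 K, per minute
#: (acid: M^-1 min^-1; base: M^-1 min^-1; water: min^-1).
_LOG_K_REF = {"acid": 1.39, "base": 10.08, "water": -1.6}
_T_REF = 293.0

#: Activation energies, cal/mol.
_E_ACT = {"acid": 14000.0, "base": 17000.0, "water": 19000.0}

#: Water ion product of the 20 C calibration (see module docstring).
_PKW = 14.17

#: Side-chain pKa values (H2O) at the 278 K reference, with their apparent
#: activation energies (cal/mol) for temperature correction.
_SIDECHAIN_PKA = {"D": (3.88, 960.0), "E": (4.35, 1083.0), "H": (7.11, 7500.0)}
_T_PKA_REF = 278.0

#: C-terminal acid-catalysis lambda in the protonated (COOH) and
#: deprotonated (COO-) forms; blended with the Glu pKa.
_CT_ACID = {"protonated": 0.05, "deprotonated": 0.96}


def load_factor_table() -> pd.DataFrame:
    """The embedded published inductive-factor table (log10 units)."""
    with resources.files("oligoprobe.data").joinpath("hx_factors.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    return df.set_index("key")


def _pka_at(residue: str, temperature: float) -> float:
    pka_ref, e_act = _SIDECHAIN_PKA[residue]
    return -np.log10(
        10.0**-pka_ref
        * np.exp(-e_act * (1.0 / temperature - 1.0 / _T_PKA_REF) / R_CAL)
    )


def _blend(prot: float, deprot: float, ph: float, pka: float) -> float:
    """pH-weighted log-average of a protonated/deprotonated factor pair."""
    return float(
        np.log10(
            (10.0 ** (prot - ph) + 10.0 ** (deprot - pka))
            / (10.0**-pka + 10.0**-ph)
        )
    )


def _resolved_factors(ph: float, temperature: float) -> pd.DataFrame:
    """Factor table with titratable residues collapsed to effective values
    at the given pH and temperature."""
    table = load_factor_table()
    cols = ["acid_lambda", "acid_rho", "base_lambda", "base_rho"]
    rows = {}
    for key in table.index:
        rows[key] = table.loc[key, cols].astype(float).to_numpy()
    for res in ("D", "E", "H"):
        pka = _pka_at(res, temperature)
        prot = rows[f"{res}+"]
        deprot = rows[f"{res}0"]
        rows[res] = np.array(
            [_blend(p, d, ph, pka) for p, d in zip(prot, deprot)]
        )
    pka_e = _pka_at("E", temperature)
    ct = rows["CT"].copy()
    ct[0] = _blend(
        _CT_ACID["protonated"], _CT_ACID["deprotonated"], ph, pka_e
    )
    rows["CT"] = ct
    return pd.DataFrame(rows, index=cols).T


def intrinsic_rates(record: SequenceRecord) -> pd.DataFrame:
    """Per-residue intrinsic exchange rates for a fully solvent-exposed
    random coil.

    Returns a DataFrame indexed by residue number (2..N, prolines omitted)
    with columns aa, k_acid, k_base, k_water and k_ex (all s^-1).
    """
    seq = record.sequence
    if len(seq) < 2:
        raise ValueError("sequence must have at least two residues")
    ph, temp = record.ph, record.temperature
    factors = _resolved_factors(ph, temp)

    def arrh(kind: str) -> float:
        k20 = 10.0 ** _LOG_K_REF[kind] / 60.0  # per second
        return k20 * np.exp(-_E_ACT[kind] * (1.0 / temp - 1.0 / _T_REF) / R_CAL)

    k_acid_ref, k_base_ref, k_water_ref = arrh("acid"), arrh("base"), arrh("water")
    conc_h = 10.0**-ph
    conc_oh = 10.0 ** (ph - _PKW)

    rows = []
    n = len(seq)
    for i in range(2, n + 1):  # residue numbers, 1-based
        aa = seq[i - 1]
        prev = seq[i - 2]
        if aa == "P":
            continue
        la_a = factors.loc[aa, "acid_lambda"]
        la_b = factors.loc[aa, "base_lambda"]
        rho_a = factors.loc[prev, "acid_rho"]
        rho_b = factors.loc[prev, "base_rho"]
        log_fa = la_a + rho_a
        log_fb = la_b + rho_b
        if i == n:
            log_fa += factors.loc["CT", "acid_lambda"]
            log_fb += factors.loc["CT", "base_lambda"]
        elif i == 2:
            log_fa += factors.loc["NT", "acid_rho"]
            log_fb += factors.loc["NT", "base_rho"]
        fa, fb = 10.0**log_fa, 10.0**log_fb
        k_acid = fa * k_acid_ref * conc_h
        k_base = fb * k_base_ref * conc_oh
        k_water = fb * k_water_ref
        rows.append(
            {
                "residue": i,
                "aa": aa,
                "k_acid": k_acid,
                "k_base": k_base,
                "k_water": k_water,
                "k_ex": k_acid + k_base + k_water,
            }
        )
    return pd.DataFrame(rows).set_index("residue")


def count_fast_exchangers(
    profile: pd.DataFrame, threshold: float
) -> Tuple[int, Optional[float], Optional[float]]:
    """Count residues with k_ex strictly above the threshold (s^-1);
    returns (count, min_rate_above, max_rate_above)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    fast = profile.loc[profile["k_ex"] > threshold, "k_ex"]
    if fast.empty:
        return 0, None, None
    return int(fast.size), float(fast.min()), float(fast.max())


def protection_report(
    profile: pd.DataFrame, observed_residues: Iterable[int], threshold: float
) -> pd.DataFrame:
    """Cross-reference experimentally observed amides against predicted
    intrinsic rates.

    A residue whose amide is observed despite a predicted k_ex above the
    threshold would have exchanged too fast to detect in a true random
    coil, so its visibility indicates structural protection.  Returns the
    per-residue table (k_ex, above-threshold flag) with the summary count
    in ``.attrs["n_protected"]``.
    """
    observed = sorted(set(int(r) for r in observed_residues))
    bad = [r for r in observed if r not in profile.index]
    if bad:
        raise ValueError(f"observed residues not in profile: {bad}")
    sub = profile.loc[observed, ["aa", "k_ex"]].copy()
    sub["fast"] = sub["k_ex"] > threshold
    sub.attrs["n_protected"] = int(sub["fast"].sum())
    return sub
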