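#!/usr/bin/env python
"""Desk-scale stoichiometry bracket: empirical monomer radii, sphere
volumes, and the subunit-count bounds for the large oligomer envelope."""

import json
from pathlib import Path

from oligoprobe import hydro

ROOT = Path(__file__).resolve().parent.parent / "results"

N_RESIDUES = 124
OLIGOMER_RH_A = 81.0


def main() -> None:
    rh_glob = hydro.rh_empirical(N_RESIDUES, "globular")
    rh_denat = hydro.rh_empirical(N_RESIDUES, "denatured")
    v_glob = hydro.sphere_volume(rh_glob)
    v_denat = hydro.sphere_volume(rh_denat)
    v_olig = hydro.sphere_volume(OLIGOMER_RH_A)
    bounds = hydro.subunit_bounds(v_olig, v_glob, v_denat)

    summary = {
        "n_residues": N_RESIDUES,
        "rh_globular_A": rh_glob,
        "rh_denatured_A": rh_denat,
        "v_globular_A3": v_glob,
        "v_denatured_A3": v_denat,
        "oligomer_rh_A": OLIGOMER_RH_A,
        "v_oligomer_A3": v_olig,
        "n_subunits_min": bounds.n_min,
        "n_subunits_max": bounds.n_max,
    }
    ROOT.mkdir(parents=True, exist_ok=True)
    (ROOT / "stoichiometry.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
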