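#!/usr/bin/env python
"""SPR kinetics: global 1:1 fit of the simulated concentration series and
the implied equilibrium binding curve."""

import json
from pathlib import Path

import numpy as np

from oligoprobe import binding, io

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    grams = io.read_sensorgrams(ROOT / "data" / "spr_series.csv")
    fit = binding.global_fit(grams)

    concs = np.logspace(-8, -5, 25)
    with open(ROOT / "spr_equilibrium.csv", "w") as fh:
        fh.write("conc_M,req_RU\n")
        for c in concs:
            fh.write(f"{c:.6e},{binding.equilibrium_response(fit, c):.6f}\n")

    summary = {
        "kon_M-1s-1": fit.kon,
        "koff_s-1": fit.koff,
        "rmax_RU": fit.rmax,
        "kd_app_M": fit.kd_app,
        "kd_app_uM": fit.kd_app * 1e6,
        "residual_sd_RU": fit.residual_sd,
        "koff_at_bound": fit.koff_at_bound,
    }
    (ROOT / "spr_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
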