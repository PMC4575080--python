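#!/usr/bin/env python
"""Generate the synthetic datasets used by the downstream analysis scripts.

All data here are synthetic stand-ins with known ground truth; every
generator is seeded so the whole analysis tree is reproducible byte for
byte.
"""

from pathlib import Path

from oligoprobe import io, sec_cd, synthetic
from oligoprobe.datatypes import MotionModel

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 20150923

SPHERE_RADIUS_A = 99.4
KON, KOFF, RMAX = 1.0e5, 5.5e-2, 100.0
STANDARDS = [(86.0, 7.2), (45.6, 9.1), (36.2, 9.9), (21.4, 11.8), (16.3, 12.6)]
SPECIES = [(23.8, 0.666, 0.25), (29.9, 0.277, 0.25), (86.0, 0.057, 0.3)]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # SAXS: large sphere mimicking the oligomer envelope, 1% relative noise
    curve = synthetic.gen_sphere_saxs(SPHERE_RADIUS_A, noise_sd=0.01, seed=SEED)
    io.write_saxs_dat(curve, OUT / "saxs_oligomer.dat")

    # SEC: three-species chromatogram on the calibrated column
    cal = sec_cd.fit_calibration(STANDARDS)
    chrom, truth = synthetic.gen_chromatogram(SPECIES, cal, noise_sd=0.006,
                                              seed=SEED)
    with open(OUT / "sec_chromatogram.csv", "w") as fh:
        fh.write("volume_mL,absorbance\n")
        for v, a in zip(chrom.volume, chrom.absorbance):
            fh.write(f"{v:.6f},{a:.8f}\n")

    # SPR: concentration series at the published-style rate constants
    grams = synthetic.gen_sensorgram(KON, KOFF, RMAX, noise_sd=0.01 * RMAX,
                                     seed=SEED)
    io.write_sensorgrams(grams, OUT / "spr_series.csv")

    # NMR shifts: partially folded table (two helices, one strand) at 0.1 ppm
    # jitter, plus an all-coil control
    table = synthetic.gen_shift_table(
        124, [(70, 83, "helix"), (88, 94, "strand"), (100, 112, "helix")],
        jitter_sd=0.1, seed=SEED,
    )
    io.write_shift_table(table, OUT / "shifts_partial_fold.csv",
                         condition="synthetic partial fold")
    coil = synthetic.gen_shift_table(124, [])
    io.write_shift_table(coil, OUT / "shifts_coil.csv", condition="synthetic coil")

    # Relaxation decays for the disordered-oligomer motional model
    motion = MotionModel(s2f=0.5, s2s=0.32, tau_f=100e-12, tau_s=1.4e-9,
                         tau_m=17e-9)
    data = synthetic.gen_relax_decay(motion, noise_sd=0.02, seed=SEED)
    with open(OUT / "relax_decays.csv", "w") as fh:
        fh.write("series,delay_s,height\n")
        for key in ("r1_series", "r2_series"):
            s = data[key]
            for d, h in zip(s.delays, s.heights):
                fh.write(f"{key},{d:.6f},{h:.8f}\n")

    print(f"wrote synthetic datasets to {OUT}")


if __name__ == "__main__":
    main()
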