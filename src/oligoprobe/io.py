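"""File formats shared by the analysis stages.

SAXS curves travel as 3-column whitespace-delimited .dat (q, I, sigma;
'#' comments); P(r) as a 2-column table with a header block; tabular data
(shift tables, decay series, sensorgrams, chromatograms, standards) as CSV
with header rows; sequences as FASTA via Biopython.  Writers produce files
their own readers accept.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .datatypes import (
    PairDistribution,
    ScatteringCurve,
    Sensorgram,
    SequenceRecord,
)

PathLike = Union[str, Path]


def read_saxs_dat(path: PathLike) -> ScatteringCurve:
    """Read a 3-column (q, I, sigma) or 2-column (q, I) scattering file."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) not in (2, 3):
                raise ValueError(
                    f"{path}:{ln}: expected 2 or 3 columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-numeric field") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError(f"{path}: inconsistent column count")
    arr = np.array(rows)
    sigma = arr[:, 2] if ncol == 3 else None
    return ScatteringCurve(q=arr[:, 0], intensity=arr[:, 1], sigma=sigma)


def write_saxs_dat(curve: ScatteringCurve, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# q_invA intensity sigma\n")
        sigma = (
            curve.sigma
            if curve.sigma is not None
            else np.full_like(curve.q, np.nan)
        )
        for q, i, s in zip(curve.q, curve.intensity, sigma):
            if np.isnan(s):
                fh.write(f"{q:.8e} {i:.8e}\n")
            else:
                fh.write(f"{q:.8e} {i:.8e} {s:.8e}\n")


def write_pr(dist: PairDistribution, path: PathLike) -> None:
    """P(r) as a 2-column table with a header block recording dmax, alpha
    and the real-space Rg."""
    with open(path, "w") as fh:
        fh.write(f"# dmax_A {dist.dmax:.6g}\n")
        fh.write(f"# alpha {dist.alpha:.6g}\n")
        fh.write(f"# rg_real_A {dist.rg_real:.6g}\n")
        fh.write("# r_A p\n")
        for r, p in zip(dist.r, dist.p):
            fh.write(f"{r:.6e} {p:.6e}\n")


def read_pr(path: PathLike) -> PairDistribution:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s.startswith("#"):
                parts = s[1:].split()
                if len(parts) == 2:
                    try:
                        meta[parts[0]] = float(parts[1])
                    except ValueError:
                        pass
                continue
            if s:
                r, p = s.split()
                rows.append((float(r), float(p)))
    arr = np.array(rows)
    return PairDistribution(
        r=arr[:, 0],
        p=arr[:, 1],
        dmax=meta.get("dmax_A", float(arr[-1, 0])),
        rg_real=meta.get("rg_real_A", float("nan")),
        alpha=meta.get("alpha", float("nan")),
        i0=float("nan"),
        chi2_reduced=float("nan"),
    )


def read_shift_table(path: PathLike) -> pd.DataFrame:
    """Long-format CSV (residue, aa, nucleus, ppm[, condition]) pivoted to
    the wide per-residue table the shift analyses consume."""
    df = pd.read_csv(path, comment="#")
    required = {"residue", "aa", "nucleus", "ppm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    wide = df.pivot_table(
        index="residue", columns="nucleus", values="ppm", aggfunc="first"
    )
    aa = df.groupby("residue")["aa"].first()
    wide.insert(0, "aa", aa)
    wide.columns.name = None
    return wide.sort_index()


def write_shift_table(table: pd.DataFrame, path: PathLike, condition: str = "") -> None:
    rows = []
    for res, row in table.iterrows():
        for nuc in table.columns:
            if nuc == "aa" or pd.isna(row[nuc]):
                continue
            rows.append(
                {
                    "residue": res,
                    "aa": row["aa"],
                    "nucleus": nuc,
                    "ppm": row[nuc],
                    "condition": condition,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sensorgrams(path: PathLike) -> List[Sensorgram]:
    """CSV with columns time_s, response_RU, conc_M, t_stop_s; one
    sensorgram per concentration."""
    df = pd.read_csv(path, comment="#")
    out = []
    for conc, grp in df.groupby("conc_M"):
        out.append(
            Sensorgram(
                time=grp["time_s"].to_numpy(),
                response=grp["response_RU"].to_numpy(),
                analyte_conc=float(conc),
                t_stop=float(grp["t_stop_s"].iloc[0]),
            )
        )
    return out


def write_sensorgrams(grams: Sequence[Sensorgram], path: PathLike) -> None:
    frames = []
    for g in grams:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": g.time,
                    "response_RU": g.response,
                    "conc_M": g.analyte_conc,
                    "t_stop_s": g.t_stop,
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False)


def read_fasta(path: PathLike, ph: float = 7.0, temperature: float = 286.15) -> SequenceRecord:
    rec = next(SeqIO.parse(str(path), "fasta"))
    return SequenceRecord(
        id=rec.id, sequence=str(rec.seq), ph=ph, temperature=temperature
    )


def bundled_standin_record(ph: float = 7.0, temperature: float = 286.15) -> SequenceRecord:
    """The bundled SYNTHETIC stand-in sequence (see its FASTA header)."""
    path = resources.files("oligoprobe.data").joinpath(
        "bex3_standin_synthetic.fasta"
    )
    with resources.as_file(path) as p:
        return read_fasta(p, ph=ph, temperature=temperature)
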