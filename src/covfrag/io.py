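"""CSV/SMILES readers and writers for the assay interfaces.

All tabular inputs are comma-separated, dot-decimal, UTF-8 with a
mandatory header row. Readers validate the expected columns and raise
line-numbered errors on malformed rows instead of silently coercing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .chemlib import Structure
from .dtnb import PlateKineticRun
from .dsf import MeltCurve
from .gsh import AucSeries
from .solubility import TurbidityTrace

__all__ = [
    "MalformedInputError",
    "read_smiles_file",
    "read_table",
    "read_turbidity_csv",
    "read_dtnb_csv",
    "read_gsh_csv",
    "read_dsf_csv",
]


class MalformedInputError(ValueError):
    """An input file violates the expected dialect; message names the line."""


def read_smiles_file(path: str | Path) -> list[Structure]:
    """Read a SMILES file: one record per line, ``notation whitespace id``."""
    structures = []
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise MalformedInputError(
                f"{path.name}:{lineno}: expected 'SMILES id', got {line!r}"
            )
        smiles, mol_id = parts
        structures.append(Structure(id=mol_id.strip(), line_notation=smiles, source=str(path)))
    ids = [s.id for s in structures]
    if len(ids) != len(set(ids)):
        raise MalformedInputError(f"{path.name}: duplicate structure ids")
    return structures


def read_table(path: str | Path, required: tuple[str, ...], numeric: tuple[str, ...]) -> pd.DataFrame:
    """Read a CSV, check columns, and coerce numerics with line reporting."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MalformedInputError(f"{path.name}: missing columns {missing}")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise MalformedInputError(
                f"{path.name}:{bad[0] + 2}: non-numeric value in column {col!r}"
            )
        df[col] = coerced
    return df


def read_turbidity_csv(path: str | Path) -> dict[str, list[TurbidityTrace]]:
    """Long-format turbidity input -> traces grouped by compound id.

    Columns: id, concentration_mM, cycle_min, wavelength_nm, extinction_AU.
    """
    df = read_table(
        path,
        required=("id", "concentration_mM", "cycle_min", "wavelength_nm", "extinction_AU"),
        numeric=("concentration_mM", "cycle_min", "wavelength_nm", "extinction_AU"),
    )
    out: dict[str, list[TurbidityTrace]] = {}
    for (cid, conc), grp in df.groupby(["id", "concentration_mM"]):
        pivot = grp.pivot_table(
            index="cycle_min", columns="wavelength_nm", values="extinction_AU"
        ).sort_index()
        out.setdefault(str(cid), []).append(
            TurbidityTrace(
                concentration=float(conc),
                cycle_times=tuple(float(t) for t in pivot.index),
                wavelengths=tuple(float(w) for w in pivot.columns),
                extinction=pivot.to_numpy(),
            )
        )
    return out


def read_dtnb_csv(
    path: str | Path, a0: float = 100e-6, b0: float = 50e-6
) -> dict[str, PlateKineticRun]:
    """Long-format DTNB plate input -> runs keyed by compound id.

    Columns: compound_id, replicate, channel (reaction | background |
    blank), time_s, a412. The blank channel is shared per compound.
    """
    df = read_table(
        path,
        required=("compound_id", "replicate", "channel", "time_s", "a412"),
        numeric=("time_s", "a412"),
    )
    bad_channel = ~df["channel"].isin(["reaction", "background", "blank"])
    if bad_channel.any():
        row = df.index[bad_channel][0]
        raise MalformedInputError(f"{Path(path).name}:{row + 2}: unknown channel")
    runs = {}
    for cid, grp in df.groupby("compound_id"):
        times = np.sort(grp["time_s"].unique())

        def matrix(channel, g=grp):
            ch = g[g["channel"] == channel]
            piv = ch.pivot_table(index="replicate", columns="time_s", values="a412")
            return piv.sort_index().to_numpy()

        blank = matrix("blank")
        runs[str(cid)] = PlateKineticRun(
            times=times.astype(float),
            a412_reaction=matrix("reaction"),
            a412_compound_background=matrix("background"),
            a412_blank=blank[0],
            nominal_A0=a0,
            nominal_B0=b0,
        )
    return runs


def read_gsh_csv(path: str | Path) -> dict[tuple[str, str, int], AucSeries]:
    """HPLC input -> series keyed by (compound_id, condition, replicate).

    Columns: compound_id, condition (GSH | PBS), replicate, time_h,
    fragment_auc, standard_auc. Empty fragment_auc cells mark missing
    peaks.
    """
    df = read_table(
        path,
        required=("compound_id", "condition", "replicate", "time_h", "fragment_auc", "standard_auc"),
        numeric=("time_h", "standard_auc"),
    )
    df["fragment_auc"] = pd.to_numeric(df["fragment_auc"], errors="coerce")
    out = {}
    for (cid, cond, rep), grp in df.groupby(["compound_id", "condition", "replicate"]):
        grp = grp.sort_values("time_h")
        out[(str(cid), str(cond), int(rep))] = AucSeries(
            times=grp["time_h"].to_numpy(),
            fragment_auc=grp["fragment_auc"].to_numpy(),
            standard_auc=grp["standard_auc"].to_numpy(),
            condition=str(cond),
        )
    return out


def read_dsf_csv(path: str | Path) -> list[MeltCurve]:
    """Melt-curve input -> one curve per (construct, compound, condition,
    replicate).

    Columns: construct, compound_id, concentration_uM, incubation_h,
    replicate, temperature_C, fluorescence. Empty compound_id marks the
    protein-only reference wells.
    """
    df = read_table(
        path,
        required=(
            "construct",
            "compound_id",
            "concentration_uM",
            "incubation_h",
            "replicate",
            "temperature_C",
            "fluorescence",
        ),
        numeric=("concentration_uM", "incubation_h", "temperature_C", "fluorescence"),
    )
    df["compound_id"] = df["compound_id"].fillna("")
    curves = []
    keys = ["construct", "compound_id", "concentration_uM", "incubation_h", "replicate"]
    for (construct, cid, conc, inc, _rep), grp in df.groupby(keys):
        grp = grp.sort_values("temperature_C")
        curves.append(
            MeltCurve(
                temperatures=grp["temperature_C"].to_numpy(),
                fluorescence=grp["fluorescence"].to_numpy(),
                construct=str(construct),
                compound_id=str(cid) or None,
                concentration=float(conc),
                incubation=float(inc),
            )
        )
    return curves
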