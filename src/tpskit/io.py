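"""CSV readers/writers for the stage file formats.

All formats are long-form UTF-8 CSV with required headers:

- melt curves:  ``condition_id,protein_id,temperature_C,fluorescence``
- plates:       ``well,role,substrate_uM,analyte_uM,absorbance,replicate``
- peak tables:  ``sample_id,substrate,rt_min,area,compound,match_score``
- corpora:      see :func:`tpskit.screen.read_corpus` (JSONL or CSV)
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import InputError
from .profiles import Peak, PeakTable
from .thermal import MeltCurve

MELT_COLUMNS = ["condition_id", "protein_id", "temperature_C", "fluorescence"]
PLATE_COLUMNS = ["well", "role", "substrate_uM", "analyte_uM", "absorbance", "replicate"]
PEAK_COLUMNS = ["sample_id", "substrate", "rt_min", "area", "compound", "match_score"]


def write_melt_curves(curves: list[MeltCurve], path: str | Path) -> Path:
    frames = []
    for curve in curves:
        frames.append(
            pd.DataFrame(
                {
                    "condition_id": curve.condition_id,
                    "protein_id": curve.protein_id,
                    "temperature_C": curve.temperatures_C,
                    "fluorescence": curve.fluorescence_AU,
                }
            )
        )
    path = Path(path)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_melt_curves(path: str | Path) -> list[MeltCurve]:
    frame = pd.read_csv(path)
    missing = set(MELT_COLUMNS) - set(frame.columns)
    if missing:
        raise InputError(f"melt CSV missing columns {sorted(missing)}")
    curves = []
    for (cid, pid), grp in frame.groupby(["condition_id", "protein_id"], sort=False):
        curves.append(
            MeltCurve(str(cid), str(pid), grp["temperature_C"].to_numpy(),
                      grp["fluorescence"].to_numpy())
        )
    return curves


def write_plate(plate: pd.DataFrame, path: str | Path) -> Path:
    missing = set(PLATE_COLUMNS) - set(plate.columns)
    if missing:
        raise InputError(f"plate table missing columns {sorted(missing)}")
    path = Path(path)
    plate[PLATE_COLUMNS].to_csv(path, index=False)
    return path


def read_plate(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(PLATE_COLUMNS) - set(frame.columns)
    if missing:
        raise InputError(f"plate CSV missing columns {sorted(missing)}")
    return frame


def write_peak_tables(tables: list[PeakTable], path: str | Path) -> Path:
    frames = [t.to_frame()[PEAK_COLUMNS] for t in tables]
    path = Path(path)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_peak_tables(path: str | Path) -> list[PeakTable]:
    frame = pd.read_csv(path, keep_default_na=False, na_values=[""])
    missing = set(PEAK_COLUMNS) - set(frame.columns)
    if missing:
        raise InputError(f"peak CSV missing columns {sorted(missing)}")
    tables = []
    for (sid, sub), grp in frame.groupby(["sample_id", "substrate"], sort=False):
        peaks = tuple(
            Peak(
                rt_min=float(row["rt_min"]),
                area=float(row["area"]),
                compound=str(row["compound"]) if pd.notna(row["compound"]) and row["compound"] != "" else None,
                match_score=float(row["match_score"]) if pd.notna(row["match_score"]) else None,
            )
            for _, row in grp.iterrows()
        )
        tables.append(PeakTable(str(sid), str(sub), peaks))
    return tables
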