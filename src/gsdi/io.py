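"""Text-only cohort persistence.

A cohort is stored as a directory bundle:

* ``eyes.csv``     -- one row per eye (identity, group, MD/PSD, disc metrics,
  demographics, stage), row order defining the map row order;
* ``gcc_maps.csv`` / ``nfl_maps.csv`` -- one row per eye, flattened map
  values at full (%.17g) precision;
* ``region_gcc.csv`` / ``region_nfl.csv`` -- the shared region-label grids;
* ``meta.json``    -- grid shapes and format version.

All eyes in a cohort share one grid geometry; a shape mismatch on read is
an error.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import DiscMetrics, EyeRecord, ThicknessMap

_FORMAT_VERSION = 1

_EYE_COLUMNS = [
    "subject_id", "eye", "group", "md_db", "psd_db",
    "vcdr", "hcdr", "rim_volume", "true_stage", "age", "sex", "ethnicity",
]


def write_cohort(cohort: list[EyeRecord], path) -> Path:
    """Write a cohort bundle; returns the directory path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = []
    for e in cohort:
        rows.append({
            "subject_id": e.subject_id, "eye": e.eye, "group": e.group,
            "md_db": e.md_db, "psd_db": e.psd_db,
            "vcdr": e.disc.vcdr, "hcdr": e.disc.hcdr,
            "rim_volume": e.disc.rim_volume,
            "true_stage": e.true_stage if e.true_stage is not None else "",
            "age": e.age, "sex": e.sex, "ethnicity": e.ethnicity,
        })
    df = pd.DataFrame(rows, columns=_EYE_COLUMNS)
    df.to_csv(path / "eyes.csv", index=False, float_format="%.17g")

    meta = {"format_version": _FORMAT_VERSION, "n_eyes": len(cohort)}
    if cohort:
        shapes = {(e.gcc_map.values.shape, e.nfl_map.values.shape) for e in cohort}
        if len(shapes) != 1:
            raise ValueError("all eyes in a cohort must share one grid geometry")
        gcc_shape, nfl_shape = next(iter(shapes))
        meta["gcc_shape"] = list(gcc_shape)
        meta["nfl_shape"] = list(nfl_shape)
        gcc_stack = np.stack([e.gcc_map.values.ravel() for e in cohort])
        nfl_stack = np.stack([e.nfl_map.values.ravel() for e in cohort])
        np.savetxt(path / "gcc_maps.csv", gcc_stack, fmt="%.17g", delimiter=",")
        np.savetxt(path / "nfl_maps.csv", nfl_stack, fmt="%.17g", delimiter=",")
        np.savetxt(path / "region_gcc.csv", cohort[0].gcc_map.region,
                   fmt="%d", delimiter=",")
        np.savetxt(path / "region_nfl.csv", cohort[0].nfl_map.region,
                   fmt="%d", delimiter=",")
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return path


def read_cohort(path) -> list[EyeRecord]:
    """Read a cohort bundle written by :func:`write_cohort`."""
    path = Path(path)
    with open(path / "meta.json") as fh:
        meta = json.load(fh)
    df = pd.read_csv(path / "eyes.csv",
                     dtype={"subject_id": str, "eye": str, "group": str},
                     keep_default_na=False, na_values=[],
                     float_precision="round_trip")
    if int(meta["n_eyes"]) != len(df):
        raise ValueError("meta.json eye count disagrees with eyes.csv")
    if df.empty:
        return []

    gcc_shape = tuple(meta["gcc_shape"])
    nfl_shape = tuple(meta["nfl_shape"])
    gcc_stack = np.loadtxt(path / "gcc_maps.csv", delimiter=",", ndmin=2)
    nfl_stack = np.loadtxt(path / "nfl_maps.csv", delimiter=",", ndmin=2)
    if gcc_stack.shape != (len(df), int(np.prod(gcc_shape))):
        raise ValueError("GCC map matrix does not match the declared grid shape")
    if nfl_stack.shape != (len(df), int(np.prod(nfl_shape))):
        raise ValueError("NFL map matrix does not match the declared grid shape")
    region_gcc = np.loadtxt(path / "region_gcc.csv", delimiter=",",
                            dtype=np.int8, ndmin=2)
    region_nfl = np.loadtxt(path / "region_nfl.csv", delimiter=",",
                            dtype=np.int8, ndmin=2)
    if region_gcc.shape != gcc_shape or region_nfl.shape != nfl_shape:
        raise ValueError("region grids do not match the declared grid shape")

    cohort = []
    for i, row in df.iterrows():
        stage = row["true_stage"] or None
        cohort.append(EyeRecord(
            subject_id=row["subject_id"], eye=row["eye"], group=row["group"],
            md_db=float(row["md_db"]), psd_db=float(row["psd_db"]),
            gcc_map=ThicknessMap(gcc_stack[i].reshape(gcc_shape),
                                 region_gcc, "GCC"),
            nfl_map=ThicknessMap(nfl_stack[i].reshape(nfl_shape),
                                 region_nfl, "NFL"),
            disc=DiscMetrics(vcdr=float(row["vcdr"]), hcdr=float(row["hcdr"]),
                             rim_volume=float(row["rim_volume"])),
            true_stage=str(stage) if stage is not None else None,
            age=float(row["age"]), sex=row["sex"], ethnicity=row["ethnicity"],
        ))
    return cohort
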