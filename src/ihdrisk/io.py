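"""Readers and writers for slices, masks and cohort tables.

Phantom cohorts are stored as paired image/mask datasets in one HDF5
container with a CSV manifest; EMR cohorts use a three-CSV layout
(encounters, observations, codes) plus a labels CSV.
"""

from __future__ import annotations

from datetime import date
from importlib import resources
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .emr.records import Code, Observation, PatientRecord
from .imaging import CTSlice, WindowSpec


def load_window_presets(path: str | Path | None = None) -> dict[str, WindowSpec]:
    """Window presets keyed soft/bone/custom from a YAML config."""
    if path is None:
        path = resources.files("ihdrisk.config") / "window_presets.yaml"
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {k: WindowSpec(v["width"], v["level"]) for k, v in raw.items()}


def save_slice_h5(path: str | Path, slc: CTSlice, mask: np.ndarray | None = None,
                  group: str = "/") -> None:
    """Write a slice (and optional mask) into an HDF5 group."""
    with h5py.File(path, "a") as fh:
        g = fh.require_group(group)
        for name in ("image", "mask"):
            if name in g:
                del g[name]
        ds = g.create_dataset("image", data=slc.pixels)
        ds.attrs["pixel_spacing_mm"] = slc.pixel_spacing_mm
        if mask is not None:
            g.create_dataset("mask", data=np.asarray(mask, dtype=np.uint8))


def load_slice_h5(path: str | Path, group: str = "/") -> tuple[CTSlice, np.ndarray | None]:
    with h5py.File(path, "r") as fh:
        g = fh[group]
        spacing = tuple(float(s) for s in g["image"].attrs["pixel_spacing_mm"])
        slc = CTSlice(np.array(g["image"]), spacing)
        mask = np.array(g["mask"]) if "mask" in g else None
    return slc, mask


def save_imaging_cohort(directory: str | Path, cohort) -> Path:
    """Write an imaging cohort: one HDF5 of image/mask pairs + CSV manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    h5_path = directory / "phantoms.h5"
    if h5_path.exists():
        h5_path.unlink()
    rows = []
    for i, (slc, mask) in enumerate(zip(cohort.slices, cohort.masks)):
        grp = f"patient_{i:05d}"
        save_slice_h5(h5_path, slc, mask, group=grp)
        rows.append(
            {
                "patient_id": grp,
                "file": h5_path.name,
                "group": grp,
                "label": int(cohort.labels[i]),
                "true_linear_predictor": float(cohort.true_linear_predictor[i]),
            }
        )
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    return directory


def save_emr_cohort(directory: str | Path, records: list[PatientRecord],
                    labels: np.ndarray | None = None) -> Path:
    """Write the three-CSV EMR layout (+ patients and optional labels)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "scan_date": r.scan_date,
                "birthdate": r.birthdate,
                "sex": r.sex,
            }
            for r in records
        ]
    ).to_csv(directory / "patients.csv", index=False)
    pd.DataFrame(
        [{"patient_id": r.patient_id, "date": e} for r in records for e in r.encounters]
    ).to_csv(directory / "encounters.csv", index=False)
    pd.DataFrame(
        [
            {"patient_id": r.patient_id, "date": o.when, "name": o.name, "value": o.value}
            for r in records
            for o in r.observations
        ]
    ).to_csv(directory / "observations.csv", index=False)
    pd.DataFrame(
        [
            {"patient_id": r.patient_id, "date": c.when, "system": c.system, "code": c.code}
            for r in records
            for c in r.codes
        ]
    ).to_csv(directory / "codes.csv", index=False)
    if labels is not None:
        pd.DataFrame(
            {"patient_id": [r.patient_id for r in records], "label": np.asarray(labels, int)}
        ).to_csv(directory / "labels.csv", index=False)
    return directory


def _to_date(s) -> date:
    return pd.Timestamp(s).date()


def load_emr_cohort(directory: str | Path) -> list[PatientRecord]:
    """Read records back from the three-CSV layout."""
    directory = Path(directory)
    patients = pd.read_csv(directory / "patients.csv")
    enc = pd.read_csv(directory / "encounters.csv")
    obs = pd.read_csv(directory / "observations.csv")
    codes = pd.read_csv(directory / "codes.csv")
    records = []
    for _, row in patients.iterrows():
        pid = row["patient_id"]
        records.append(
            PatientRecord(
                patient_id=pid,
                scan_date=_to_date(row["scan_date"]),
                birthdate=_to_date(row["birthdate"]),
                sex=str(row["sex"]),
                encounters=[_to_date(d) for d in enc.loc[enc.patient_id == pid, "date"]],
                observations=[
                    Observation(_to_date(r.date), r.name, float(r.value))
                    for r in obs.loc[obs.patient_id == pid].itertuples()
                ],
                codes=[
                    Code(_to_date(r.date), str(r.system), str(r.code))
                    for r in codes.loc[codes.patient_id == pid].itertuples()
                ],
            )
        )
    return records
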