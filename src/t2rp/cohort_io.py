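"""On-disk cohort layout: per-patient NIfTI volumes plus a cohort CSV.

Layout written by :func:`write_cohort` and consumed by :func:`read_cohort`::

    <dir>/cohort.csv                 id, rp_grade, dates, prescription
    <dir>/meta.yaml                  echo times, spacing, axis convention
    <dir>/<id>/echo_00.nii.gz ...    one volume per echo
    <dir>/<id>/mask_lung.nii.gz      binary masks (uint8)
    <dir>/<id>/mask_gtv.nii.gz
    <dir>/<id>/mask_ptv.nii.gz
    <dir>/<id>/mask_rp_truth.nii.gz
    <dir>/<id>/dose.nii.gz           physical dose (Gy)
    <dir>/<id>/t2_truth.nii.gz       simulation ground truth (ms)
"""

from __future__ import annotations

from datetime import date
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .nifti import read_volume, write_volume
from .phantom import cohort_table
from .types import DoseGrid, MultiEchoSeries, PatientCase, QuantitativeMap, StructureSet

__all__ = ["write_cohort", "read_cohort"]

_MASK_NAMES = ("lung", "gtv", "ptv", "rp_truth")


def write_cohort(cases: Sequence[PatientCase], out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    first = cases[0]
    meta = {
        "te_ms": [float(t) for t in first.series.te_ms],
        "spacing_mm": [float(s) for s in first.series.spacing_mm],
        "n_fractions": {c.id: int(c.dose.n_fractions) for c in cases},
        "dose_per_fraction_gy": {c.id: float(c.dose.dose_per_fraction_gy) for c in cases},
    }
    with open(out / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    cohort_table(list(cases)).to_csv(out / "cohort.csv", index=False)
    for c in cases:
        pdir = out / c.id
        pdir.mkdir(exist_ok=True)
        for e in range(c.series.n_echoes):
            write_volume(pdir / f"echo_{e:02d}.nii.gz", c.series.signals[e], c.series.spacing_mm)
        for name in _MASK_NAMES:
            if name in c.structures:
                write_volume(pdir / f"mask_{name}.nii.gz", c.structures[name], c.structures.spacing_mm)
        write_volume(pdir / "dose.nii.gz", c.dose.values, c.dose.spacing_mm)
        if c.truth_t2 is not None:
            write_volume(pdir / "t2_truth.nii.gz", c.truth_t2.values, c.truth_t2.spacing_mm)
    return out


def read_cohort(in_dir) -> list[PatientCase]:
    root = Path(in_dir)
    with open(root / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    te_ms = np.asarray(meta["te_ms"], dtype=float)
    spacing = tuple(meta["spacing_mm"])
    table = pd.read_csv(root / "cohort.csv")
    cases: list[PatientCase] = []
    for _, row in table.iterrows():
        pid = str(row["id"])
        pdir = root / pid
        echo_paths = sorted(pdir.glob("echo_*.nii.gz"))
        if len(echo_paths) != te_ms.size:
            raise FileNotFoundError(
                f"patient {pid}: expected {te_ms.size} echo volumes, found {len(echo_paths)}"
            )
        signals = np.stack([read_volume(p)[0] for p in echo_paths])
        series = MultiEchoSeries(signals=signals, te_ms=te_ms, spacing_mm=spacing)
        masks = {}
        for name in _MASK_NAMES:
            p = pdir / f"mask_{name}.nii.gz"
            if p.exists():
                masks[name] = read_volume(p)[0] > 0
        structs = StructureSet(masks=masks, spacing_mm=spacing)
        dose_values, _ = read_volume(pdir / "dose.nii.gz")
        dose = DoseGrid(
            values=dose_values,
            kind="physical",
            n_fractions=int(row["prescription_n"]),
            dose_per_fraction_gy=float(row["prescription_d_gy"]),
            spacing_mm=spacing,
        )
        truth = None
        tpath = pdir / "t2_truth.nii.gz"
        if tpath.exists():
            truth = QuantitativeMap(read_volume(tpath)[0], spacing)
        cases.append(
            PatientCase(
                id=pid,
                series=series,
                structures=structs,
                dose=dose,
                rp_grade=int(row["rp_grade"]),
                fupct_date=date.fromisoformat(str(row["fupct_date"])),
                fupmri_date=date.fromisoformat(str(row["fupmri_date"])),
                truth_t2=truth,
            )
        )
    return cases
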