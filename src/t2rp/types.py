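"""Core in-memory containers shared by every pipeline stage.

All volumes live on a common voxel grid indexed ``(x, y, z)`` in a fixed
canonical orientation: axis 0 is left-right, axis 1 cranio-caudal and axis 2
anterior-posterior (the coronal slice axis of the multi-echo acquisition).
Physical distances are always derived from ``spacing_mm``; masks are stored
as 0/1 integer (or boolean) volumes with 0-based voxel indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Optional

import numpy as np

__all__ = [
    "GridMismatchError",
    "MultiEchoSeries",
    "QuantitativeMap",
    "DoseGrid",
    "StructureSet",
    "RegionParameters",
    "PatientCase",
]


class GridMismatchError(ValueError):
    """Raised when volumes that must share a grid do not."""


def _as_spacing(spacing_mm) -> tuple[float, float, float]:
    s = tuple(float(v) for v in spacing_mm)
    if len(s) != 3 or any(v <= 0 for v in s):
        raise ValueError(f"spacing_mm must be three positive values, got {spacing_mm!r}")
    return s


@dataclass
class MultiEchoSeries:
    """A stack of co-registered 3D echo volumes with their echo times.

    Parameters
    ----------
    signals:
        Array of shape ``(n_echoes, nx, ny, nz)`` holding the magnitude
        signal of each echo in arbitrary units.
    te_ms:
        Strictly increasing echo times in milliseconds, one per volume.
    spacing_mm:
        Per-axis voxel size in millimetres.
    """

    signals: np.ndarray
    te_ms: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals)
        self.te_ms = np.asarray(self.te_ms, dtype=float)
        self.spacing_mm = _as_spacing(self.spacing_mm)
        if self.signals.ndim != 4:
            raise GridMismatchError(
                f"signals must be (n_echoes, nx, ny, nz), got shape {self.signals.shape}"
            )
        if self.te_ms.ndim != 1 or self.te_ms.size != self.signals.shape[0]:
            raise ValueError("te_ms must have one entry per echo volume")
        if self.te_ms.size < 2:
            raise ValueError("at least two echoes are required")
        if np.any(self.te_ms <= 0) or np.any(np.diff(self.te_ms) <= 0):
            raise ValueError("te_ms must be positive and strictly increasing")

    @property
    def n_echoes(self) -> int:
        return int(self.signals.shape[0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.signals.shape[1:])


@dataclass
class QuantitativeMap:
    """One 3D scalar field (e.g. a T2 map in ms) on the common grid.

    ``valid_mask`` marks voxels whose value comes from a trustworthy fit;
    region statistics are only ever taken over valid voxels.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    valid_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.spacing_mm = _as_spacing(self.spacing_mm)
        if self.values.ndim != 3:
            raise GridMismatchError("QuantitativeMap values must be 3D")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask).astype(bool)
            if self.valid_mask.shape != self.values.shape:
                raise GridMismatchError("valid_mask shape does not match values")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("map values must be finite inside valid_mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)


@dataclass
class DoseGrid:
    """A 3D dose distribution in Gy, either physical or EQD2.

    ``kind`` only transitions ``"physical" -> "eqd2"`` through
    :func:`t2rp.dosimetry.eqd2`; the fractionation scheme that produced the
    physical dose is carried along for that conversion.
    """

    values: np.ndarray
    kind: str
    n_fractions: int
    dose_per_fraction_gy: float
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.spacing_mm = _as_spacing(self.spacing_mm)
        if self.kind not in ("physical", "eqd2"):
            raise ValueError(f"kind must be 'physical' or 'eqd2', got {self.kind!r}")
        if self.values.ndim != 3:
            raise GridMismatchError("DoseGrid values must be 3D")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")

    @property
    def prescription_gy(self) -> float:
        return self.n_fractions * self.dose_per_fraction_gy

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)


@dataclass
class StructureSet:
    """Named binary masks (lung, gtv, ptv, v20, rp_truth, ...) on one grid.

    ``lung_subvolumes`` holds the six cranio-caudal lung bands as an integer
    label volume (labels 1-6, 0 outside lung); ``reference_subvolume_id`` is
    the band used for the baseline correction once selected.
    """

    masks: dict
    spacing_mm: tuple[float, float, float]
    lung_subvolumes: Optional[np.ndarray] = None
    reference_subvolume_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.spacing_mm = _as_spacing(self.spacing_mm)
        shapes = {np.asarray(m).shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise GridMismatchError(f"masks on mixed grids: {sorted(shapes)}")
        self.masks = {k: np.asarray(m).astype(bool) for k, m in self.masks.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(next(iter(self.masks.values())).shape)


@dataclass
class RegionParameters:
    """Per-patient region means of the baseline-corrected T2 map (ms)."""

    t2_ref_ms: float
    t2_ptv_mean_ms: float
    t2_v20_minus_gtv_mean_ms: float


@dataclass
class PatientCase:
    """One patient's series, structures, dose, outcome and follow-up dates."""

    id: str
    series: Optional[MultiEchoSeries]
    structures: StructureSet
    dose: DoseGrid
    rp_grade: int
    fupct_date: Optional[date] = None
    fupmri_date: Optional[date] = None
    truth_t2: Optional[QuantitativeMap] = None
    t2_map: Optional[QuantitativeMap] = None
    t2_corr: Optional[QuantitativeMap] = None
    extras: dict = field(default_factory=dict)

    @property
    def is_rp(self) -> bool:
        return self.rp_grade >= 1

    @property
    def gap_days(self) -> Optional[int]:
        if self.fupct_date is None or self.fupmri_date is None:
            return None
        return abs((self.fupct_date - self.fupmri_date).days)
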