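"""Dose conversion and dose-derived geometry.

EQD2 conversion follows the linear-quadratic model: for a voxel receiving
total dose D in n fractions (per-fraction dose d = D/n),

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta)

so that EQD2 equals D exactly at 2 Gy per fraction.  The V20 region is the
lung volume receiving strictly more than 20 Gy, evaluated on the EQD2 grid.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import DoseGrid, GridMismatchError

__all__ = ["eqd2", "compute_v20", "expand_margin"]

DEFAULT_ALPHA_BETA_GY = 3.0
DEFAULT_V20_THRESHOLD_GY = 20.0


def eqd2(dose: DoseGrid, alpha_beta_gy: float = DEFAULT_ALPHA_BETA_GY) -> DoseGrid:
    """Convert a physical dose grid to equi-effective dose in 2 Gy fractions.

    Parameters
    ----------
    dose:
        Physical dose grid; its fractionation scheme supplies the number of
        fractions used for the voxel-wise per-fraction dose.
    alpha_beta_gy:
        Tissue alpha/beta ratio in Gy (3 Gy for lung toxicity endpoints).
    """
    if dose.kind != "physical":
        raise ValueError(f"eqd2 expects a physical dose grid, got kind={dose.kind!r}")
    if alpha_beta_gy <= -2.0:
        raise ValueError("alpha_beta_gy must be > -2 (EQD2 denominator 2 + alpha/beta)")
    d = dose.values / dose.n_fractions
    values = dose.values * (d + alpha_beta_gy) / (2.0 + alpha_beta_gy)
    return DoseGrid(
        values=values,
        kind="eqd2",
        n_fractions=dose.n_fractions,
        dose_per_fraction_gy=dose.dose_per_fraction_gy,
        spacing_mm=dose.spacing_mm,
    )


def compute_v20(
    dose_eqd2: DoseGrid, lung: np.ndarray, threshold_gy: float = DEFAULT_V20_THRESHOLD_GY
) -> np.ndarray:
    """Mask of lung voxels whose EQD2 dose strictly exceeds ``threshold_gy``."""
    if dose_eqd2.kind != "eqd2":
        raise ValueError("compute_v20 expects an EQD2 dose grid; call eqd2() first")
    lung = np.asarray(lung).astype(bool)
    if lung.shape != dose_eqd2.shape:
        raise GridMismatchError("lung mask and dose grid shapes differ")
    return lung & (dose_eqd2.values > threshold_gy)


def expand_margin(mask: np.ndarray, margin_mm: float, spacing_mm) -> np.ndarray:
    """Dilate a binary mask by a physical margin (mm), anisotropy-aware.

    A voxel belongs to the result iff its centre lies within ``margin_mm``
    of the centre of some mask voxel (Euclidean distance in mm).  With
    ``margin_mm=0`` this is the identity.  Used to build the PTV as the GTV
    plus an isotropic 5 mm margin.
    """
    mask = np.asarray(mask).astype(bool)
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    if not mask.any():
        raise ValueError("cannot expand an empty mask")
    if margin_mm == 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing_mm)
    return dist <= margin_mm
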