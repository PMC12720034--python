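"""Lung subdivision, reference-region selection and baseline correction.

Because no pre-treatment T2 map exists, each patient's T2 map is corrected
against distant healthy lung: the lung is split into six sub-volumes (three
cranio-caudal bands per lung), the band farthest from the tumor is selected,
and its mean T2 — averaged over the coronal slices in which the GTV is
defined, to limit gravitational anterior-posterior T2 gradients — is
subtracted voxel-wise:

    T2_baseline-corr = T2 - T2_ref(GTV slices)

The two stratification parameters are then region means of the corrected
map over the PTV and over (V20 intersect lung) minus GTV.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import GridMismatchError, QuantitativeMap, RegionParameters, StructureSet

__all__ = [
    "split_lung_subvolumes",
    "select_reference_subvolume",
    "reference_mean",
    "reference_mean_with_fallback",
    "baseline_correct",
    "region_mean",
    "extract_region_parameters",
]


def split_lung_subvolumes(lung: np.ndarray, cc_axis: int = 1) -> np.ndarray:
    """Partition the lung into six labelled cranio-caudal bands (1-6).

    Each of the two lung components is split into three contiguous bands of
    equal slice extent (+-1 slice) along ``cc_axis``.  The left lung (lower
    centroid along axis 0) gets labels 1-3, the right lung 4-6, each ordered
    by increasing cranio-caudal index.
    """
    lung = np.asarray(lung).astype(bool)
    comp, n = ndimage.label(lung)
    if n != 2:
        raise ValueError(f"expected exactly 2 lung components, found {n}")
    centroids = ndimage.center_of_mass(lung, comp, [1, 2])
    comp_order = sorted([1, 2], key=lambda c: centroids[c - 1][0])

    labels = np.zeros(lung.shape, dtype=np.int8)
    for lung_i, c in enumerate(comp_order):
        mask = comp == c
        occupied = np.flatnonzero(mask.any(axis=tuple(a for a in range(3) if a != cc_axis)))
        bands = np.array_split(occupied, 3)
        for band_i, band_slices in enumerate(bands):
            label = lung_i * 3 + band_i + 1
            sel = np.zeros(lung.shape[cc_axis], dtype=bool)
            sel[band_slices] = True
            bshape = [1, 1, 1]
            bshape[cc_axis] = lung.shape[cc_axis]
            labels[mask & sel.reshape(bshape)] = label
    return labels


def select_reference_subvolume(
    labels: np.ndarray, gtv: np.ndarray, spacing_mm
) -> int:
    """Sub-volume whose centroid is farthest (physical mm) from the GTV centroid.

    Ties are broken by the lowest label id for determinism.
    """
    gtv = np.asarray(gtv).astype(bool)
    if not gtv.any():
        raise ValueError("GTV mask is empty")
    spacing = np.asarray(spacing_mm, dtype=float)
    gtv_c = np.asarray(ndimage.center_of_mass(gtv)) * spacing
    ids = [int(v) for v in np.unique(labels) if v > 0]
    if not ids:
        raise ValueError("label volume contains no sub-volumes")
    best_id, best_d = ids[0], -1.0
    for i in ids:
        c = np.asarray(ndimage.center_of_mass(labels == i)) * spacing
        d = float(np.linalg.norm(c - gtv_c))
        if d > best_d + 1e-12:
            best_id, best_d = i, d
    return best_id


def reference_mean(
    t2map: QuantitativeMap,
    ref_subvol: np.ndarray,
    gtv: np.ndarray,
    coronal_axis: int = 2,
) -> float:
    """Mean reference T2 over the GTV-bearing coronal slices.

    For every coronal slice containing at least one GTV voxel, the mean
    valid-fit T2 inside the reference sub-volume on that slice is computed;
    the returned value is the unweighted mean of those per-slice means
    (slices without reference voxels contribute nothing).
    """
    ref = np.asarray(ref_subvol).astype(bool) & t2map.valid_mask
    gtv = np.asarray(gtv).astype(bool)
    if ref.shape != gtv.shape or ref.shape != t2map.shape:
        raise GridMismatchError("reference/GTV masks must share the map grid")
    other = tuple(a for a in range(3) if a != coronal_axis)
    gtv_slices = np.flatnonzero(gtv.any(axis=other))
    if gtv_slices.size == 0:
        raise ValueError("GTV mask is empty")
    slice_means = []
    for k in gtv_slices:
        sl = [slice(None)] * 3
        sl[coronal_axis] = k
        m = ref[tuple(sl)]
        if m.any():
            slice_means.append(float(t2map.values[tuple(sl)][m].mean()))
    if not slice_means:
        raise ValueError(
            "reference sub-volume has no valid voxels on GTV-bearing coronal "
            "slices; consider falling back to the next-farthest sub-volume"
        )
    return float(np.mean(slice_means))


def reference_mean_with_fallback(
    t2map: QuantitativeMap,
    labels: np.ndarray,
    gtv: np.ndarray,
    spacing_mm,
    coronal_axis: int = 2,
) -> tuple[float, int]:
    """Reference mean using the farthest sub-volume, falling back outward-in.

    Sub-volumes are tried in order of decreasing centroid distance from the
    GTV until one yields a defined reference mean.  Returns the mean and the
    sub-volume id actually used.
    """
    gtvb = np.asarray(gtv).astype(bool)
    spacing = np.asarray(spacing_mm, dtype=float)
    gtv_c = np.asarray(ndimage.center_of_mass(gtvb)) * spacing
    ids = [int(v) for v in np.unique(labels) if v > 0]
    dists = {
        i: float(
            np.linalg.norm(np.asarray(ndimage.center_of_mass(labels == i)) * spacing - gtv_c)
        )
        for i in ids
    }
    for i in sorted(ids, key=lambda i: (-dists[i], i)):
        try:
            return reference_mean(t2map, labels == i, gtvb, coronal_axis), i
        except ValueError:
            continue
    raise ValueError("no lung sub-volume yields a defined reference mean")


def baseline_correct(t2map: QuantitativeMap, t2_ref: float) -> QuantitativeMap:
    """Voxel-wise affine shift T2 - t2_ref; negative values are allowed."""
    if not np.isfinite(t2_ref):
        raise ValueError("t2_ref must be finite")
    return QuantitativeMap(
        values=t2map.values - t2_ref,
        spacing_mm=t2map.spacing_mm,
        valid_mask=t2map.valid_mask.copy(),
    )


def region_mean(qmap: QuantitativeMap, mask: np.ndarray) -> float:
    """Arithmetic mean of the map over ``mask`` intersected with valid voxels."""
    mask = np.asarray(mask).astype(bool)
    if mask.shape != qmap.shape:
        raise GridMismatchError("mask shape does not match map")
    eff = mask & qmap.valid_mask
    if not eff.any():
        raise ValueError("region mean undefined: mask has no valid-fit voxels")
    return float(qmap.values[eff].mean())


def extract_region_parameters(
    t2map: QuantitativeMap,
    structs: StructureSet,
    v20: np.ndarray,
    coronal_axis: int = 2,
    cc_axis: int = 1,
) -> tuple[RegionParameters, QuantitativeMap]:
    """Run the full baseline-correction chain for one patient.

    Splits the lung, selects and averages the reference sub-volume over the
    GTV-bearing coronal slices, baseline-corrects the map and extracts the
    two stratification parameters (PTV mean and (V20 ^ lung) \\ GTV mean).
    Returns the parameters and the corrected map; the sub-volume labels and
    the reference id are stored back on the structure set.
    """
    lung, gtv, ptv = structs["lung"], structs["gtv"], structs["ptv"]
    labels = split_lung_subvolumes(lung, cc_axis=cc_axis)
    t2_ref, ref_id = reference_mean_with_fallback(
        t2map, labels, gtv, structs.spacing_mm, coronal_axis
    )
    structs.lung_subvolumes = labels
    structs.reference_subvolume_id = ref_id
    corrected = baseline_correct(t2map, t2_ref)
    v20_minus_gtv = np.asarray(v20).astype(bool) & lung & ~gtv
    params = RegionParameters(
        t2_ref_ms=t2_ref,
        t2_ptv_mean_ms=region_mean(corrected, ptv),
        t2_v20_minus_gtv_mean_ms=region_mean(corrected, v20_minus_gtv),
    )
    return params, corrected
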