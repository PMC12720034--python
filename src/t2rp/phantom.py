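"""Synthetic cohort generator for the RP T2-mapping pipeline.

Builds fully co-registered digital patients with known ground truth so that
every downstream stage (T2 fitting, baseline correction, stratification,
segmentation) can be exercised and validated without clinical data.

Each phantom consists of:

* two disjoint ellipsoidal lungs scaled to the field of view, with a
  spherical gross tumor volume (GTV) inside one lung and a planning target
  volume (PTV) obtained by a physical 5 mm isotropic expansion;
* a sigmoidal dose falloff centred on the GTV that covers the PTV with the
  prescription dose, the fractionation scheme drawn from a table of typical
  hypofractionated lung schemes;
* a lung-parenchyma T2 background with smooth spatial variation and, for RP
  patients, an elevated-T2 blob seeded at the PTV boundary inside the lung
  (the "pneumonitis" region, the segmentation ground truth); non-RP patients
  instead receive a mild, on average slightly negative post-treatment T2
  change in the high-dose region, emulating fibrotic change / volume loss;
* a five-echo magnitude MR series with mono-exponential decay
  ``S = S0 * exp(-TE/T2)`` corrupted by Rician noise.

Everything is reproducible from ``PhantomConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import ndimage

from .dosimetry import expand_margin
from .types import DoseGrid, MultiEchoSeries, PatientCase, QuantitativeMap, StructureSet

__all__ = [
    "PhantomConfig",
    "ConfigError",
    "FRACTIONATION_SCHEMES",
    "generate_anatomy",
    "generate_dose",
    "generate_t2_truth",
    "simulate_multiecho",
    "generate_cohort",
    "cohort_table",
]


class ConfigError(ValueError):
    """Raised for invalid or geometrically infeasible phantom configurations."""


#: (n_fractions, dose_per_fraction_gy, patients) of the emulated cohort's
#: hypofractionated schemes; prescriptions are allocated proportionally.
FRACTIONATION_SCHEMES: tuple[tuple[int, float, int], ...] = (
    (3, 13.5, 7),
    (3, 15.0, 4),
    (5, 8.0, 1),
    (5, 10.0, 1),
    (8, 7.5, 2),
    (10, 4.0, 1),
    (10, 5.0, 8),
)


@dataclass
class PhantomConfig:
    """Configuration of the synthetic cohort.

    Defaults reflect the emulated study conditions: a 24-patient cohort with
    15 RP patients (prevalence 15/24), five echoes at TE = 18/36/61/100/131
    ms, 1.6 x 1.6 mm in-plane resolution with 8.8 mm coronal slices, and an
    RP T2 elevation sized so the RP / non-RP separation of the region
    parameters lands on the ~10 ms scale of the reference cohort.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 25)
    spacing_mm: tuple[float, float, float] = (1.6, 1.6, 8.8)
    #: axis along which coronal slices are stacked (8.8 mm spacing)
    coronal_axis: int = 2
    #: cranio-caudal axis, used for the six lung sub-volumes
    cc_axis: int = 1

    lung_t2_ms: float = 40.0
    lung_t2_sd_ms: float = 3.0
    #: SD (ms) of the per-patient large-scale linear T2 gradient across half
    #: the field of view, per axis; emulates gravitational / physiological
    #: regional T2 variation that the distant-lung baseline cannot remove
    lung_gradient_sd_ms: float = 4.0
    tumor_delta_t2_ms: float = 7.0
    rp_delta_t2_ms: float = 16.0
    #: lognormal sigma of the per-patient RP severity factor (median 1)
    rp_severity_sigma: float = 0.8
    #: mild post-treatment T2 change for non-RP patients (ms)
    nonrp_delta_mean_ms: float = -2.0
    nonrp_delta_sd_ms: float = 2.5
    #: RP blob centre offset from the GTV centroid, in units of the PTV
    #: radius (drawn uniformly; larger offsets mean less PTV overlap)
    blob_offset_range: tuple[float, float] = (0.8, 2.2)
    #: RP blob target volume range (cm^3), drawn log-uniformly
    rp_volume_range_cm3: tuple[float, float] = (40.0, 160.0)
    nonrp_volume_range_cm3: tuple[float, float] = (20.0, 80.0)

    gtv_radius_mm: float = 10.0
    margin_mm: float = 5.0

    s0: float = 100.0
    noise_sigma: float = 2.0
    te_ms: tuple[float, ...] = (18.0, 36.0, 61.0, 100.0, 131.0)

    n_patients: int = 24
    prevalence: float = 15.0 / 24.0
    #: RP patients whose CT/MRI follow-up gap exceeds four weeks
    n_long_gap_rp: int = 5
    seed: int = 0

    def validate(self) -> None:
        te = np.asarray(self.te_ms, dtype=float)
        if te.size < 2 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ConfigError("te_ms must be >= 2 strictly increasing positive values")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ConfigError("prevalence must be in [0, 1]")
        if any(s < 8 for s in self.grid_shape):
            raise ConfigError("grid_shape axes must all be >= 8")
        if any(s <= 0 for s in self.spacing_mm):
            raise ConfigError("spacing_mm must be positive")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.coronal_axis not in (0, 1, 2) or self.cc_axis not in (0, 1, 2):
            raise ConfigError("coronal_axis and cc_axis must be 0, 1 or 2")

    @property
    def fov_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * np.asarray(self.spacing_mm)

    def to_dict(self) -> dict:
        return asdict(self)


def _voxel_centers_mm(cfg: PhantomConfig):
    """Per-axis 1D physical coordinates of voxel centres (open grids)."""
    axes = [
        (np.arange(n) + 0.5) * s
        for n, s in zip(cfg.grid_shape, cfg.spacing_mm)
    ]
    return np.ix_(axes[0], axes[1], axes[2])


def _ellipsoid(cfg: PhantomConfig, center_mm, semi_axes_mm) -> np.ndarray:
    x, y, z = _voxel_centers_mm(cfg)
    cx, cy, cz = center_mm
    ax, ay, az = semi_axes_mm
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _lung_geometry(cfg: PhantomConfig):
    """Centres and semi-axes (mm) of the two lung ellipsoids."""
    fov = cfg.fov_mm
    center = fov / 2.0
    semi = np.array([0.16 * fov[0], 0.42 * fov[1], 0.38 * fov[2]])
    offset = 0.23 * fov[0]
    left = center + np.array([-offset, 0.0, 0.0])
    right = center + np.array([offset, 0.0, 0.0])
    return (left, right), semi


def generate_anatomy(cfg: PhantomConfig, rng: np.random.Generator) -> StructureSet:
    """Generate lung, GTV and PTV masks for one patient.

    The GTV sphere is placed inside one (randomly chosen) lung with a random
    cranio-caudal offset; the PTV is the GTV dilated by ``margin_mm`` in
    physical units.
    """
    cfg.validate()
    (left_c, right_c), semi = _lung_geometry(cfg)
    lung_l = _ellipsoid(cfg, left_c, semi)
    lung_r = _ellipsoid(cfg, right_c, semi)
    if not lung_l.any() or not lung_r.any() or (lung_l & lung_r).any():
        raise ConfigError("grid too small to contain two disjoint lungs")
    lung = lung_l | lung_r

    host_center = left_c if rng.random() < 0.5 else right_c
    sup = 1.0 if rng.random() < 0.6 else -1.0
    # containment: |offset|/a_cc + r/min(semi) <= 0.95 keeps the sphere inside
    max_frac = max(0.0, 0.95 - cfg.gtv_radius_mm / semi.min())
    frac = float(np.clip(0.30 + rng.normal(0.0, 0.03), 0.18, max_frac))
    gtv_center = host_center + np.array([0.0, sup * frac * semi[1], rng.normal(0.0, 2.0)])

    x, y, z = _voxel_centers_mm(cfg)
    r2 = (x - gtv_center[0]) ** 2 + (y - gtv_center[1]) ** 2 + (z - gtv_center[2]) ** 2
    gtv = r2 <= cfg.gtv_radius_mm**2
    if not gtv.any():
        raise ConfigError("grid too coarse to contain the GTV sphere")
    if not np.all(lung[gtv]):
        raise ConfigError("GTV does not fit inside the lung; enlarge the grid")

    ptv = expand_margin(gtv, cfg.margin_mm, cfg.spacing_mm)
    return StructureSet(
        masks={"lung": lung, "gtv": gtv, "ptv": ptv},
        spacing_mm=cfg.spacing_mm,
    )


def _centroid_mm(mask: np.ndarray, spacing_mm) -> np.ndarray:
    idx = np.argwhere(mask)
    return (idx.mean(axis=0) + 0.5) * np.asarray(spacing_mm)


def generate_dose(
    structs: StructureSet,
    cfg: PhantomConfig,
    scheme: tuple[int, float] | None = None,
    rng: np.random.Generator | None = None,
    falloff_width_mm: float = 6.0,
) -> DoseGrid:
    """Physical dose grid: sigmoidal falloff with distance from the GTV centre.

    The dose is maximal at the GTV centroid (1.25 x prescription, a typical
    SBRT inhomogeneity) and scaled so every PTV voxel receives at least the
    prescription dose.
    """
    gtv = structs["gtv"]
    if not gtv.any():
        raise ValueError("generate_dose requires a non-empty GTV")
    if scheme is None:
        if rng is None:
            rng = np.random.default_rng()
        weights = np.array([s[2] for s in FRACTIONATION_SCHEMES], dtype=float)
        k = int(rng.choice(len(FRACTIONATION_SCHEMES), p=weights / weights.sum()))
        scheme = FRACTIONATION_SCHEMES[k][:2]
    n_fx, d_fx = int(scheme[0]), float(scheme[1])
    rx = n_fx * d_fx
    d_max = 1.25 * rx

    centroid = _centroid_mm(gtv, structs.spacing_mm)
    x, y, z = _voxel_centers_mm(cfg)
    r = np.sqrt((x - centroid[0]) ** 2 + (y - centroid[1]) ** 2 + (z - centroid[2]) ** 2)

    ptv_r = r[structs["ptv"]].max() + 1.0  # 1 mm pad guarantees PTV coverage
    w = falloff_width_mm
    r50 = ptv_r - w * math.log(d_max / rx - 1.0)
    values = d_max / (1.0 + np.exp((r - r50) / w))
    return DoseGrid(
        values=values,
        kind="physical",
        n_fractions=n_fx,
        dose_per_fraction_gy=d_fx,
        spacing_mm=structs.spacing_mm,
    )


def _smooth_field(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean smooth random field with unit SD (spatial T2 heterogeneity)."""
    sigma_vox = np.maximum(8.0 / np.asarray(cfg.spacing_mm), 1.0)
    f = ndimage.gaussian_filter(rng.standard_normal(cfg.grid_shape), sigma=sigma_vox)
    sd = f.std()
    if sd > 0:
        f /= sd
    return f


def _seed_blob(
    structs: StructureSet,
    cfg: PhantomConfig,
    rng: np.random.Generator,
    volume_range_cm3: tuple[float, float],
) -> np.ndarray:
    """Ellipsoidal blob seeded at the PTV boundary inside the host lung."""
    lung, gtv = structs["lung"], structs["gtv"]
    spacing = np.asarray(cfg.spacing_mm)
    gtv_c = _centroid_mm(gtv, spacing)

    labels, n = ndimage.label(lung)
    gtv_idx = np.argwhere(gtv)[0]
    host_label = labels[tuple(gtv_idx)]
    host = labels == host_label
    host_c = _centroid_mm(host, spacing)
    direction = host_c - gtv_c
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 1e-9 else np.array([0.0, -1.0, 0.0])

    lo, hi = volume_range_cm3
    vol_mm3 = 1000.0 * math.exp(rng.uniform(math.log(lo), math.log(hi)))
    ratios = np.array([0.8, 1.1, 1.1])
    radius = (3.0 * vol_mm3 / (4.0 * math.pi * np.prod(ratios))) ** (1.0 / 3.0)
    semi = ratios * radius

    ptv_r = cfg.gtv_radius_mm + cfg.margin_mm
    center = gtv_c + direction * ptv_r * rng.uniform(*cfg.blob_offset_range)
    blob = _ellipsoid(cfg, center, semi) & lung
    return blob


def generate_t2_truth(
    structs: StructureSet,
    cfg: PhantomConfig,
    is_rp: bool,
    rng: np.random.Generator,
) -> tuple[QuantitativeMap, np.ndarray]:
    """Ground-truth T2 map (ms) and the RP truth mask.

    Lung voxels receive the background T2 with smooth spatial variation, the
    tumor a small positive offset.  RP patients additionally get
    ``rp_delta_t2_ms`` (scaled by a lognormal per-patient severity factor)
    inside a blob adjacent to / overlapping the PTV; non-RP patients get a
    mild N(nonrp_delta_mean, nonrp_delta_sd) change there and an empty RP
    truth mask.
    """
    lung, gtv = structs["lung"], structs["gtv"]
    if not lung.any():
        raise ValueError("generate_t2_truth requires a non-empty lung mask")

    t2 = np.full(cfg.grid_shape, cfg.lung_t2_ms, dtype=float)
    t2 += _smooth_field(cfg, rng) * cfg.lung_t2_sd_ms
    if cfg.lung_gradient_sd_ms > 0:
        # linear regional trend: +-gradient_sd ms (1 SD) across half the FOV
        fov = cfg.fov_mm
        grad = rng.normal(0.0, cfg.lung_gradient_sd_ms, size=3) / (fov / 2.0)
        x, y, z = _voxel_centers_mm(cfg)
        c = fov / 2.0
        t2 += grad[0] * (x - c[0]) + grad[1] * (y - c[1]) + grad[2] * (z - c[2])
    t2[gtv] += cfg.tumor_delta_t2_ms

    rp_truth = np.zeros(cfg.grid_shape, dtype=bool)
    if is_rp:
        blob = _seed_blob(structs, cfg, rng, cfg.rp_volume_range_cm3)
        severity = math.exp(rng.normal(0.0, cfg.rp_severity_sigma))
        t2[blob] += cfg.rp_delta_t2_ms * severity
        rp_truth = blob
    else:
        blob = _seed_blob(structs, cfg, rng, cfg.nonrp_volume_range_cm3)
        t2[blob] += rng.normal(cfg.nonrp_delta_mean_ms, cfg.nonrp_delta_sd_ms)

    np.clip(t2, 5.0, None, out=t2)
    return QuantitativeMap(t2, cfg.spacing_mm), rp_truth


def simulate_multiecho(
    t2_truth: QuantitativeMap,
    cfg: PhantomConfig,
    rng: np.random.Generator | None = None,
    s0=None,
) -> MultiEchoSeries:
    """Mono-exponential multi-echo magnitude signal with Rician noise.

    ``S(TE) = S0 * exp(-TE / T2)`` per voxel; the magnitude noise model is
    ``sqrt((S + n1)^2 + n2^2)`` with independent zero-mean Gaussians of SD
    ``noise_sigma``.  ``s0`` may be a scalar or a proton-density map (zero in
    non-body voxels, which then sit at the noise floor).
    """
    te = np.asarray(cfg.te_ms, dtype=float)
    if te.size == 0:
        raise ValueError("te_ms must be non-empty")
    t2 = t2_truth.values
    if np.any(t2 <= 0):
        raise ValueError("truth T2 map must be strictly positive")
    if s0 is None:
        s0 = cfg.s0
    s0 = np.broadcast_to(np.asarray(s0, dtype=float), t2.shape)

    signals = s0[None] * np.exp(-te[:, None, None, None] / t2[None])
    if cfg.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        n1 = rng.normal(0.0, cfg.noise_sigma, size=signals.shape)
        n2 = rng.normal(0.0, cfg.noise_sigma, size=signals.shape)
        signals = np.sqrt((signals + n1) ** 2 + n2**2)
    return MultiEchoSeries(
        signals=signals.astype(np.float32), te_ms=te, spacing_mm=cfg.spacing_mm
    )


def _allocate_schemes(n: int, rng: np.random.Generator) -> list[tuple[int, float]]:
    """Largest-remainder allocation of fractionation schemes, then shuffled."""
    weights = np.array([s[2] for s in FRACTIONATION_SCHEMES], dtype=float)
    quota = weights / weights.sum() * n
    counts = np.floor(quota).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:remainder]] += 1
    schemes: list[tuple[int, float]] = []
    for (n_fx, d_fx, _), c in zip(FRACTIONATION_SCHEMES, counts):
        schemes.extend([(n_fx, d_fx)] * int(c))
    rng.shuffle(schemes)
    return schemes


def generate_cohort(cfg: PhantomConfig) -> list[PatientCase]:
    """Generate the full synthetic cohort, reproducible from ``cfg.seed``.

    ``round(prevalence * n_patients)`` patients are RP (grade >= 1, with
    roughly the 11:4 grade-1:grade-2 split of the emulated cohort);
    ``n_long_gap_rp`` of the RP patients get a CT-MRI follow-up gap above 28
    days so the segmentation eligibility rule is exercised.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_patients + 1)
    master = np.random.default_rng(children[0])

    n = cfg.n_patients
    n_rp = int(round(cfg.prevalence * n))
    order = master.permutation(n)
    rp_flags = np.zeros(n, dtype=bool)
    rp_flags[order[:n_rp]] = True

    rp_ids = np.flatnonzero(rp_flags)
    n_grade2 = int(round(n_rp * 4.0 / 15.0))
    grade2 = set(master.choice(rp_ids, size=n_grade2, replace=False)) if n_rp else set()
    n_long = min(cfg.n_long_gap_rp, n_rp)
    long_gap = set(master.choice(rp_ids, size=n_long, replace=False)) if n_rp else set()

    schemes = _allocate_schemes(n, master)
    rt_end = date(2024, 1, 15)

    cases: list[PatientCase] = []
    for i in range(n):
        prng = np.random.default_rng(children[i + 1])
        structs = generate_anatomy(cfg, prng)
        dose = generate_dose(structs, cfg, scheme=schemes[i], rng=prng)
        truth, rp_truth = generate_t2_truth(structs, cfg, bool(rp_flags[i]), prng)
        body = structs["lung"] | structs["gtv"]
        series = simulate_multiecho(truth, cfg, prng, s0=np.where(body, cfg.s0, 0.0))
        structs.masks["rp_truth"] = rp_truth

        fupct = rt_end + timedelta(weeks=float(np.clip(prng.normal(11.0, 3.0), 5.0, 25.0)))
        if i in long_gap:
            gap = int(prng.integers(29, 62))
        else:
            gap = int(prng.integers(0, 26))
        fupmri = fupct + timedelta(days=gap if prng.random() < 0.5 else -gap)

        grade = 0
        if rp_flags[i]:
            grade = 2 if i in grade2 else 1
        cases.append(
            PatientCase(
                id=f"p{i + 1:02d}",
                series=series,
                structures=structs,
                dose=dose,
                rp_grade=grade,
                fupct_date=fupct,
                fupmri_date=fupmri,
                truth_t2=truth,
            )
        )
    return cases


def cohort_table(cases: list[PatientCase]) -> pd.DataFrame:
    """Cohort CSV table: one row per patient with outcome, dates and scheme."""
    rows = [
        {
            "id": c.id,
            "rp_grade": c.rp_grade,
            "fupct_date": c.fupct_date.isoformat(),
            "fupmri_date": c.fupmri_date.isoformat(),
            "prescription_n": c.dose.n_fractions,
            "prescription_d_gy": c.dose.dose_per_fraction_gy,
        }
        for c in cases
    ]
    return pd.DataFrame(rows)
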