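"""Synthetic cohorts, paired test arms and 3D dose/anatomy phantoms.

No public dataset of clinical liver plans exists for this method, so every
other module is exercised on synthetic data with the statistical structure
the method assumes:

* a knowledge cohort in which normal-liver, kidney and cord metrics are
  linear in RTL with additive Gaussian noise, while stomach, bowel, heart
  and esophagus metrics scatter independently of RTL;
* paired plan arms that differ by a configurable per-metric shift; and
* geometric phantoms (ellipsoidal liver, spherical GTV/PTV, cord cylinder,
  kidney ellipsoids) with a prescription dose inside the PTV and an
  exponential fall-off outside.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .dvh import DoseGrid, PlanMetrics, StructureMask
from .errors import SpecError

__all__ = [
    "LinearMetric",
    "IndependentMetric",
    "CohortSpec",
    "DEFAULT_COHORT_SPEC",
    "generate_cohort",
    "PhantomSpec",
    "generate_phantom",
    "generate_paired_metrics",
]


@dataclass(frozen=True)
class LinearMetric:
    """Metric generated as intercept + slope·rtl + Normal(0, sd), floored at 0."""

    intercept: float
    slope: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise SpecError("noise sd must be >= 0")


@dataclass(frozen=True)
class IndependentMetric:
    """RTL-independent metric: Normal(loc, sd) scatter, floored at 0."""

    loc: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise SpecError("noise sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Generating rules for a knowledge cohort.

    Defaults emulate a 50-patient knowledge database: RTL uniform on
    [0.05, 0.9] (bracketing typical liver targets), liver/kidney/cord
    metrics on the reference lines with noise, the remaining organs
    scattering around their population constants.  The noise scales are
    order-of-magnitude choices, not fitted quantities.
    """

    n: int = 50
    rtl_range: tuple[float, float] = (0.05, 0.9)
    metrics: Mapping[str, LinearMetric | IndependentMetric] = field(
        default_factory=lambda: dict(DEFAULT_METRIC_RULES)
    )

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SpecError("cohort size must be >= 1")
        lo, hi = self.rtl_range
        if not 0 < lo < hi:
            raise SpecError(f"invalid rtl range {self.rtl_range}")


#: Default generating rules; linear coefficients are the reference lines.
DEFAULT_METRIC_RULES: tuple[tuple[str, LinearMetric | IndependentMetric], ...] = (
    ("liver_gtv_v5_pct", LinearMetric(43.19, 29.49, sd=5.0)),
    ("liver_gtv_v10_pct", LinearMetric(30.62, 27.26, sd=5.0)),
    ("liver_gtv_v20_pct", LinearMetric(8.22, 38.81, sd=5.0)),
    ("liver_gtv_v30_pct", LinearMetric(3.15, 41.52, sd=5.0)),
    ("left_kidney_mean_cgy", LinearMetric(211.0, 462.0, sd=120.0)),
    ("right_kidney_mean_cgy", LinearMetric(380.0, 1465.0, sd=250.0)),
    ("spinal_cord_prv5_max_cgy", LinearMetric(1990.0, 2005.0, sd=400.0)),
    ("stomach_v20_pct", IndependentMetric(15.0, sd=8.0)),
    ("small_bowel_v15_pct", IndependentMetric(35.0, sd=10.0)),
    ("heart_mean_cgy", IndependentMetric(630.0, sd=250.0)),
    ("esophagus_max_cgy", IndependentMetric(3863.0, sd=800.0)),
)

DEFAULT_COHORT_SPEC = CohortSpec()


def noise_free(spec: CohortSpec = DEFAULT_COHORT_SPEC) -> CohortSpec:
    """Copy of a cohort spec with every noise sd set to 0."""
    return replace(
        spec,
        metrics={name: replace(rule, sd=0.0) for name, rule in spec.metrics.items()},
    )


def generate_cohort(spec: CohortSpec = DEFAULT_COHORT_SPEC, seed: int = 0) -> pd.DataFrame:
    """Synthetic knowledge-cohort table: patient_id, rtl, metric columns.

    Deterministic for a fixed (spec, seed); metric values are truncated at 0
    to stay physical.
    """
    rng = np.random.default_rng(seed)
    lo, hi = spec.rtl_range
    rtl = rng.uniform(lo, hi, size=spec.n)
    table: dict[str, object] = {
        "patient_id": [f"P{i:03d}" for i in range(spec.n)],
        "rtl": rtl,
    }
    for name, rule in spec.metrics.items():
        if isinstance(rule, LinearMetric):
            base = rule.intercept + rule.slope * rtl
        elif isinstance(rule, IndependentMetric):
            base = np.full(spec.n, rule.loc)
        else:
            raise SpecError(f"unknown metric rule type for {name!r}")
        noise = rng.normal(0.0, rule.sd, size=spec.n) if rule.sd > 0 else 0.0
        table[name] = np.maximum(base + noise, 0.0)
    return pd.DataFrame(table)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and dose model of an abdominal phantom.

    All lengths in mm on the grid axes (axis 0 = lateral, 1 = AP, 2 = SI by
    convention).  The dose is ``prescription_gy`` inside the PTV and decays
    exponentially with distance d to the PTV surface outside:
    D(d) = prescription·exp(-d / falloff_mm); ``falloff_mm=None`` means zero
    dose outside the PTV.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    liver_center_mm: tuple[float, float, float] = (32.0, 32.0, 32.0)
    liver_semiaxes_mm: tuple[float, float, float] = (28.0, 26.0, 24.0)
    ptv_center_mm: tuple[float, float, float] = (38.0, 32.0, 32.0)
    ptv_radius_mm: float = 12.0
    gtv_margin_mm: float = 5.0  # PTV = GTV + margin, so GTV radius = ptv_radius - margin
    prescription_gy: float = 50.0
    falloff_mm: float | None = 12.0
    noise_sd_gy: float = 0.0

    def __post_init__(self) -> None:
        if self.prescription_gy <= 0:
            raise SpecError("prescription must be positive")
        if self.ptv_radius_mm <= self.gtv_margin_mm:
            raise SpecError("PTV radius must exceed the GTV margin")
        if self.falloff_mm is not None and self.falloff_mm <= 0:
            raise SpecError("falloff length must be positive (or None)")
        # PTV center must sit inside the liver ellipsoid
        u = [
            (p - c) / a
            for p, c, a in zip(
                self.ptv_center_mm, self.liver_center_mm, self.liver_semiaxes_mm
            )
        ]
        if sum(x * x for x in u) >= 1.0:
            raise SpecError("PTV center lies outside the liver ellipsoid")
        # and the full PTV sphere inside the grid
        extent = [n * s for n, s in zip(self.shape, self.spacing)]
        for c, e in zip(self.ptv_center_mm, extent):
            if c - self.ptv_radius_mm < 0 or c + self.ptv_radius_mm > e:
                raise SpecError("PTV sphere extends outside the dose grid")


def _coordinate_grids(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_mask(shape, spacing, center, semiaxes) -> np.ndarray:
    xx, yy, zz = _coordinate_grids(shape, spacing)
    return (
        ((xx - center[0]) / semiaxes[0]) ** 2
        + ((yy - center[1]) / semiaxes[1]) ** 2
        + ((zz - center[2]) / semiaxes[2]) ** 2
    ) <= 1.0


def _sphere_mask(shape, spacing, center, radius) -> np.ndarray:
    return _ellipsoid_mask(shape, spacing, center, (radius, radius, radius))


def generate_phantom(
    spec: PhantomSpec = PhantomSpec(), seed: int = 0
) -> tuple[DoseGrid, dict[str, StructureMask]]:
    """Voxelized phantom: dose grid plus liver / gtv / ptv / cord / kidneys.

    Structure voxelization keeps analytic and voxel-counted volumes within a
    few percent at 1 mm spacing.  The cord is a cylinder along the SI axis
    at the posterior edge; the kidneys are two small ellipsoids below the
    liver.  Optional Gaussian dose noise (truncated at 0) is seeded.
    """
    shape, spacing = spec.shape, spec.spacing
    liver = _ellipsoid_mask(shape, spacing, spec.liver_center_mm, spec.liver_semiaxes_mm)
    ptv = _sphere_mask(shape, spacing, spec.ptv_center_mm, spec.ptv_radius_mm)
    gtv = _sphere_mask(
        shape, spacing, spec.ptv_center_mm, spec.ptv_radius_mm - spec.gtv_margin_mm
    )

    extent = [n * s for n, s in zip(shape, spacing)]
    xx, yy, zz = _coordinate_grids(shape, spacing)
    cord_center = (extent[0] * 0.5, extent[1] * 0.92, None)
    cord = ((xx - cord_center[0]) ** 2 + (yy - cord_center[1]) ** 2) <= 4.0**2
    kid_dy = extent[1] * 0.75
    left_kidney = _ellipsoid_mask(
        shape, spacing, (extent[0] * 0.22, kid_dy, extent[2] * 0.5), (7.0, 5.0, 10.0)
    )
    right_kidney = _ellipsoid_mask(
        shape, spacing, (extent[0] * 0.78, kid_dy, extent[2] * 0.5), (7.0, 5.0, 10.0)
    )

    if spec.falloff_mm is None:
        dose = np.where(ptv, spec.prescription_gy, 0.0)
    else:
        # distance (mm) from each outside voxel center to the PTV
        dist = ndimage.distance_transform_edt(~ptv, sampling=spacing)
        dose = spec.prescription_gy * np.exp(-dist / spec.falloff_mm)
    if spec.noise_sd_gy > 0:
        rng = np.random.default_rng(seed)
        dose = np.maximum(dose + rng.normal(0, spec.noise_sd_gy, size=shape), 0.0)

    structures = {
        "liver": StructureMask("liver", liver, spacing),
        "gtv": StructureMask("gtv", gtv, spacing),
        "ptv": StructureMask("ptv", ptv, spacing),
        "spinal_cord": StructureMask("spinal_cord", cord, spacing),
        "left_kidney": StructureMask("left_kidney", left_kidney, spacing),
        "right_kidney": StructureMask("right_kidney", right_kidney, spacing),
    }
    return DoseGrid(dose, spacing), structures


def generate_paired_metrics(
    n: int,
    shift_map: Mapping[str, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    metric_names: Sequence[str] | None = None,
    baseline: Mapping[str, float] | None = None,
) -> tuple[list[PlanMetrics], list[PlanMetrics]]:
    """Two paired plan arms: arm B = arm A + shift + Normal(0, noise_sd).

    Arm A scatters around per-metric baselines (defaults span typical plan
    values); ``shift_map`` adds a systematic per-metric offset to arm B, the
    construction used to verify that the paired test detects a built-in
    effect and stays null without one.
    """
    if n < 2:
        raise SpecError("need at least 2 patients for paired arms")
    rng = np.random.default_rng(seed)
    if metric_names is None:
        metric_names = list(DEFAULT_BASELINES)
    base = dict(DEFAULT_BASELINES)
    if baseline:
        base.update(baseline)
    shift_map = dict(shift_map or {})
    ids = [f"P{i:03d}" for i in range(n)]
    arm_a = [PlanMetrics(pid, {}) for pid in ids]
    arm_b = [PlanMetrics(pid, {}) for pid in ids]
    for name in metric_names:
        loc = base.get(name, 100.0)
        spread = 0.05 * abs(loc) + 1e-6
        a_vals = rng.normal(loc, spread, size=n)
        noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
        b_vals = a_vals + shift_map.get(name, 0.0) + noise
        for pm, v in zip(arm_a, a_vals):
            pm.values[name] = float(v)
        for pm, v in zip(arm_b, b_vals):
            pm.values[name] = float(v)
    return arm_a, arm_b


#: Typical per-metric plan values used as arm-A baselines.
DEFAULT_BASELINES: dict[str, float] = {
    "ptv.CI": 0.85,
    "ptv.HI": 1.08,
    "ptv.mean_cgy": 5150.0,
    "liver_gtv.mean_cgy": 1700.0,
    "liver_gtv.V15_cc": 460.0,
    "left_kidney.mean_cgy": 250.0,
    "right_kidney.mean_cgy": 770.0,
    "spinal_cord.mean_cgy": 1160.0,
    "spinal_cord.max_cgy": 2600.0,
    "stomach.mean_cgy": 680.0,
    "small_bowel.mean_cgy": 780.0,
    "heart.mean_cgy": 415.0,
    "esophagus.mean_cgy": 900.0,
}
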