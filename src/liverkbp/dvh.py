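"""Dose-volume histograms and plan-quality metrics.

The central objects are :class:`DoseGrid` (a 3D absorbed-dose field with
voxel spacing), :class:`StructureMask` (a named boolean volume on the same
grid) and :class:`CumulativeDVH` (dose vs. fraction of structure volume
receiving at least that dose).  Point metrics — Vx, Dx%, mean, max, the
conformity index CI = (V_pres∩PTV / V_PTV) · (V_pres∩PTV / V_pres) and the
homogeneity index HI = D2% / D98% — are computed from raw voxel doses, so
they carry no binning error; binned DVH curves exist for plotting, export
and cohort averaging only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CongruenceError,
    DegeneratePlanError,
    DomainError,
    EmptyStructureError,
)

__all__ = [
    "DoseGrid",
    "StructureMask",
    "CumulativeDVH",
    "PlanMetrics",
    "structure_doses",
    "compute_cumulative_dvh",
    "volume_at_dose",
    "dose_at_volume",
    "dose_statistics",
    "conformity_index",
    "homogeneity_index",
    "mean_dvh_curve",
    "compute_plan_metrics",
    "dvhs_to_csv",
    "dvhs_from_csv",
]


@dataclass(frozen=True)
class DoseGrid:
    """3D absorbed-dose distribution.

    Parameters
    ----------
    values
        3D array of dose in Gy; finite and non-negative.
    spacing
        Voxel edge lengths in mm along each axis, all positive.
    origin
        Physical position (mm) of the first voxel center.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise DomainError(f"dose grid must be 3D, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise DomainError("dose grid contains non-finite values")
        if np.any(values < 0):
            raise DomainError("dose grid contains negative dose")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise DomainError(f"spacing must be 3 positive lengths, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cc (1 cc = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class StructureMask:
    """Named binary volume congruent with a :class:`DoseGrid`."""

    name: str
    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 3:
            raise DomainError(f"structure mask must be 3D, got ndim={mask.ndim}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise DomainError(f"spacing must be 3 positive lengths, got {self.spacing}")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def volume_cc(self) -> float:
        return self.voxel_count * self.voxel_volume_cc


@dataclass(frozen=True)
class CumulativeDVH:
    """Cumulative dose-volume histogram for one structure.

    ``rel_volume[i]`` is the fraction of the structure receiving at least
    ``dose_axis[i]`` Gy; the curve starts at (0 Gy, 1) and is non-increasing,
    reaching 0 beyond the maximum structure dose.
    """

    structure: str
    dose_axis: np.ndarray
    rel_volume: np.ndarray
    total_volume_cc: float

    def __post_init__(self) -> None:
        axis = np.asarray(self.dose_axis, dtype=float)
        rel = np.asarray(self.rel_volume, dtype=float)
        if axis.ndim != 1 or rel.shape != axis.shape:
            raise DomainError("dose_axis and rel_volume must be 1D of equal length")
        if axis[0] != 0.0 or np.any(np.diff(axis) <= 0):
            raise DomainError("dose_axis must start at 0 and strictly increase")
        if np.any(np.diff(rel) > 1e-12):
            raise DomainError("rel_volume must be non-increasing")
        if np.any(rel < -1e-12) or np.any(rel > 1 + 1e-12):
            raise DomainError("rel_volume must lie in [0, 1]")
        object.__setattr__(self, "dose_axis", axis)
        object.__setattr__(self, "rel_volume", np.clip(rel, 0.0, 1.0))
        object.__setattr__(self, "total_volume_cc", float(self.total_volume_cc))

    def rel_volume_at(self, dose_gy: float) -> float:
        """Relative volume at ``dose_gy`` by linear interpolation on the curve."""
        if dose_gy < 0:
            raise DomainError("query dose must be >= 0")
        return float(np.interp(dose_gy, self.dose_axis, self.rel_volume, right=0.0))


@dataclass
class PlanMetrics:
    """Named plan-quality metrics for one patient.

    Metric names follow the ``structure.metric_unit`` convention, e.g.
    ``liver_gtv.mean_cgy``, ``ptv.CI``, ``liver_gtv.V15_cc``.
    """

    patient_id: str
    values: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def _check_congruent(dose: DoseGrid, structure: StructureMask) -> None:
    if dose.shape != structure.shape:
        raise CongruenceError(
            f"dose grid {dose.shape} and mask '{structure.name}' {structure.shape} differ"
        )


def structure_doses(dose: DoseGrid, structure: StructureMask) -> np.ndarray:
    """Voxel doses (Gy) inside a structure; raises on empty masks."""
    _check_congruent(dose, structure)
    if structure.voxel_count == 0:
        raise EmptyStructureError(f"structure '{structure.name}' is empty")
    return dose.values[structure.mask]


def compute_cumulative_dvh(
    dose: DoseGrid, structure: StructureMask, bin_width_gy: float = 0.05
) -> CumulativeDVH:
    """Cumulative DVH by exact voxel counting on a regular dose axis.

    The axis runs from 0 Gy to one bin beyond the maximum structure dose so
    the curve always closes at 0.
    """
    if bin_width_gy <= 0:
        raise DomainError("bin_width_gy must be positive")
    doses = structure_doses(dose, structure)
    d_max = float(doses.max())
    n_bins = int(np.ceil(d_max / bin_width_gy)) + 2
    axis = np.arange(n_bins) * bin_width_gy
    sorted_doses = np.sort(doses)
    # voxels with dose >= axis value == n - searchsorted(left)
    n_at_least = doses.size - np.searchsorted(sorted_doses, axis, side="left")
    return CumulativeDVH(
        structure=structure.name,
        dose_axis=axis,
        rel_volume=n_at_least / doses.size,
        total_volume_cc=structure.volume_cc,
    )


def volume_at_dose(
    source: CumulativeDVH | np.ndarray,
    dose_gy: float,
    mode: str = "relative",
    voxel_volume_cc: float | None = None,
) -> float:
    """V(dose): fraction (or cc) of a structure receiving >= ``dose_gy``.

    ``source`` may be raw voxel doses (exact counting — the default route for
    all reported metrics) or a :class:`CumulativeDVH` (interpolated on the
    curve).  Absolute mode needs ``voxel_volume_cc`` for the voxel route.
    """
    if dose_gy < 0:
        raise DomainError("query dose must be >= 0")
    if mode not in ("relative", "absolute"):
        raise DomainError(f"mode must be 'relative' or 'absolute', got {mode!r}")
    if isinstance(source, CumulativeDVH):
        frac = source.rel_volume_at(dose_gy)
        return frac if mode == "relative" else frac * source.total_volume_cc
    doses = np.asarray(source, dtype=float)
    if doses.size == 0:
        raise EmptyStructureError("no voxel doses supplied")
    frac = float(np.count_nonzero(doses >= dose_gy)) / doses.size
    if mode == "relative":
        return frac
    if voxel_volume_cc is None:
        raise DomainError("absolute mode on voxel doses requires voxel_volume_cc")
    return frac * doses.size * voxel_volume_cc


def dose_at_volume(voxel_doses: np.ndarray, volume_pct: float) -> float:
    """Dx%: minimum dose received by the hottest ``volume_pct`` of the structure.

    Linear percentile interpolation over sorted voxel doses; D100% is the
    minimum voxel dose.
    """
    doses = np.asarray(voxel_doses, dtype=float)
    if doses.size == 0:
        raise EmptyStructureError("no voxel doses supplied")
    if not 0 < volume_pct <= 100:
        raise DomainError(f"volume_pct must lie in (0, 100], got {volume_pct}")
    return float(np.percentile(doses, 100.0 - volume_pct, method="linear"))


def dose_statistics(dose: DoseGrid, structure: StructureMask) -> tuple[float, float]:
    """(mean, max) dose in Gy over the masked voxels."""
    doses = structure_doses(dose, structure)
    return float(doses.mean()), float(doses.max())


def conformity_index(
    dose: DoseGrid,
    ptv: StructureMask,
    prescription_gy: float,
    external: StructureMask | None = None,
) -> float:
    """Paddick-style conformity index of the prescription isodose to the PTV.

    CI = (V_pres∩PTV / V_PTV) · (V_pres∩PTV / V_pres), evaluated over the whole
    dose grid unless an external (body) contour restricts it.  CI is 1 only
    when the prescription isodose volume and the PTV coincide.
    """
    if prescription_gy <= 0:
        raise DomainError("prescription dose must be positive")
    _check_congruent(dose, ptv)
    if ptv.voxel_count == 0:
        raise EmptyStructureError("PTV is empty")
    isodose = dose.values >= prescription_gy
    if external is not None:
        _check_congruent(dose, external)
        isodose = isodose & external.mask
    v_pres = int(isodose.sum())
    if v_pres == 0:
        warnings.warn(
            "no voxel reaches the prescription dose; conformity index set to 0",
            stacklevel=2,
        )
        return 0.0
    v_pres_in_ptv = int((isodose & ptv.mask).sum())
    return (v_pres_in_ptv / ptv.voxel_count) * (v_pres_in_ptv / v_pres)


def homogeneity_index(ptv_voxel_doses: np.ndarray) -> float:
    """HI = D2% / D98% over the PTV; 1 means a perfectly uniform target dose."""
    d2 = dose_at_volume(ptv_voxel_doses, 2.0)
    d98 = dose_at_volume(ptv_voxel_doses, 98.0)
    if d98 <= 0:
        raise DegeneratePlanError("D98% is zero; homogeneity index undefined")
    return d2 / d98


def mean_dvh_curve(
    dvhs: Sequence[CumulativeDVH],
    dose_axis: np.ndarray | None = None,
) -> CumulativeDVH:
    """Pointwise mean of cumulative DVHs on a common dose axis.

    Each curve is resampled by linear interpolation (0 beyond its own maximum
    dose).  The default axis spans 0-55 Gy at 0.05 Gy, the full dose range of
    a ~50 Gy prescription plan.
    """
    if len(dvhs) == 0:
        raise DomainError("mean_dvh_curve requires at least one curve")
    if dose_axis is None:
        dose_axis = np.arange(0.0, 55.0 + 0.05, 0.05)
    dose_axis = np.asarray(dose_axis, dtype=float)
    stacked = np.vstack(
        [np.interp(dose_axis, d.dose_axis, d.rel_volume, right=0.0) for d in dvhs]
    )
    return CumulativeDVH(
        structure=f"mean({len(dvhs)})",
        dose_axis=dose_axis,
        rel_volume=stacked.mean(axis=0),
        total_volume_cc=float(np.mean([d.total_volume_cc for d in dvhs])),
    )


#: Table-2-shaped default metric set: target indices plus OAR dose summaries.
STANDARD_METRICS = (
    "ptv.CI",
    "ptv.HI",
    "ptv.mean_cgy",
    "liver_gtv.mean_cgy",
    "liver_gtv.V15_cc",
    "left_kidney.mean_cgy",
    "right_kidney.mean_cgy",
    "spinal_cord.mean_cgy",
    "spinal_cord.max_cgy",
    "stomach.mean_cgy",
    "small_bowel.mean_cgy",
    "heart.mean_cgy",
    "esophagus.mean_cgy",
)


def compute_plan_metrics(
    dose: DoseGrid,
    structures: Mapping[str, StructureMask],
    prescription_gy: float,
    patient_id: str = "anon",
) -> PlanMetrics:
    """Standard plan-quality panel from a dose grid and named structures.

    Requires ``ptv``; every other structure present among ``liver_gtv``,
    ``left_kidney``, ``right_kidney``, ``spinal_cord``, ``stomach``,
    ``small_bowel``, ``heart``, ``esophagus`` contributes its mean dose (cGy),
    the cord additionally its maximum and liver_gtv its V15 in cc.
    """
    if "ptv" not in structures:
        raise DomainError("structures must include 'ptv'")
    out: dict[str, float] = {}
    ptv_doses = structure_doses(dose, structures["ptv"])
    out["ptv.CI"] = conformity_index(dose, structures["ptv"], prescription_gy)
    out["ptv.HI"] = homogeneity_index(ptv_doses)
    out["ptv.mean_cgy"] = float(ptv_doses.mean()) * 100.0
    for name, struct in structures.items():
        if name == "ptv":
            continue
        mean_gy, max_gy = dose_statistics(dose, struct)
        out[f"{name}.mean_cgy"] = mean_gy * 100.0
        if name == "spinal_cord":
            out["spinal_cord.max_cgy"] = max_gy * 100.0
        if name == "liver_gtv":
            out["liver_gtv.V15_cc"] = volume_at_dose(
                structure_doses(dose, struct),
                15.0,
                mode="absolute",
                voxel_volume_cc=struct.voxel_volume_cc,
            )
    return PlanMetrics(patient_id=patient_id, values=out)


def dvhs_to_csv(dvhs: Iterable[tuple[str, CumulativeDVH]], path) -> None:
    """Write DVH curves in long format: patient_id, structure, dose_gy, rel_volume."""
    frames = [
        pd.DataFrame(
            {
                "patient_id": pid,
                "structure": d.structure,
                "dose_gy": d.dose_axis,
                "rel_volume": d.rel_volume,
            }
        )
        for pid, d in dvhs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def dvhs_from_csv(path) -> list[tuple[str, CumulativeDVH]]:
    """Read long-format DVH curves written by :func:`dvhs_to_csv`."""
    df = pd.read_csv(path)
    required = {"patient_id", "structure", "dose_gy", "rel_volume"}
    missing = required - set(df.columns)
    if missing:
        from .errors import SchemaError

        raise SchemaError(f"DVH CSV missing columns: {sorted(missing)}")
    out = []
    for (pid, name), grp in df.groupby(["patient_id", "structure"], sort=False):
        grp = grp.sort_values("dose_gy")
        out.append(
            (
                str(pid),
                CumulativeDVH(
                    structure=str(name),
                    dose_axis=grp["dose_gy"].to_numpy(),
                    rel_volume=grp["rel_volume"].to_numpy(),
                    total_volume_cc=float("nan"),
                ),
            )
        )
    return out
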