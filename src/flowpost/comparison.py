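"""Velocity-field agreement statistics between two modalities.

One field (typically a simulation result) is resampled onto the other's
grid with linear interpolation; the lumen is split into three regions along
the vessel (ascending / arch / descending by default) by two cut planes; and
per region and per velocity component the Pearson correlation (with p-value)
and the mean +/- SD of the absolute difference are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import stats
from scipy.interpolate import RegularGridInterpolator

from .io_grids.types import BinaryMask, GridGeometry, VelocityField

__all__ = [
    "REGION_NAMES",
    "COMPONENT_NAMES",
    "RegionPartition",
    "ComparisonCell",
    "ComparisonReport",
    "resample_to_grid",
    "partition_regions",
    "compare_fields",
]

REGION_NAMES = ("AAo", "Arch", "DAo")
#: velocity component order (AP, RL, SI)
COMPONENT_NAMES = ("u_AP", "v_RL", "w_SI")
EXCLUDED = 0  # label value for out-of-lumen voxels


@dataclass
class RegionPartition:
    """Per-voxel region labels: 0 = excluded, 1..3 = AAo / Arch / DAo."""

    geometry: GridGeometry
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != self.geometry.shape:
            raise ValueError("labels shape does not match geometry")
        if self.labels.min() < 0 or self.labels.max() > len(REGION_NAMES):
            raise ValueError("labels must lie in 0..3")

    def region_mask(self, region: int) -> np.ndarray:
        return self.labels == region

    def counts(self) -> dict[str, int]:
        return {name: int((self.labels == i + 1).sum())
                for i, name in enumerate(REGION_NAMES)}


@dataclass
class ComparisonCell:
    """Statistics for one (region, component) cell."""

    region: str
    component: str
    n: int
    r: float  # Pearson correlation; NaN when undefined
    p_value: float
    mean_abs_error: float  # m/s
    sd_abs_error: float  # m/s


@dataclass
class ComparisonReport:
    cells: list[ComparisonCell] = dc_field(default_factory=list)

    def cell(self, region: str, component: str) -> ComparisonCell:
        for c in self.cells:
            if c.region == region and c.component == component:
                return c
        raise KeyError((region, component))

    def to_records(self) -> list[dict]:
        return [
            {
                "region": c.region,
                "component": c.component,
                "n": c.n,
                "pearson_r": c.r,
                "p_value": c.p_value,
                "mean_abs_error_m_per_s": c.mean_abs_error,
                "sd_abs_error_m_per_s": c.sd_abs_error,
            }
            for c in self.cells
        ]

    def to_dict(self) -> dict:
        out: dict = {"units": {"error": "m/s"}, "regions": {}}
        for c in self.cells:
            region = out["regions"].setdefault(c.region, {})
            region[c.component] = {
                "n": c.n,
                "pearson_r": None if math.isnan(c.r) else c.r,
                "p_value": None if math.isnan(c.p_value) else c.p_value,
                "mean_abs_error_m_per_s": c.mean_abs_error,
                "sd_abs_error_m_per_s": c.sd_abs_error,
            }
        return out


def resample_to_grid(source: VelocityField, target: GridGeometry,
                     target_mask: BinaryMask, frame: int = 0) -> VelocityField:
    """Linearly interpolate ``source`` onto the target grid.

    Masked target voxels outside the source support are marked missing (and
    stored as zero); unmasked voxels are missing by definition.  Raises if no
    masked voxel is covered at all.
    """
    if target_mask.geometry.shape != target.shape:
        raise ValueError("target mask and target geometry do not match")
    axes = [source.geometry.axis_coords(a) for a in range(3)]
    interp = RegularGridInterpolator(axes, source.frame(frame), method="linear",
                                     bounds_error=False, fill_value=np.nan)
    centers = target.voxel_centers()
    sampled = interp(centers.reshape(-1, 3)).reshape(*target.shape, 3)
    covered = np.all(np.isfinite(sampled), axis=-1)
    missing = ~(target_mask.values & covered)
    if missing.all():
        raise ValueError("source field does not overlap the masked target grid")
    values = np.where(missing[..., None], 0.0, sampled)
    return VelocityField(geometry=target, values=values[None], missing=missing)


def partition_regions(mask: BinaryMask, plane1: tuple, plane2: tuple) -> RegionPartition:
    """Split the lumen into three regions by two ordered cut planes.

    Each plane is an ``(origin_mm, normal)`` pair; a voxel belongs to region
    1 (AAo) while still on the negative side of plane 1, to region 3 (DAo)
    once past plane 2, and to region 2 (Arch) in between.
    """
    o1, n1 = (np.asarray(x, dtype=float) for x in plane1)
    o2, n2 = (np.asarray(x, dtype=float) for x in plane2)
    n1 = n1 / np.linalg.norm(n1)
    n2 = n2 / np.linalg.norm(n2)
    if np.allclose(o1, o2) and (np.allclose(n1, n2) or np.allclose(n1, -n2)):
        raise ValueError("cut planes must be distinct")
    centers = mask.geometry.voxel_centers()
    s1 = (centers - o1) @ n1
    s2 = (centers - o2) @ n2
    labels = np.full(mask.geometry.shape, 2, dtype=np.int8)  # Arch
    labels[s1 < 0] = 1  # AAo
    labels[s2 >= 0] = 3  # DAo
    labels[~mask.values] = EXCLUDED
    return RegionPartition(geometry=mask.geometry, labels=labels)


def _joint_valid(a: VelocityField, b: VelocityField) -> np.ndarray:
    ok = np.ones(a.geometry.shape, dtype=bool)
    if a.missing is not None:
        ok &= ~a.missing
    if b.missing is not None:
        ok &= ~b.missing
    return ok


def compare_fields(a: VelocityField, b: VelocityField,
                   partition: RegionPartition, frame: int = 0) -> ComparisonReport:
    """Per-region, per-component Pearson r and absolute-error statistics.

    A voxel enters a cell only when it carries non-missing data in both
    fields; cells with fewer than 2 joint samples report NaN statistics
    rather than raising.
    """
    if a.geometry.shape != b.geometry.shape:
        raise ValueError("fields must share one grid")
    if partition.geometry.shape != a.geometry.shape:
        raise ValueError("partition geometry does not match fields")
    va = a.frame(frame)
    vb = b.frame(frame)
    ok = _joint_valid(a, b)
    report = ComparisonReport()
    for region_idx, region in enumerate(REGION_NAMES, start=1):
        sel = partition.region_mask(region_idx) & ok
        for comp_idx, component in enumerate(COMPONENT_NAMES):
            x = va[sel, comp_idx]
            y = vb[sel, comp_idx]
            n = int(x.size)
            if n >= 2:
                err = np.abs(x - y)
                mae = float(err.mean())
                sd = float(err.std(ddof=1))
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    r = p = float("nan")  # Pearson r undefined for constant input
                else:
                    res = stats.pearsonr(x, y)
                    r, p = float(res.statistic), float(res.pvalue)
            else:
                r = p = mae = sd = float("nan")
            report.cells.append(ComparisonCell(region=region, component=component,
                                               n=n, r=r, p_value=p,
                                               mean_abs_error=mae, sd_abs_error=sd))
    return report
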