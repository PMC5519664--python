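"""Core grid, field, mask, and mesh types.

Conventions
-----------
* Voxel indices are 0-based; the world position of voxel ``(i, j, k)`` is
  ``origin + index * spacing`` (millimetres), i.e. values live at voxel
  centers.
* Grid metadata (spacing, origin, vertex positions) is in millimetres, as is
  conventional for medical volumes; all physical computation downstream is in
  SI units (m, s, Pa, W).
* Velocity components are ordered (AP, RL, SI) internally; the mapping from
  file axes is carried by :attr:`GridGeometry.axis_labels`.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AXIS_LABELS",
    "GridGeometry",
    "VelocityField",
    "ScalarVolume",
    "SCALAR_UNITS",
    "BinaryMask",
    "TriMesh",
]

AXIS_LABELS = ("AP", "RL", "SI")

#: unit tags accepted for scalar volumes
SCALAR_UNITS = frozenset(
    {
        "a.u.",  # image magnitude
        "m/s",  # speed
        "m^2/s^2",  # turbulent kinetic energy k
        "m^2/s^3",  # dissipation rate epsilon
        "Pa*s",  # (eddy) viscosity
        "1/s",  # strain-rate magnitude
    }
)


@dataclass(frozen=True)
class GridGeometry:
    """Regular 3-D grid: shape, spacing and origin in mm, anatomical axes."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_labels: tuple[str, str, str] = AXIS_LABELS

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "axis_labels", tuple(self.axis_labels))
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths (mm), got {self.spacing}")
        if sorted(self.axis_labels) != sorted(AXIS_LABELS):
            raise ValueError(
                f"axis_labels must be a permutation of {AXIS_LABELS}, got {self.axis_labels}"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_m3(self) -> float:
        return self.voxel_volume_mm3 * 1e-9

    @property
    def spacing_m(self) -> tuple[float, float, float]:
        return tuple(s * 1e-3 for s in self.spacing)

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def voxel_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of world positions in mm."""
        axes = [self.axis_coords(a) for a in range(3)]
        grids = np.meshgrid(*axes, indexing="ij")
        return np.stack(grids, axis=-1)

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices for world points (mm)."""
        points_mm = np.asarray(points_mm, dtype=float)
        return (points_mm - np.asarray(self.origin)) / np.asarray(self.spacing)

    def contains_index(self, idx: Sequence[int]) -> bool:
        return all(0 <= int(i) < n for i, n in zip(idx, self.shape))


def _check_geometry_match(a: GridGeometry, b: GridGeometry) -> None:
    if a.shape != b.shape or not np.allclose(a.spacing, b.spacing) or not np.allclose(
        a.origin, b.origin
    ):
        raise ValueError("grid geometries do not match")


@dataclass
class VelocityField:
    """Time-resolved 3-component velocity on a regular grid.

    ``values`` has shape ``(n_frames, nx, ny, nz, 3)`` in m/s.  ``missing``
    (optional, same spatial shape without the component axis) marks voxels
    with no valid data, e.g. resampling targets outside the source support;
    values at missing voxels are stored as 0.
    """

    geometry: GridGeometry
    values: np.ndarray
    frames: np.ndarray = dc_field(default_factory=lambda: np.zeros(1))
    venc: Optional[float] = None
    missing: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 4:  # single frame supplied without time axis
            self.values = self.values[None]
        self.frames = np.atleast_1d(np.asarray(self.frames, dtype=float))
        expected = (len(self.frames), *self.geometry.shape, 3)
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match frames+geometry {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("velocity values must be finite")
        if self.venc is not None and np.abs(self.values).max(initial=0.0) > self.venc + 1e-12:
            raise ValueError("velocity component exceeds declared venc")
        if self.missing is not None:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.geometry.shape:
                raise ValueError("missing mask shape does not match geometry")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame(self, index: int) -> np.ndarray:
        """(nx, ny, nz, 3) velocity values of one time frame, m/s."""
        if not -self.n_frames <= index < self.n_frames:
            raise IndexError(f"frame index {index} out of range [0, {self.n_frames})")
        return self.values[index]


@dataclass
class ScalarVolume:
    """Per-voxel scalar with an explicit unit tag."""

    geometry: GridGeometry
    values: np.ndarray
    unit: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match geometry {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scalar values must be finite")
        if self.unit not in SCALAR_UNITS:
            raise ValueError(f"unknown unit tag {self.unit!r}; expected one of {sorted(SCALAR_UNITS)}")


@dataclass
class BinaryMask:
    """Per-voxel boolean lumen / domain mask."""

    geometry: GridGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"mask shape {self.values.shape} does not match geometry {self.geometry.shape}"
            )

    @property
    def count(self) -> int:
        return int(self.values.sum())

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.geometry, self.values.copy())


def _face_geometry(vertices: np.ndarray, faces: np.ndarray):
    tri = vertices[faces]  # (m, 3, 3)
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        normals = cross / (2.0 * areas)[:, None]
    return normals, areas


@dataclass
class TriMesh:
    """Triangle surface mesh; vertices in world mm, outward face normals.

    Face normals and areas are derived from the vertex winding at
    construction; callers are responsible for supplying outward-wound faces
    (``segmentation.extract_surface`` does).
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if len(self.faces) == 0 or len(self.vertices) == 0:
            raise ValueError("mesh must have at least one face and one vertex")
        if self.faces.max() >= len(self.vertices) or self.faces.min() < 0:
            raise ValueError("face index out of range")
        normals, areas = _face_geometry(self.vertices, self.faces)
        if np.any(areas <= 0):
            raise ValueError("mesh contains degenerate (zero-area) faces")
        self.face_normals = normals
        self.face_areas = areas

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def face_centers(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    @property
    def total_area(self) -> float:
        """Total surface area, mm^2."""
        return float(self.face_areas.sum())

    def signed_volume(self) -> float:
        """Enclosed volume (mm^3); positive when faces are wound outward."""
        tri = self.vertices[self.faces]
        return float(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0)

    def edge_face_counts(self) -> dict[tuple[int, int], int]:
        """Number of faces incident on each undirected edge."""
        edges = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        edges = np.sort(edges, axis=1)
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        return {tuple(e): int(c) for e, c in zip(uniq, counts)}

    def is_watertight(self) -> bool:
        edges = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        edges = np.sort(edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))
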