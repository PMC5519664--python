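"""Wall shear stress, viscous energy loss, and flow-rate computation.

Physics conventions (all SI internally):

* WSS per surface face: the wall velocity is zero, the velocity is sampled a
  half voxel inside the lumen along the inward normal, projected tangentially
  to the face, and divided by the sampling depth — a one-sided finite
  difference of the wall velocity gradient:
  ``tau = mu * v_tangential / depth`` (Pa).
* Energy loss over a masked volume:
  ``EL = sum (mu + mu_t) * sum_ij 0.5*(du_i/dx_j + du_j/dx_i)^2 * dV`` (W),
  with the eddy viscosity ``mu_t`` supplied by the chosen closure:
  0 (laminar), ``(Cs*Delta)^2 * sqrt(2 S_ij S_ij)`` (Smagorinsky LES), or
  ``Cmu * rho * k^2 / eps`` (RNG k-eps, from externally supplied k and eps).
* The boundary layer is the outermost voxel shell of the mask (>= 1 false
  6-neighbor); EL is reported split into boundary-layer and core parts.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional, Union

import numpy as np
from scipy.interpolate import CubicSpline, RegularGridInterpolator

from .io_grids.types import (
    BinaryMask,
    GridGeometry,
    ScalarVolume,
    TriMesh,
    VelocityField,
)
from .segmentation import _boundary_voxels

__all__ = [
    "FluidProperties",
    "ClosureModel",
    "WallShearField",
    "StrainRateVolume",
    "EnergyLossResult",
    "sample_inner_velocity",
    "compute_wss",
    "strain_rate",
    "eddy_viscosity_rng",
    "eddy_viscosity_les",
    "boundary_layer_mask",
    "compute_el",
    "flow_rate",
    "interpolate_waveform",
]

EPSILON_FLOOR = 1e-12  # m^2/s^3; below this the RNG eddy viscosity is zeroed


@dataclass(frozen=True)
class FluidProperties:
    """Blood constants: dynamic viscosity (Pa*s) and density (kg/m^3)."""

    mu: float = 0.004
    rho: float = 1060.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.rho <= 0:
            raise ValueError("mu and rho must be positive")


CLOSURE_KINDS = ("laminar", "les_smagorinsky", "rng_k_epsilon")


@dataclass(frozen=True)
class ClosureModel:
    """Eddy-viscosity closure selection and constants.

    ``delta`` is the local grid size for the LES closure, in metres; when
    None it defaults to the cube root of the voxel volume of the grid the
    closure is evaluated on.
    """

    kind: str = "laminar"
    c_mu: float = 0.0845
    c_s: float = 0.1
    delta: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in CLOSURE_KINDS:
            raise ValueError(f"closure kind must be one of {CLOSURE_KINDS}, got {self.kind!r}")
        if self.c_mu <= 0 or self.c_s <= 0:
            raise ValueError("closure constants must be positive")
        if self.delta is not None and self.delta <= 0:
            raise ValueError("delta must be positive (metres)")

    def grid_delta(self, geometry: GridGeometry) -> float:
        if self.delta is not None:
            return self.delta
        return float(np.cbrt(geometry.voxel_volume_m3))


@dataclass
class WallShearField:
    """Per-face wall shear vectors (Pa) on a surface mesh.

    Faces whose inner sample point left the grid carry NaN (missing marker).
    """

    mesh: TriMesh
    vectors: np.ndarray
    magnitude: np.ndarray = dc_field(init=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != (self.mesh.n_faces, 3):
            raise ValueError("wss vectors must be (n_faces, 3)")
        self.magnitude = np.linalg.norm(self.vectors, axis=1)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.magnitude)

    def area_averaged_magnitude(self) -> float:
        """Area-weighted mean |WSS| over valid faces, Pa."""
        w = self.mesh.face_areas[self.valid]
        return float(np.sum(self.magnitude[self.valid] * w) / np.sum(w))

    def to_dict(self) -> dict:
        return {
            "units": {"wss": "Pa"},
            "n_faces": int(self.mesh.n_faces),
            "n_valid": int(self.valid.sum()),
            "area_averaged_wss_pa": self.area_averaged_magnitude(),
            "max_wss_pa": float(np.nanmax(self.magnitude)),
        }

    def to_records(self) -> list[dict]:
        return [
            {
                "face": i,
                "wss_x_pa": self.vectors[i, 0],
                "wss_y_pa": self.vectors[i, 1],
                "wss_z_pa": self.vectors[i, 2],
                "wss_magnitude_pa": self.magnitude[i],
            }
            for i in range(self.mesh.n_faces)
        ]


@dataclass
class StrainRateVolume:
    """Per-voxel symmetric strain-rate tensor S_ij (1/s) and validity mask."""

    geometry: GridGeometry
    tensor: np.ndarray  # (nx, ny, nz, 3, 3)
    valid: np.ndarray  # (nx, ny, nz) bool

    def magnitude(self) -> np.ndarray:
        """sqrt(2 S_ij S_ij), 1/s; zero where invalid."""
        s2 = 2.0 * np.einsum("...ij,...ij->...", self.tensor, self.tensor)
        out = np.sqrt(np.maximum(s2, 0.0))
        out[~self.valid] = 0.0
        return out


@dataclass
class EnergyLossResult:
    """Viscous dissipation totals in W, split at the boundary-layer shell."""

    el_total: float
    el_boundary_layer: float
    el_core: float
    closure: ClosureModel
    includes_eddy_viscosity: bool
    n_voxels_boundary_layer: int
    n_voxels_core: int

    def __post_init__(self) -> None:
        parts = self.el_boundary_layer + self.el_core
        scale = max(abs(self.el_total), 1e-300)
        if abs(self.el_total - parts) > 1e-9 * scale:
            raise ValueError("EL compartments do not sum to the total")
        if min(self.el_total, self.el_boundary_layer, self.el_core) < 0:
            raise ValueError("EL must be non-negative")

    def to_dict(self) -> dict:
        return {
            "units": {"el": "W"},
            "closure": self.closure.kind,
            "includes_eddy_viscosity": self.includes_eddy_viscosity,
            "el_total_w": self.el_total,
            "el_boundary_layer_w": self.el_boundary_layer,
            "el_core_w": self.el_core,
            "n_voxels_boundary_layer": self.n_voxels_boundary_layer,
            "n_voxels_core": self.n_voxels_core,
        }

    def to_records(self) -> list[dict]:
        return [
            {"compartment": "total", "el_w": self.el_total,
             "n_voxels": self.n_voxels_boundary_layer + self.n_voxels_core},
            {"compartment": "boundary_layer", "el_w": self.el_boundary_layer,
             "n_voxels": self.n_voxels_boundary_layer},
            {"compartment": "core", "el_w": self.el_core,
             "n_voxels": self.n_voxels_core},
        ]


# ---------------------------------------------------------------------------
# Near-wall sampling and WSS
# ---------------------------------------------------------------------------

def _velocity_interpolator(field: VelocityField, frame: int) -> Callable:
    geometry = field.geometry
    axes = [geometry.axis_coords(a) for a in range(3)]
    values = field.frame(frame)
    return RegularGridInterpolator(axes, values, method="linear",
                                   bounds_error=False, fill_value=np.nan)


def sample_inner_velocity(mesh: TriMesh, field: VelocityField, frame: int = 0,
                          depth: Union[float, np.ndarray] = 5e-4) -> np.ndarray:
    """Trilinear velocity at ``face center - depth * outward normal``.

    ``depth`` is in metres (scalar or per-face).  Faces whose sample point
    falls outside the grid return NaN rows (flagged and excluded downstream).
    """
    depth = np.broadcast_to(np.asarray(depth, dtype=float), (mesh.n_faces,))
    if np.any(depth <= 0):
        raise ValueError("sampling depth must be positive")
    interp = _velocity_interpolator(field, frame)
    points_mm = mesh.face_centers - (depth[:, None] * 1e3) * mesh.face_normals
    return interp(points_mm)


def _default_depths(mesh: TriMesh, geometry: GridGeometry) -> np.ndarray:
    """Half the voxel spacing along each face's dominant normal axis, metres."""
    spacing_m = np.asarray(geometry.spacing_m)
    dominant = np.argmax(np.abs(mesh.face_normals), axis=1)
    return 0.5 * spacing_m[dominant]


def compute_wss(mesh: TriMesh, field: VelocityField, frame: int = 0,
                props: FluidProperties = FluidProperties(),
                depth: Optional[Union[float, np.ndarray]] = None) -> WallShearField:
    """Wall shear stress per face: ``mu * v_tangential / depth``.

    The wall velocity is taken as zero; ``depth`` defaults to half a voxel
    along the dominant normal axis.
    """
    if depth is None:
        depth = _default_depths(mesh, field.geometry)
    depth = np.broadcast_to(np.asarray(depth, dtype=float), (mesh.n_faces,))
    sampled = sample_inner_velocity(mesh, field, frame, depth)
    normals = mesh.face_normals
    tangential = sampled - np.einsum("ij,ij->i", sampled, normals)[:, None] * normals
    vectors = props.mu * tangential / depth[:, None]
    if not np.isfinite(vectors).any():
        raise ValueError("all faces sampled outside the velocity grid")
    return WallShearField(mesh=mesh, vectors=vectors)


# ---------------------------------------------------------------------------
# Strain rate and energy loss
# ---------------------------------------------------------------------------

def _shift(arr: np.ndarray, axis: int, step: int, fill=0):
    """Array shifted so out[i] = arr[i + step] along ``axis``; padded with fill."""
    out = np.full_like(arr, fill)
    src = [slice(None)] * arr.ndim
    dst = [slice(None)] * arr.ndim
    if step > 0:
        src[axis] = slice(step, None)
        dst[axis] = slice(None, -step)
    elif step < 0:
        src[axis] = slice(None, step)
        dst[axis] = slice(-step, None)
    else:
        return arr.copy()
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _masked_gradient(u: np.ndarray, mask: np.ndarray, axis: int,
                     h: float) -> tuple[np.ndarray, np.ndarray]:
    """d(u)/dx along ``axis`` restricted to the mask.

    Central differences where both face neighbors are in the mask; one-sided
    second-order differences where two consecutive same-side neighbors exist;
    otherwise the voxel has no valid stencil along this axis.
    Returns (gradient, has_stencil); u may carry a trailing component axis.
    """
    m = mask
    m_p1 = _shift(m, axis, 1, False)
    m_m1 = _shift(m, axis, -1, False)
    m_p2 = _shift(m, axis, 2, False)
    m_m2 = _shift(m, axis, -2, False)
    u_p1 = _shift(u, axis, 1, 0.0)
    u_m1 = _shift(u, axis, -1, 0.0)
    u_p2 = _shift(u, axis, 2, 0.0)
    u_m2 = _shift(u, axis, -2, 0.0)

    central = m & m_p1 & m_m1
    forward = m & m_p1 & m_p2 & ~central
    backward = m & m_m1 & m_m2 & ~central & ~forward
    has_stencil = central | forward | backward

    grad = np.zeros_like(u)
    if u.ndim > m.ndim:  # component axis present
        central_b, forward_b, backward_b = (x[..., None] for x in (central, forward, backward))
    else:
        central_b, forward_b, backward_b = central, forward, backward
    grad = np.where(central_b, (u_p1 - u_m1) / (2 * h), grad)
    grad = np.where(forward_b, (-3 * u + 4 * u_p1 - u_p2) / (2 * h), grad)
    grad = np.where(backward_b, (3 * u - 4 * u_m1 + u_m2) / (2 * h), grad)
    return grad, has_stencil


def strain_rate(field: VelocityField, frame: int = 0,
                mask: Optional[BinaryMask] = None) -> StrainRateVolume:
    """Symmetric strain-rate tensor S_ij = 0.5 (du_i/dx_j + du_j/dx_i), 1/s.

    Gradients are finite differences restricted to the mask; voxels lacking a
    stencil in any direction are excluded from the valid mask.
    """
    geometry = field.geometry
    if mask is None:
        mask = BinaryMask(geometry, np.ones(geometry.shape, dtype=bool))
    if mask.geometry.shape != geometry.shape:
        raise ValueError("mask and field geometries do not match")
    u = field.frame(frame)  # (nx, ny, nz, 3)
    m = mask.values
    spacing_m = geometry.spacing_m

    grad = np.zeros((*geometry.shape, 3, 3))  # grad[..., i, j] = du_i / dx_j
    valid = m.copy()
    for axis in range(3):
        g, ok = _masked_gradient(u, m, axis, spacing_m[axis])
        grad[..., :, axis] = g
        valid &= ok

    tensor = 0.5 * (grad + np.swapaxes(grad, -1, -2))
    tensor[~valid] = 0.0
    return StrainRateVolume(geometry=geometry, tensor=tensor, valid=valid)


def eddy_viscosity_rng(k: ScalarVolume, epsilon: ScalarVolume,
                       props: FluidProperties = FluidProperties(),
                       model: ClosureModel = ClosureModel(kind="rng_k_epsilon"),
                       ) -> ScalarVolume:
    """RNG k-eps eddy viscosity: mu_t = Cmu * rho * k^2 / eps, Pa*s.

    Where eps falls below a small floor the eddy viscosity is set to zero.
    """
    if k.geometry.shape != epsilon.geometry.shape:
        raise ValueError("k and epsilon geometries do not match")
    if k.unit != "m^2/s^2" or epsilon.unit != "m^2/s^3":
        raise ValueError("k must be tagged m^2/s^2 and epsilon m^2/s^3")
    if np.any(k.values < 0):
        raise ValueError("turbulent kinetic energy must be non-negative")
    safe = epsilon.values > EPSILON_FLOOR
    mu_t = np.zeros_like(k.values)
    mu_t[safe] = model.c_mu * props.rho * k.values[safe] ** 2 / epsilon.values[safe]
    return ScalarVolume(geometry=k.geometry, values=mu_t, unit="Pa*s")


def eddy_viscosity_les(strain: StrainRateVolume,
                       model: ClosureModel = ClosureModel(kind="les_smagorinsky"),
                       ) -> ScalarVolume:
    """Smagorinsky eddy viscosity: mu_t = (Cs*Delta)^2 sqrt(2 S_ij S_ij), Pa*s."""
    delta = model.grid_delta(strain.geometry)
    if delta <= 0:
        raise ValueError("delta must be positive")
    mu_t = (model.c_s * delta) ** 2 * strain.magnitude()
    return ScalarVolume(geometry=strain.geometry, values=mu_t, unit="Pa*s")


def boundary_layer_mask(mask: BinaryMask) -> BinaryMask:
    """Outermost voxel shell: mask voxels with >= 1 false 6-neighbor."""
    if not mask.values.any():
        raise ValueError("mask is empty")
    return BinaryMask(mask.geometry, _boundary_voxels(mask.values))


def compute_el(field: VelocityField, frame: int, mask: BinaryMask,
               props: FluidProperties = FluidProperties(),
               model: ClosureModel = ClosureModel(kind="laminar"),
               mu_t: Optional[ScalarVolume] = None) -> EnergyLossResult:
    """Viscous energy loss over the mask, W, split at the boundary layer.

    For the RNG closure ``mu_t`` must be supplied (evaluated from external k
    and eps fields via :func:`eddy_viscosity_rng`); the LES closure computes
    its eddy viscosity internally; the laminar closure uses mu_t = 0.
    """
    if mask.geometry.shape != field.geometry.shape:
        raise ValueError("mask and field geometries do not match")
    strain = strain_rate(field, frame, mask)
    if model.kind == "laminar":
        mu_t_values = np.zeros(field.geometry.shape)
        uses_eddy = False
    elif model.kind == "les_smagorinsky":
        mu_t_values = eddy_viscosity_les(strain, model).values
        uses_eddy = True
    else:  # rng_k_epsilon
        if mu_t is None:
            raise ValueError("RNG k-epsilon closure requires a supplied mu_t volume")
        if mu_t.geometry.shape != field.geometry.shape:
            raise ValueError("mu_t geometry does not match field")
        if mu_t.unit != "Pa*s":
            raise ValueError("mu_t must be tagged Pa*s")
        if np.any(mu_t.values < 0):
            raise ValueError("mu_t must be non-negative")
        mu_t_values = mu_t.values
        uses_eddy = True

    # sum_ij 0.5 * (du_i/dx_j + du_j/dx_i)^2 = 2 S_ij S_ij
    phi = 2.0 * np.einsum("...ij,...ij->...", strain.tensor, strain.tensor)
    density = (props.mu + mu_t_values) * phi  # W/m^3
    dv = field.geometry.voxel_volume_m3

    shell = boundary_layer_mask(mask).values
    valid = strain.valid
    el_bl = float(density[valid & shell].sum() * dv)
    el_core = float(density[valid & ~shell].sum() * dv)
    return EnergyLossResult(
        el_total=el_bl + el_core,
        el_boundary_layer=el_bl,
        el_core=el_core,
        closure=model,
        includes_eddy_viscosity=uses_eddy,
        n_voxels_boundary_layer=int((valid & shell).sum()),
        n_voxels_core=int((valid & ~shell).sum()),
    )


# ---------------------------------------------------------------------------
# Flow rate and inlet waveform
# ---------------------------------------------------------------------------

def flow_rate(field: VelocityField, frame: int, mask: BinaryMask,
              plane_origin_mm, plane_normal,
              props: FluidProperties = FluidProperties()) -> tuple[float, float]:
    """Volume flow (m^3/s) and mass flow (kg/s) through a plane cross-section.

    The plane is rasterized at the finest voxel spacing; velocity is sampled
    trilinearly and a point counts as in-lumen when the trilinearly
    interpolated mask is >= 0.5.  The sign follows the supplied normal.
    """
    if mask.geometry.shape != field.geometry.shape:
        raise ValueError("mask and field geometries do not match")
    geometry = field.geometry
    n = np.asarray(plane_normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("plane normal must be nonzero")
    n = n / norm
    # canonical orientation so the sample lattice is identical for n and -n
    sign = 1.0
    if n[np.argmax(np.abs(n))] < 0:
        n = -n
        sign = -1.0

    e = np.zeros(3)
    e[np.argmin(np.abs(n))] = 1.0
    u = np.cross(n, e)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)

    origin = np.asarray(plane_origin_mm, dtype=float)
    lo = np.asarray(geometry.origin)
    hi = lo + (np.asarray(geometry.shape) - 1) * np.asarray(geometry.spacing)
    corners = np.array([[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1])
                        for z in (lo[2], hi[2])])
    rel = corners - origin
    a_range = rel @ u
    b_range = rel @ v
    ds = float(min(geometry.spacing))  # mm
    a = np.arange(a_range.min(), a_range.max() + ds, ds)
    b = np.arange(b_range.min(), b_range.max() + ds, ds)
    aa, bb = np.meshgrid(a, b, indexing="ij")
    points = origin + aa[..., None] * u + bb[..., None] * v

    axes = [geometry.axis_coords(ax) for ax in range(3)]
    mask_interp = RegularGridInterpolator(axes, mask.values.astype(float),
                                          bounds_error=False, fill_value=0.0)
    vel_interp = RegularGridInterpolator(axes, field.frame(frame),
                                         bounds_error=False, fill_value=0.0)
    flat = points.reshape(-1, 3)
    inside = mask_interp(flat) >= 0.5
    if not inside.any():
        raise ValueError("plane does not intersect the mask")
    vel = vel_interp(flat[inside])
    da_m2 = (ds * 1e-3) ** 2
    q = sign * float(np.sum(vel @ n) * da_m2)
    return q, props.rho * q


def interpolate_waveform(times, flows) -> Callable[[float], float]:
    """Cubic-spline flow waveform through the (time, flow) samples.

    Requires >= 4 strictly increasing time samples; evaluation outside the
    sampled interval raises.
    """
    times = np.asarray(times, dtype=float)
    flows = np.asarray(flows, dtype=float)
    if times.ndim != 1 or len(times) < 4:
        raise ValueError("waveform interpolation requires at least 4 samples")
    if len(times) != len(flows):
        raise ValueError("times and flows must have equal length")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    spline = CubicSpline(times, flows)
    t0, t1 = float(times[0]), float(times[-1])

    def waveform(t):
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < t0) or np.any(t_arr > t1):
            raise ValueError(f"evaluation time outside sampled range [{t0}, {t1}]")
        out = spline(t_arr)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    return waveform
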