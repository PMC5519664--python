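"""Read/write velocity and scalar volumes: NIfTI-1, NRRD, legacy VTK.

NIfTI is handled by :mod:`nibabel`.  NRRD and legacy-VTK structured points
are handled by small in-house codecs (the full libraries are heavyweight and
only a narrow slice is needed: regular grids, float/uint8 data, explicit
spacing).  All file spacing is interpreted as millimetres and all velocity
data as m/s.

Velocity layout on disk:

* NIfTI: 4-D array ``(nx, ny, nz, 3)`` for a single frame, or 5-D
  ``(nx, ny, nz, T, 3)`` for a time series (frame times from pixdim[4]).
* NRRD:  axis 0 is the component axis, ``(3, nx, ny, nz)``, single frame.
* VTK:   ``VECTORS`` point data on ``STRUCTURED_POINTS``.
"""

from __future__ import annotations

import io
import os
from typing import Optional

import nibabel as nib
import numpy as np

from .types import BinaryMask, GridGeometry, ScalarVolume, VelocityField

__all__ = [
    "read_velocity_volume",
    "write_velocity_volume",
    "read_scalar_volume",
    "write_scalar_volume",
    "read_mask",
    "write_mask",
    "FormatError",
    "MetadataError",
]


class FormatError(ValueError):
    """File cannot be parsed in the requested/detected format."""


class MetadataError(ValueError):
    """Required grid metadata (e.g. spacing) is absent."""


_NRRD_DTYPES = {
    "float": np.float32,
    "float32": np.float32,
    "double": np.float64,
    "float64": np.float64,
    "uchar": np.uint8,
    "uint8": np.uint8,
    "unsigned char": np.uint8,
}


def _detect_format(path: str, format_hint: Optional[str]) -> str:
    if format_hint:
        return format_hint.lower()
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        return "nifti"
    if lower.endswith(".nrrd"):
        return "nrrd"
    if lower.endswith(".vtk"):
        return "vtk"
    raise FormatError(f"cannot infer volume format from {path!r}")


# ---------------------------------------------------------------------------
# NRRD (minimal: raw little-endian encoding, regular grid)
# ---------------------------------------------------------------------------

def _write_nrrd(path: str, array: np.ndarray, spacings: list[float]) -> None:
    array = np.ascontiguousarray(array)
    dtype_name = {np.dtype(np.float32): "float", np.dtype(np.float64): "double",
                  np.dtype(np.uint8): "uint8"}[array.dtype]
    header = [
        "NRRD0004",
        f"type: {dtype_name}",
        f"dimension: {array.ndim}",
        "sizes: " + " ".join(str(s) for s in array.shape),
        "spacings: " + " ".join("nan" if s is None else repr(float(s)) for s in spacings),
        "endian: little",
        "encoding: raw",
        "",
        "",
    ]
    with open(path, "wb") as fh:
        fh.write("\n".join(header).encode("ascii"))
        fh.write(array.astype(array.dtype.newbyteorder("<")).tobytes())


def _read_nrrd(path: str) -> tuple[np.ndarray, list[float]]:
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise FormatError(f"{path}: not an NRRD file")
        fields: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii").strip()
            if text.startswith("#") or ":" not in text:
                continue
            key, _, value = text.partition(":")
            fields[key.strip().lower()] = value.strip()
        blob = fh.read()
    try:
        dtype = _NRRD_DTYPES[fields["type"]]
        sizes = [int(s) for s in fields["sizes"].split()]
        encoding = fields["encoding"]
    except KeyError as exc:
        raise MetadataError(f"{path}: missing NRRD field {exc}") from exc
    if "spacings" not in fields:
        raise MetadataError(f"{path}: NRRD header has no spacings")
    spacings = [float(s) for s in fields["spacings"].split()]
    if encoding == "raw":
        array = np.frombuffer(blob, dtype=np.dtype(dtype).newbyteorder("<"))
    elif encoding in ("txt", "text", "ascii"):
        array = np.loadtxt(io.BytesIO(blob), dtype=dtype).ravel()
    else:
        raise FormatError(f"{path}: unsupported NRRD encoding {encoding!r}")
    if array.size != int(np.prod(sizes)):
        raise FormatError(f"{path}: NRRD payload size mismatch")
    return array.reshape(sizes).astype(dtype), spacings


# ---------------------------------------------------------------------------
# Legacy VTK structured points (ASCII)
# ---------------------------------------------------------------------------

def _write_vtk_structured(path: str, geometry: GridGeometry, *,
                          vectors: Optional[np.ndarray] = None,
                          scalars: Optional[np.ndarray] = None,
                          name: str = "field") -> None:
    nx, ny, nz = geometry.shape
    npoints = nx * ny * nz
    lines = [
        "# vtk DataFile Version 3.0",
        "flowpost volume (spacing in mm, velocity in m/s)",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        "SPACING {} {} {}".format(*(repr(s) for s in geometry.spacing)),
        "ORIGIN {} {} {}".format(*(repr(o) for o in geometry.origin)),
        f"POINT_DATA {npoints}",
    ]
    # VTK orders points with x fastest: transpose to (z, y, x) then ravel.
    if vectors is not None:
        lines.append(f"VECTORS {name} double")
        flat = np.transpose(vectors, (2, 1, 0, 3)).reshape(-1, 3)
        lines.extend(" ".join(repr(float(v)) for v in row) for row in flat)
    if scalars is not None:
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        flat = np.transpose(scalars, (2, 1, 0)).ravel()
        lines.extend(repr(float(v)) for v in flat)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _read_vtk_structured(path: str):
    with open(path) as fh:
        tokens = fh.read().split()
    t = [tok.upper() for tok in tokens]

    def _after(keyword: str, n: int) -> list[str]:
        idx = t.index(keyword)
        return tokens[idx + 1: idx + 1 + n]

    try:
        if "STRUCTURED_POINTS" not in t:
            raise FormatError(f"{path}: only STRUCTURED_POINTS supported")
        shape = tuple(int(v) for v in _after("DIMENSIONS", 3))
        spacing = tuple(float(v) for v in _after("SPACING", 3))
        origin = tuple(float(v) for v in _after("ORIGIN", 3))
    except (ValueError, IndexError) as exc:
        raise MetadataError(f"{path}: bad VTK structured-points header") from exc
    geometry = GridGeometry(shape=shape, spacing=spacing, origin=origin)
    npoints = int(np.prod(shape))
    vectors = scalars = None
    if "VECTORS" in t:
        idx = t.index("VECTORS") + 3  # VECTORS name dtype
        data = np.array(tokens[idx: idx + 3 * npoints], dtype=float)
        vectors = data.reshape(shape[2], shape[1], shape[0], 3).transpose(2, 1, 0, 3)
    if "SCALARS" in t:
        idx = t.index("LOOKUP_TABLE") + 2
        data = np.array(tokens[idx: idx + npoints], dtype=float)
        scalars = data.reshape(shape[2], shape[1], shape[0]).transpose(2, 1, 0)
    if vectors is None and scalars is None:
        raise FormatError(f"{path}: no point data found")
    return geometry, vectors, scalars


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_velocity_volume(path: str, format_hint: Optional[str] = None) -> VelocityField:
    """Read a 3-component velocity volume; spacing in mm, velocity in m/s."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format_hint)
    if fmt == "nifti":
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=float)
        zooms = img.header.get_zooms()
        if len(zooms) < 3 or any(z <= 0 for z in zooms[:3]):
            raise MetadataError(f"{path}: missing or invalid voxel spacing")
        spacing = tuple(float(z) for z in zooms[:3])
        if data.ndim == 4:
            if data.shape[3] != 3:
                raise FormatError(
                    f"{path}: expected 3 velocity components, found {data.shape[3]}"
                )
            values = data[None]
            frames = np.zeros(1)
        elif data.ndim == 5:
            if data.shape[4] != 3:
                raise FormatError(
                    f"{path}: expected 3 velocity components, found {data.shape[4]}"
                )
            values = np.moveaxis(data, 3, 0)
            dt = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
            frames = dt * np.arange(data.shape[3])
        else:
            raise FormatError(f"{path}: expected 4-D or 5-D velocity data, got {data.ndim}-D")
        geometry = GridGeometry(shape=values.shape[1:4], spacing=spacing)
        return VelocityField(geometry=geometry, values=values, frames=frames)
    if fmt == "nrrd":
        array, spacings = _read_nrrd(path)
        if array.ndim != 4 or array.shape[0] != 3:
            raise FormatError(f"{path}: expected (3, nx, ny, nz) NRRD velocity data")
        spacing = tuple(spacings[1:4])
        if any(not np.isfinite(s) or s <= 0 for s in spacing):
            raise MetadataError(f"{path}: missing spatial spacings")
        geometry = GridGeometry(shape=array.shape[1:], spacing=spacing)
        return VelocityField(geometry=geometry,
                             values=np.moveaxis(array, 0, -1).astype(float)[None])
    if fmt == "vtk":
        geometry, vectors, _ = _read_vtk_structured(path)
        if vectors is None:
            raise FormatError(f"{path}: VTK file carries no VECTORS point data")
        return VelocityField(geometry=geometry, values=vectors[None])
    raise FormatError(f"unsupported velocity volume format {fmt!r}")


def write_velocity_volume(field: VelocityField, path: str,
                          format_hint: Optional[str] = None) -> None:
    fmt = _detect_format(path, format_hint)
    geometry = field.geometry
    if fmt == "nifti":
        if field.n_frames == 1:
            data = field.values[0]
            zooms = (*geometry.spacing, 1.0)
        else:
            data = np.moveaxis(field.values, 0, 3)
            dt = float(field.frames[1] - field.frames[0]) if field.n_frames > 1 else 1.0
            zooms = (*geometry.spacing, dt, 1.0)
        affine = np.diag([*geometry.spacing, 1.0])
        affine[:3, 3] = geometry.origin
        img = nib.Nifti1Image(data.astype(np.float64), affine)
        img.header.set_zooms(zooms[: data.ndim])
        img.header.set_xyzt_units("mm", "sec")
        nib.save(img, path)
    elif fmt == "nrrd":
        if field.n_frames != 1:
            raise FormatError("NRRD writer supports single-frame fields only")
        array = np.moveaxis(field.values[0], -1, 0).astype(np.float64)
        _write_nrrd(path, array, [np.nan, *geometry.spacing])
    elif fmt == "vtk":
        if field.n_frames != 1:
            raise FormatError("VTK writer supports single-frame fields only")
        _write_vtk_structured(path, geometry, vectors=field.values[0], name="velocity")
    else:
        raise FormatError(f"unsupported velocity volume format {fmt!r}")


def read_scalar_volume(path: str, unit: str, format_hint: Optional[str] = None) -> ScalarVolume:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format_hint)
    if fmt == "nifti":
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 3:
            raise FormatError(f"{path}: expected 3-D scalar data, got {data.ndim}-D")
        zooms = img.header.get_zooms()[:3]
        geometry = GridGeometry(shape=data.shape, spacing=tuple(float(z) for z in zooms))
        return ScalarVolume(geometry=geometry, values=data, unit=unit)
    if fmt == "nrrd":
        array, spacings = _read_nrrd(path)
        if array.ndim != 3:
            raise FormatError(f"{path}: expected 3-D scalar NRRD data")
        geometry = GridGeometry(shape=array.shape, spacing=tuple(spacings[:3]))
        return ScalarVolume(geometry=geometry, values=array.astype(float), unit=unit)
    if fmt == "vtk":
        geometry, _, scalars = _read_vtk_structured(path)
        if scalars is None:
            raise FormatError(f"{path}: VTK file carries no SCALARS point data")
        return ScalarVolume(geometry=geometry, values=scalars, unit=unit)
    raise FormatError(f"unsupported scalar volume format {fmt!r}")


def write_scalar_volume(volume: ScalarVolume, path: str,
                        format_hint: Optional[str] = None) -> None:
    fmt = _detect_format(path, format_hint)
    geometry = volume.geometry
    if fmt == "nifti":
        affine = np.diag([*geometry.spacing, 1.0])
        affine[:3, 3] = geometry.origin
        img = nib.Nifti1Image(volume.values.astype(np.float64), affine)
        img.header.set_zooms(geometry.spacing)
        nib.save(img, path)
    elif fmt == "nrrd":
        _write_nrrd(path, volume.values.astype(np.float64), list(geometry.spacing))
    elif fmt == "vtk":
        _write_vtk_structured(path, geometry, scalars=volume.values, name="scalar")
    else:
        raise FormatError(f"unsupported scalar volume format {fmt!r}")


def read_mask(path: str, format_hint: Optional[str] = None) -> BinaryMask:
    volume = read_scalar_volume(path, unit="a.u.", format_hint=format_hint)
    return BinaryMask(geometry=volume.geometry, values=volume.values >= 0.5)


def write_mask(mask: BinaryMask, path: str, format_hint: Optional[str] = None) -> None:
    volume = ScalarVolume(geometry=mask.geometry,
                          values=mask.values.astype(float), unit="a.u.")
    write_scalar_volume(volume, path, format_hint=format_hint)
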