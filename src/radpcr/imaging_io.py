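"""Volume and lesion-mask IO with geometry metadata.

Arrays are indexed ``(slice, row, column)`` throughout the package; spacing and
origin follow the same axis order, in millimetres.  MetaImage (``.mhd`` +
``.raw``) is the reference on-disk dialect; NIfTI (``.nii``/``.nii.gz``) is
read and written through nibabel.  MetaImage headers store sizes/spacings in
``(x, y, z)`` order with x fastest in the raw payload, which maps directly onto
a C-ordered ``(z, y, x)`` numpy array, so only the metadata tuples are
reversed here, never the voxel buffer.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, GeometryMismatchError

__all__ = [
    "VolumeImage",
    "LesionMask",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "GEOMETRY_TOL_MM",
]

#: Tolerance (mm) when checking that an image and its mask share one geometry.
GEOMETRY_TOL_MM = 1e-4

_MET_TO_DTYPE = {
    "MET_CHAR": np.int8,
    "MET_UCHAR": np.uint8,
    "MET_SHORT": np.int16,
    "MET_USHORT": np.uint16,
    "MET_INT": np.int32,
    "MET_UINT": np.uint32,
    "MET_LONG": np.int64,
    "MET_ULONG": np.uint64,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_DTYPE_TO_MET = {np.dtype(v): k for k, v in _MET_TO_DTYPE.items()}


@dataclass
class VolumeImage:
    """3D intensity grid with physical geometry.

    Attributes
    ----------
    voxels : ndarray, shape (slices, rows, columns)
    spacing : tuple of 3 floats, mm per voxel along (slice, row, column)
    origin : tuple of 3 floats, physical position (mm) of voxel (0, 0, 0)
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError(
                f"volume must be 3D, got {self.voxels.ndim}D shape {self.voxels.shape}"
            )
        if min(self.voxels.shape) < 1:
            raise FormatError(f"empty volume shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise FormatError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class LesionMask:
    """Binary lesion support aligned to a :class:`VolumeImage` grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    empty: bool = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise FormatError(f"mask must be 3D, got {arr.ndim}D")
        self.voxels = (arr != 0).astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.empty = not bool(self.voxels.any())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def foreground_indices(self) -> np.ndarray:
        """(n, 3) array of (slice, row, column) foreground voxel indices."""
        return np.argwhere(self.voxels != 0)


# ---------------------------------------------------------------------------
# MetaImage dialect
# ---------------------------------------------------------------------------

def _parse_mhd_header(path: str) -> dict[str, str]:
    header: dict[str, str] = {}
    with open(path, "r", encoding="ascii", errors="replace") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}: malformed header line {line!r}")
            key, value = line.split("=", 1)
            header[key.strip()] = value.strip()
    return header


def _read_mhd(path: str) -> VolumeImage:
    header = _parse_mhd_header(path)
    for required in ("NDims", "DimSize", "ElementType", "ElementDataFile"):
        if required not in header:
            raise FormatError(f"{path}: missing required header field {required}")
    ndims = int(header["NDims"])
    if ndims != 3:
        raise FormatError(f"{path}: NDims must be 3, got {ndims}")
    dims_xyz = [int(t) for t in header["DimSize"].split()]
    if len(dims_xyz) != 3:
        raise FormatError(f"{path}: DimSize must have 3 entries, got {header['DimSize']!r}")
    met_type = header["ElementType"]
    if met_type not in _MET_TO_DTYPE:
        raise FormatError(f"{path}: unsupported ElementType {met_type}")
    dtype = np.dtype(_MET_TO_DTYPE[met_type])
    if header.get("BinaryDataByteOrderMSB", "False").lower() == "true":
        dtype = dtype.newbyteorder(">")
    if header.get("CompressedData", "False").lower() == "true":
        raise FormatError(f"{path}: compressed MetaImage payloads are not supported")

    spacing_xyz = [float(t) for t in header.get("ElementSpacing", "1 1 1").split()]
    origin_xyz = [float(t) for t in header.get("Offset", "0 0 0").split()]
    if len(spacing_xyz) != 3:
        raise FormatError(f"{path}: ElementSpacing must have 3 entries")
    if len(origin_xyz) != 3:
        raise FormatError(f"{path}: Offset must have 3 entries")

    datafile = header["ElementDataFile"]
    if datafile == "LOCAL":
        raise FormatError(f"{path}: inline (LOCAL) payloads are not supported")
    raw_path = os.path.join(os.path.dirname(os.path.abspath(path)), datafile)
    if not os.path.exists(raw_path):
        raise FileNotFoundError(f"raw payload {raw_path} referenced by {path} not found")
    count = dims_xyz[0] * dims_xyz[1] * dims_xyz[2]
    buf = np.fromfile(raw_path, dtype=dtype)
    if buf.size != count:
        raise FormatError(
            f"{raw_path}: expected {count} elements from DimSize, found {buf.size}"
        )
    # raw order: x fastest -> C-contiguous (z, y, x)
    voxels = buf.reshape(dims_xyz[2], dims_xyz[1], dims_xyz[0])
    return VolumeImage(
        voxels=voxels,
        spacing=tuple(spacing_xyz[::-1]),
        origin=tuple(origin_xyz[::-1]),
    )


def _write_mhd(volume: VolumeImage, path: str) -> None:
    arr = np.ascontiguousarray(volume.voxels)
    if arr.dtype not in _DTYPE_TO_MET:
        arr = arr.astype(np.float64)
    met_type = _DTYPE_TO_MET[arr.dtype]
    base = os.path.splitext(os.path.basename(path))[0]
    raw_name = base + ".raw"
    spacing_xyz = volume.spacing[::-1]
    origin_xyz = volume.origin[::-1]
    dims_xyz = volume.shape[::-1]
    lines = [
        "ObjectType = Image",
        "NDims = 3",
        "BinaryData = True",
        "BinaryDataByteOrderMSB = False",
        "CompressedData = False",
        "TransformMatrix = 1 0 0 0 1 0 0 0 1",
        f"Offset = {origin_xyz[0]:.10g} {origin_xyz[1]:.10g} {origin_xyz[2]:.10g}",
        "CenterOfRotation = 0 0 0",
        f"ElementSpacing = {spacing_xyz[0]:.10g} {spacing_xyz[1]:.10g} {spacing_xyz[2]:.10g}",
        f"DimSize = {dims_xyz[0]} {dims_xyz[1]} {dims_xyz[2]}",
        f"ElementType = {met_type}",
        f"ElementDataFile = {raw_name}",
    ]
    with open(path, "w", encoding="ascii") as fh:
        fh.write("\n".join(lines) + "\n")
    arr.tofile(os.path.join(os.path.dirname(os.path.abspath(path)), raw_name))


# ---------------------------------------------------------------------------
# NIfTI dialect (nibabel)
# ---------------------------------------------------------------------------

def _read_nifti(path: str) -> VolumeImage:
    import nibabel as nib

    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D NIfTI, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    # nibabel arrays are (x, y, z); reverse to (slice, row, column)
    return VolumeImage(
        voxels=np.ascontiguousarray(data.transpose(2, 1, 0)),
        spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        origin=(float(origin[2]), float(origin[1]), float(origin[0])),
    )


def _write_nifti(volume: VolumeImage, path: str) -> None:
    import nibabel as nib

    data = np.ascontiguousarray(volume.voxels.transpose(2, 1, 0))
    affine = np.diag(list(volume.spacing[::-1]) + [1.0])
    affine[:3, 3] = volume.origin[::-1]
    nib.save(nib.Nifti1Image(data, affine), path)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def _dialect(path: str) -> str:
    lower = path.lower()
    if lower.endswith(".mhd"):
        return "mhd"
    if lower.endswith(".nii") or lower.endswith(".nii.gz"):
        return "nifti"
    raise FormatError(f"unrecognized volume extension for {path}")


def read_volume(path: str) -> VolumeImage:
    """Read a 3D volume (MetaImage or NIfTI) with spacing/origin metadata."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if _dialect(path) == "mhd":
        return _read_mhd(path)
    return _read_nifti(path)


def write_volume(volume: VolumeImage, path: str) -> None:
    """Write ``volume``; format chosen by extension. Lossless for raw dtypes."""
    if _dialect(path) == "mhd":
        _write_mhd(volume, path)
    else:
        _write_nifti(volume, path)


def read_mask(path: str, reference: VolumeImage) -> LesionMask:
    """Read a binary mask and validate alignment with ``reference``.

    Any nonzero voxel is foreground.  Shape must match exactly; spacing and
    origin must agree within :data:`GEOMETRY_TOL_MM`.
    """
    raw = read_volume(path)
    if raw.shape != reference.shape:
        raise GeometryMismatchError(
            f"mask shape {raw.shape} != volume shape {reference.shape} ({path})"
        )
    for name, a, b in (
        ("spacing", raw.spacing, reference.spacing),
        ("origin", raw.origin, reference.origin),
    ):
        if max(abs(x - y) for x, y in zip(a, b)) > GEOMETRY_TOL_MM:
            raise GeometryMismatchError(
                f"mask {name} {a} differs from volume {name} {b} "
                f"beyond {GEOMETRY_TOL_MM} mm ({path})"
            )
    return LesionMask(voxels=raw.voxels, spacing=reference.spacing, origin=reference.origin)


def write_mask(mask: LesionMask, path: str) -> None:
    """Write a mask as an unsigned 8-bit volume."""
    write_volume(
        VolumeImage(mask.voxels.astype(np.uint8), mask.spacing, mask.origin), path
    )
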