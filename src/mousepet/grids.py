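"""Volume I/O, physical grid geometry and resampling.

All volumes are canonicalized on load to a fixed right-handed index order
matching the Allen Common Coordinate Framework: axis 0 points posterior (P),
axis 1 inferior (I), axis 2 right (R).  World coordinates are expressed in
millimetres in that same P/I/R frame; the world position of a voxel is the
position of its *center*, ``world = origin + index * spacing``.  Affines are
required to be axis-aligned (no shear, no oblique acquisition).
"""
from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel import orientations as nio
from scipy.ndimage import map_coordinates

from .errors import FormatError, GeometryError, ValidationError

REFERENCE_AXCODES = ("P", "I", "R")

#: rows map RAS (x,y,z) world vectors into the internal P/I/R frame.
_RAS_TO_PIR = np.array([[0.0, -1.0, 0.0],
                        [0.0, 0.0, -1.0],
                        [1.0, 0.0, 0.0]])

MODALITIES = ("CT", "MR", "PET", "annotation", "mask", "label")
#: modalities whose voxel values are categorical and must never be blended
LABEL_MODALITIES = ("annotation", "mask", "label")

#: native Allen Reference Atlas bounding box (mm), AP x DV x ML index order
ARA_NATIVE_EXTENT = (13.2, 8.0, 11.4)
#: extended working box with extra-cerebral margin (mm)
EXTENDED_EXTENT = (16.1, 9.6, 12.1)
#: atlas-space voxel sizes used throughout (mm)
ATLAS_SPACING = 0.1
WORKING_SPACING = 0.2


@dataclass(frozen=True)
class Grid:
    """Axis-aligned physical sampling grid in the P/I/R reference frame."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_codes: tuple[str, str, str] = REFERENCE_AXCODES

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValidationError(f"grid shape must be 3 positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"grid spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical extent per axis in mm (shape x spacing)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def world_points(self) -> np.ndarray:
        """(N, 3) world coordinates of every voxel center, C order."""
        axes = [self.axis_coords(i) for i in range(3)]
        g = np.meshgrid(*axes, indexing="ij")
        return np.stack([a.ravel() for a in g], axis=1)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world points (…, 3) to fractional voxel indices."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def center(self) -> np.ndarray:
        """World coordinate of the grid's geometric center."""
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) * np.asarray(self.spacing) / 2.0

    def same_geometry(self, other: "Grid", tol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing, atol=tol)
                and np.allclose(self.origin, other.origin, atol=tol))

    @classmethod
    def centered(cls, extent_mm, spacing) -> "Grid":
        """Grid covering ``extent_mm`` at ``spacing`` centred on world 0."""
        spacing3 = (spacing,) * 3 if np.isscalar(spacing) else tuple(spacing)
        shape = tuple(int(np.ceil(e / s - 1e-6)) for e, s in zip(extent_mm, spacing3))
        origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing3))
        return cls(shape=shape, spacing=spacing3, origin=origin)


@dataclass
class AnnotatedVolume:
    """A 3-D scalar grid with physical geometry and a modality tag."""

    grid: Grid
    values: np.ndarray
    modality: str = "CT"
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValidationError(
                f"array shape {self.values.shape} != grid shape {self.grid.shape}")
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if self.is_label:
            if not np.issubdtype(self.values.dtype, np.integer):
                if not np.allclose(self.values, np.round(self.values)):
                    raise ValidationError("label volumes must hold integers")
                self.values = np.round(self.values).astype(np.int32)
            if self.values.size and self.values.min() < 0:
                raise ValidationError("label volumes must be non-negative")

    @property
    def is_label(self) -> bool:
        return self.modality in LABEL_MODALITIES

    def copy_with(self, **kw) -> "AnnotatedVolume":
        kw.setdefault("grid", self.grid)
        kw.setdefault("values", self.values.copy())
        kw.setdefault("modality", self.modality)
        kw.setdefault("units", self.units)
        return AnnotatedVolume(**kw)


@dataclass(frozen=True)
class BoundingBox:
    """Physical box extent in mm with a provenance tag."""

    extent: tuple[float, float, float]
    notes: str = ""

    def contains(self, other: "BoundingBox", tol: float = 1e-9) -> bool:
        return all(a + tol >= b for a, b in zip(self.extent, other.extent))


ARA_NATIVE_BOX = BoundingBox(ARA_NATIVE_EXTENT, notes="ARA native bounding box")
EXTENDED_BOX = BoundingBox(EXTENDED_EXTENT, notes="extended working box with extra-cerebral margin")


# ---------------------------------------------------------------------------
# NIfTI I/O

def _canonicalize(data: np.ndarray, affine: np.ndarray):
    """Reorient array+affine to the P/I/R reference order; return (data, spacing, origin)."""
    ornt = nio.io_orientation(affine)
    target = nio.axcodes2ornt(REFERENCE_AXCODES)
    xform = nio.ornt_transform(ornt, target)
    data = nio.apply_orientation(data, xform)
    affine = affine @ nio.inv_ornt_aff(xform, data.shape)
    m = _RAS_TO_PIR @ affine[:3, :3]
    spacing = np.diag(m).copy()
    off = m - np.diag(spacing)
    if np.any(spacing <= 0) or np.abs(off).max() > 1e-3 * np.abs(spacing).max():
        raise GeometryError("affine is oblique/sheared beyond tolerance; "
                            "only axis-aligned volumes are supported")
    origin = _RAS_TO_PIR @ affine[:3, 3]
    return data, tuple(spacing), tuple(origin)


def _pir_affine(grid: Grid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = _RAS_TO_PIR.T @ np.diag(grid.spacing)
    aff[:3, 3] = _RAS_TO_PIR.T @ np.asarray(grid.origin)
    return aff


def _infer_modality(values: np.ndarray) -> str:
    return "annotation" if np.issubdtype(values.dtype, np.integer) else "CT"


def read_volume(path, format_hint: str | None = None,
                modality: str | None = None) -> AnnotatedVolume:
    """Read a NIfTI-1 or NRRD volume and canonicalize its orientation.

    ``modality`` overrides the inferred tag (integer arrays default to
    ``annotation``, floating point to ``CT``).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = format_hint
    if fmt is None:
        fmt = "nrrd" if path.suffix.lower() == ".nrrd" else "nifti"
    if fmt == "nrrd":
        data, spacing, origin = _read_nrrd(path)
    else:
        try:
            img = nib.load(str(path))
            affine = img.affine
            data = np.asanyarray(img.dataobj)
        except Exception as exc:  # nibabel raises various types for bad files
            raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
        data = np.squeeze(data)
        if data.ndim != 3:
            raise FormatError(f"expected a 3-D volume, got shape {data.shape}")
        data, spacing, origin = _canonicalize(data, affine)
    grid = Grid(shape=data.shape, spacing=spacing, origin=origin)
    if modality is None:
        modality = _infer_modality(data)
    return AnnotatedVolume(grid=grid, values=np.ascontiguousarray(data), modality=modality)


def write_volume(vol: AnnotatedVolume, path) -> None:
    """Write a volume as NIfTI-1 with the P/I/R geometry encoded in the affine."""
    if vol.is_label and not np.all(np.isfinite(vol.values)):
        raise ValidationError("label volume contains non-finite values")
    path = Path(path)
    values = vol.values
    if vol.is_label:
        values = values.astype(np.int32)
    else:
        values = values.astype(np.float32)
    img = nib.Nifti1Image(values, _pir_affine(vol.grid))
    img.header.set_data_dtype(values.dtype)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Minimal NRRD reader (Allen atlas distribution format)

_NRRD_DTYPES = {
    "signed char": np.int8, "int8": np.int8, "uchar": np.uint8,
    "unsigned char": np.uint8, "uint8": np.uint8,
    "short": np.int16, "int16": np.int16, "ushort": np.uint16, "uint16": np.uint16,
    "int": np.int32, "int32": np.int32, "uint": np.uint32, "uint32": np.uint32,
    "long long": np.int64, "int64": np.int64, "uint64": np.uint64,
    "float": np.float32, "double": np.float64,
}


def _read_nrrd(path: Path):
    """Read a detached-header-free NRRD file (raw or gzip encoding).

    Supports the subset used by the Allen CCF distribution: 3-D, axis-aligned
    ``space directions``.  Spacings larger than 50 are interpreted as
    micrometres and converted to mm.
    """
    raw = path.read_bytes()
    if not raw.startswith(b"NRRD"):
        raise FormatError(f"{path} is not an NRRD file")
    end = raw.find(b"\n\n")
    if end < 0:
        end = raw.find(b"\r\n\r\n")
        data_start = end + 4
    else:
        data_start = end + 2
    if end < 0:
        raise FormatError(f"{path}: missing NRRD header terminator")
    header: dict[str, str] = {}
    for line in raw[:end].decode("ascii", "replace").splitlines()[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        key, _, value = line.partition(":")
        header[key.strip().lower()] = value.lstrip("=").strip()
    try:
        sizes = tuple(int(s) for s in header["sizes"].split())
        dtype = _NRRD_DTYPES[header["type"].strip()]
        encoding = header.get("encoding", "raw").strip()
    except KeyError as exc:
        raise FormatError(f"{path}: incomplete NRRD header ({exc})") from exc
    if len(sizes) != 3:
        raise FormatError(f"{path}: only 3-D NRRD supported, sizes={sizes}")
    payload = raw[data_start:]
    if encoding in ("gzip", "gz"):
        payload = gzip.decompress(payload)
    elif encoding != "raw":
        raise FormatError(f"{path}: unsupported NRRD encoding {encoding!r}")
    endian = "<" if header.get("endian", "little").strip() == "little" else ">"
    arr = np.frombuffer(payload, dtype=np.dtype(dtype).newbyteorder(endian),
                        count=int(np.prod(sizes)))
    data = arr.reshape(sizes, order="F")
    spacing = np.ones(3)
    if "space directions" in header:
        vecs = re.findall(r"\(([^)]*)\)", header["space directions"])
        dirs = np.array([[float(x) for x in v.split(",")] for v in vecs])
        for j, col in enumerate(dirs):
            sp = np.linalg.norm(col)
            if sp == 0 or np.abs(col).max() / sp < 0.999:
                raise GeometryError(f"{path}: oblique NRRD space directions unsupported")
            spacing[j] = sp
    elif "spacings" in header:
        spacing = np.array([float(s) for s in header["spacings"].split()])
    if np.all(spacing > 50):  # Allen headers quote micrometres
        spacing = spacing / 1000.0
    origin = np.zeros(3)
    if "space origin" in header:
        vals = re.findall(r"[-+0-9.eE]+", header["space origin"])
        origin = np.array([float(v) for v in vals[:3]])
        if np.abs(origin).max() > 50:
            origin = origin / 1000.0
    data = np.ascontiguousarray(data)
    return data, tuple(spacing), tuple(origin)


# ---------------------------------------------------------------------------
# Resampling and embedding

def resample(vol: AnnotatedVolume, target: Grid,
             interpolation: str = "trilinear") -> AnnotatedVolume:
    """Resample a volume onto ``target`` in world coordinates.

    Out-of-field samples take the fill value 0.  Label-like modalities must
    use nearest-neighbour interpolation.
    """
    if interpolation not in ("nearest", "trilinear"):
        raise ValidationError(f"unknown interpolation {interpolation!r}")
    if vol.is_label and interpolation != "nearest":
        raise ValidationError(f"{vol.modality} volumes require nearest interpolation")
    if vol.grid.same_geometry(target):
        return vol.copy_with(grid=target)
    axes_idx = [(target.axis_coords(i) - vol.grid.origin[i]) / vol.grid.spacing[i]
                for i in range(3)]
    coords = np.meshgrid(*axes_idx, indexing="ij")
    order = 0 if interpolation == "nearest" else 1
    out = map_coordinates(vol.values, np.stack(coords), order=order,
                          mode="constant", cval=0.0,
                          output=vol.values.dtype if order == 0 else np.float64)
    return AnnotatedVolume(grid=target, values=out, modality=vol.modality, units=vol.units)


def sample_at_points(vol: AnnotatedVolume, points: np.ndarray,
                     interpolation: str = "trilinear") -> np.ndarray:
    """Sample a volume at arbitrary world points (N, 3); 0 outside the field."""
    if vol.is_label and interpolation != "nearest":
        raise ValidationError(f"{vol.modality} volumes require nearest interpolation")
    idx = vol.grid.world_to_index(points).T
    order = 0 if interpolation == "nearest" else 1
    return map_coordinates(vol.values, idx, order=order, mode="constant", cval=0.0,
                           output=vol.values.dtype if order == 0 else np.float64)


def embed_in_box(vol: AnnotatedVolume, box: BoundingBox,
                 spacing: float | None = None) -> AnnotatedVolume:
    """Zero-pad a volume so its grid covers ``box``, keeping it centred.

    Padding conserves voxel values exactly; the asymmetric one-voxel
    remainder goes to the high-index side.  ``spacing`` must match the
    volume's own (resample first if a different spacing is wanted).
    """
    sp = np.asarray(vol.grid.spacing)
    if spacing is not None:
        if not np.allclose(sp, spacing, rtol=1e-6):
            raise ValidationError(
                f"embed_in_box spacing {spacing} != volume spacing {tuple(sp)}; "
                "resample explicitly first")
    out_shape = tuple(int(np.ceil(e / s - 1e-6)) for e, s in zip(box.extent, sp))
    pads = []
    for n_out, n_in in zip(out_shape, vol.grid.shape):
        if n_out < n_in:
            raise ValidationError(
                f"box {box.extent} smaller than volume extent {vol.grid.extent}")
        low = (n_out - n_in) // 2
        pads.append((low, n_out - n_in - low))
    values = np.pad(vol.values, pads, mode="constant", constant_values=0)
    origin = tuple(o - p[0] * s for o, p, s in zip(vol.grid.origin, pads, sp))
    grid = Grid(shape=out_shape, spacing=tuple(sp), origin=origin)
    return AnnotatedVolume(grid=grid, values=values, modality=vol.modality, units=vol.units)


def crop_to_shape(vol: AnnotatedVolume, shape: tuple[int, int, int]) -> AnnotatedVolume:
    """Inverse of :func:`embed_in_box`: crop centred to ``shape``."""
    slices, origin = [], []
    for n_cur, n_new, o, s in zip(vol.grid.shape, shape, vol.grid.origin, vol.grid.spacing):
        if n_new > n_cur:
            raise ValidationError("crop shape larger than volume")
        low = (n_cur - n_new) // 2
        slices.append(slice(low, low + n_new))
        origin.append(o + low * s)
    grid = Grid(shape=tuple(shape), spacing=vol.grid.spacing, origin=tuple(origin))
    return AnnotatedVolume(grid=grid, values=vol.values[tuple(slices)].copy(),
                           modality=vol.modality, units=vol.units)
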