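"""Reading and writing multichannel confocal z-stacks and binary ROI masks.

Conventions used throughout the package:

* In-memory stacks are 4-D arrays indexed ``(channel, z, y, x)``; every
  reader normalizes to this order.
* Voxel indices are 0-based; the physical coordinate of a voxel center is
  ``(index + 0.5) * spacing`` so that exported centroids and distances are
  in micrometres (μm).
* Binary masks travel as single-channel 8-bit TIFF volumes, 0 outside /
  255 inside, and round-trip bit-exactly.
"""

from __future__ import annotations

import os
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import tifffile


class StackIOError(RuntimeError):
    """Raised for unreadable, malformed or metadata-less stack files."""


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel size in μm per voxel along x, y and z.

    Anisotropy is permitted and typical for confocal stacks (dz ≥ dx).
    """

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"voxel spacing {name} must be strictly positive, got {v}")

    @property
    def voxel_volume_um3(self) -> float:
        return self.dx * self.dy * self.dz

    @property
    def zyx(self) -> Tuple[float, float, float]:
        """Spacing ordered to match array axes (z, y, x)."""
        return (self.dz, self.dy, self.dx)

    @property
    def xyz(self) -> Tuple[float, float, float]:
        return (self.dx, self.dy, self.dz)


@dataclass(frozen=True)
class ChannelRoleMap:
    """Maps biological channel roles to channel indices of a stack.

    ``nuclear`` is the DNA stain (e.g. DAPI), ``somatodendritic`` the
    cytoskeletal neuron marker (e.g. MAP2), ``puncta`` the punctate
    vesicle marker (e.g. EEA1 or SORLA).
    """

    nuclear: int
    somatodendritic: int
    puncta: int

    def __post_init__(self) -> None:
        idx = (self.nuclear, self.somatodendritic, self.puncta)
        if any((not isinstance(i, (int, np.integer))) or i < 0 for i in idx):
            raise ValueError(f"channel indices must be non-negative integers, got {idx}")
        if len(set(idx)) != 3:
            raise ValueError(f"channel role indices must be distinct, got {idx}")

    def validate_for(self, n_channels: int) -> None:
        for role in ("nuclear", "somatodendritic", "puncta"):
            i = getattr(self, role)
            if i >= n_channels:
                raise ValueError(
                    f"channel role '{role}' index {i} out of range for {n_channels}-channel stack"
                )


@dataclass
class ImageStack:
    """A multichannel 3-D intensity volume with physical metadata."""

    intensities: np.ndarray  # (channel, z, y, x), non-negative, finite
    spacing: VoxelSpacing
    roles: Optional[ChannelRoleMap] = None
    case_id: str = ""
    image_id: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.intensities)
        if a.ndim != 4:
            raise ValueError(f"stack must be 4-D (channel, z, y, x), got shape {a.shape}")
        if a.shape[1] < 2:
            raise ValueError("z-stack required: at least 2 z planes")
        if not np.all(np.isfinite(a)):
            raise ValueError("stack intensities must be finite")
        if a.min() < 0:
            raise ValueError("stack intensities must be non-negative")
        if self.roles is not None:
            if a.shape[0] < 3:
                raise ValueError("role-mapped stacks need at least 3 channels")
            self.roles.validate_for(a.shape[0])
        self.intensities = a

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        """Spatial shape (z, y, x)."""
        return self.intensities.shape[1:]

    def channel(self, role: str) -> np.ndarray:
        """Return the (z, y, x) volume for a named role."""
        if self.roles is None:
            raise ValueError("stack has no channel role map")
        return self.intensities[getattr(self.roles, role)]


@dataclass(frozen=True)
class AcquisitionProfile:
    """Acquisition geometry plus the optics figure used by the sampling QC.

    ``lateral_resolution_um`` is the optics-limited size of the smallest
    resolvable object; the default 0.2 μm is a diffraction-scale figure
    for high-NA green-emission confocal imaging and only feeds the
    Nyquist check.
    """

    plane_shape: Tuple[int, int]  # (y, x) pixels
    n_z: int
    spacing: VoxelSpacing
    lateral_resolution_um: float = 0.2
    min_oversampling_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.n_z < 2:
            raise ValueError("acquisition profile needs n_z >= 2")
        if self.min_oversampling_factor < 1:
            raise ValueError("min_oversampling_factor must be >= 1")


@dataclass
class NyquistReport:
    passed: bool
    factor_x: float
    factor_y: float
    required: float
    message: str = ""


def check_nyquist(profile: AcquisitionProfile) -> NyquistReport:
    """Check the ≥2× lateral oversampling guideline for an acquisition.

    Passes iff the smallest resolvable object spans at least
    ``min_oversampling_factor`` pixels in both x and y.
    """
    res = profile.lateral_resolution_um
    if not res > 0:
        raise ValueError("lateral_resolution_um must be positive")
    fx = res / profile.spacing.dx
    fy = res / profile.spacing.dy
    req = profile.min_oversampling_factor
    ok = fx >= req and fy >= req
    msg = (
        f"lateral oversampling x={fx:.2f}×, y={fy:.2f}× "
        f"({'meets' if ok else 'below'} required {req:.2f}×)"
    )
    return NyquistReport(passed=ok, factor_x=fx, factor_y=fy, required=req, message=msg)


# ---------------------------------------------------------------------------
# TIFF / OME-TIFF reading


_OME_NS = "{http://www.openmicroscopy.org/Schemas/OME/2016-06}"


def _um(value: float, unit: Optional[str]) -> float:
    unit = (unit or "µm").strip()
    if unit in ("µm", "um", "micron", "microns", "micrometer", "micrometre"):
        return value
    if unit == "nm":
        return value * 1e-3
    if unit == "mm":
        return value * 1e3
    raise StackIOError(f"unsupported physical-size unit {unit!r}")


def _spacing_from_ome(xml: str) -> Optional[VoxelSpacing]:
    try:
        root = ET.fromstring(xml)
    except ET.ParseError:
        return None
    for pixels in root.iter(f"{_OME_NS}Pixels"):
        a = pixels.attrib
        if all(k in a for k in ("PhysicalSizeX", "PhysicalSizeY", "PhysicalSizeZ")):
            return VoxelSpacing(
                dx=_um(float(a["PhysicalSizeX"]), a.get("PhysicalSizeXUnit")),
                dy=_um(float(a["PhysicalSizeY"]), a.get("PhysicalSizeYUnit")),
                dz=_um(float(a["PhysicalSizeZ"]), a.get("PhysicalSizeZUnit")),
            )
    return None


def _normalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder a tifffile series to (C, Z, Y, X), inserting C if absent."""
    axes = axes.upper().replace("S", "C").replace("Q", "Z").replace("I", "Z")
    if sorted(set(axes)) != sorted(axes):
        raise StackIOError(f"cannot normalize duplicate axes {axes!r}")
    keep = [ax for ax in axes if ax in "CZYX"]
    # squeeze singleton axes outside CZYX (e.g. T)
    for i, ax in reversed(list(enumerate(axes))):
        if ax not in "CZYX":
            if data.shape[i] != 1:
                raise StackIOError(f"unsupported non-singleton axis {ax!r} in TIFF")
            data = np.squeeze(data, axis=i)
    axes = "".join(keep)
    if "Z" not in axes or "Y" not in axes or "X" not in axes:
        raise StackIOError(f"TIFF axes {axes!r} lack a z/y/x interpretation")
    if "C" not in axes:
        data = data[np.newaxis]
        axes = "C" + axes
    order = [axes.index(ax) for ax in "CZYX"]
    return np.transpose(data, order)


def read_stack(
    path: os.PathLike | str,
    roles: Optional[ChannelRoleMap] = None,
    spacing_override: Optional[VoxelSpacing] = None,
    case_id: str = "",
    image_id: str = "",
) -> ImageStack:
    """Read a TIFF / OME-TIFF z-stack into an :class:`ImageStack`.

    Voxel spacing is taken from OME metadata when present, otherwise from
    ``spacing_override``.  When both are present the file metadata wins
    (with a warning): embedded metadata is authoritative.
    """
    if not os.path.exists(path):
        raise StackIOError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        ome_xml = tf.ome_metadata
    if data.ndim == 2:
        raise StackIOError("z-stack required: file contains a single plane")
    data = _normalize_axes(data, axes)
    if data.shape[1] < 2:
        raise StackIOError("z-stack required: fewer than 2 z planes")

    spacing = _spacing_from_ome(ome_xml) if ome_xml else None
    if spacing is not None and spacing_override is not None:
        warnings.warn(
            "both OME metadata and spacing_override given; using file metadata",
            stacklevel=2,
        )
    if spacing is None:
        spacing = spacing_override
    if spacing is None:
        raise StackIOError(f"no voxel spacing: {path} has no OME metadata and no override given")

    return ImageStack(
        intensities=np.ascontiguousarray(data),
        spacing=spacing,
        roles=roles,
        case_id=case_id,
        image_id=image_id,
    )


def write_stack(stack: ImageStack, path: os.PathLike | str) -> None:
    """Write an :class:`ImageStack` as OME-TIFF with physical voxel sizes."""
    sp = stack.spacing
    data = stack.intensities
    if data.dtype not in (np.uint8, np.uint16, np.float32):
        data = data.astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": sp.dx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": sp.dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": sp.dz,
            "PhysicalSizeZUnit": "µm",
        },
    )


# ---------------------------------------------------------------------------
# Binary mask I/O


def write_mask(mask, path: os.PathLike | str) -> None:
    """Write a binary 3-D mask as single-channel 8-bit TIFF (0 / 255).

    ``mask`` may be a boolean ``(z, y, x)`` array or any object with a
    boolean ``voxels`` attribute (e.g. :class:`endopuncta.roi.RoiMask`).
    Round-trips bit-exactly through :func:`read_mask_array`.
    """
    voxels = getattr(mask, "voxels", mask)
    voxels = np.asarray(voxels)
    if voxels.ndim != 3:
        raise ValueError(f"mask must be 3-D (z, y, x), got shape {voxels.shape}")
    tifffile.imwrite(path, (voxels.astype(bool).astype(np.uint8) * 255))


def read_mask_array(path: os.PathLike | str) -> np.ndarray:
    """Read a mask TIFF back as a boolean (z, y, x) array."""
    if not os.path.exists(path):
        raise StackIOError(f"no such file: {path}")
    data = np.asarray(tifffile.imread(path))
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise StackIOError(f"mask file must hold a single-channel volume, got shape {data.shape}")
    return data > 0
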