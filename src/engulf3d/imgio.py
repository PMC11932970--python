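"""Multi-channel 3D stack I/O and geometric pre-processing.

Confocal z-stacks are held as ``(channel, z, y, x)`` arrays together with an
anisotropic physical voxel size in micrometres.  Two acquisition presets are
common for this assay: a 20x water objective at 0.3 x 0.3 x 0.67 um (axonal
fibre imaging) and a 63x oil objective at Nyquist sampling, 0.07 x 0.07 x
0.23 um (synaptic puncta).  Stacks are exchanged as OME-TIFF with the voxel
size carried in the ``PhysicalSize*`` pixel attributes.

Geometric pre-processing mirrors the acquisition protocol: stacks are cropped
to a fixed square field of view (default 192 um) centred on the imaged
region, and for adult tissue, where antibody penetration is limited, only the
top few micrometres below the imaging surface are analysed
(:func:`crop_top_z`).  The imaging surface is taken to be z-index 0; stacks
acquired in the opposite order can be handled with ``surface="bottom"``.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "VoxelSize",
    "ChannelStack",
    "SectionRecord",
    "MARKER_KINDS",
    "read_stack",
    "write_stack",
    "crop_xy",
    "crop_top_z",
]

#: Recognised neurite / synapse / apoptosis marker channels.
MARKER_KINDS = ("VGAT", "VGLUT2", "AFIBRE", "CASPASE3")


@dataclass(frozen=True)
class VoxelSize:
    """Physical voxel edge lengths in micrometres (x, y, z)."""

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"voxel size {name}={v!r} must be strictly positive")

    @property
    def volume_um3(self) -> float:
        return self.dx * self.dy * self.dz

    @property
    def zyx(self) -> tuple[float, float, float]:
        """Edge lengths ordered like array axes (z, y, x)."""
        return (self.dz, self.dy, self.dx)


@dataclass
class ChannelStack:
    """A multi-channel 3D image with physical voxel metadata.

    ``data`` is indexed ``(channel, z, y, x)``, 0-based, with all channels on
    the same grid.  Intensities are non-negative integers (raw photon counts)
    or floats.
    """

    data: np.ndarray
    voxel: VoxelSize
    channel_names: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 4:
            raise ValueError(
                f"stack data must be (channel, z, y, x); got ndim={self.data.ndim}"
            )
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{self.data.shape[0]} channels in data but "
                f"{len(self.channel_names)} channel names {self.channel_names!r}"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError(f"channel names not unique: {self.channel_names!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent (z, y, x) in micrometres."""
        nz, ny, nx = self.shape_zyx
        return (nz * self.voxel.dz, ny * self.voxel.dy, nx * self.voxel.dx)

    def channel(self, name: str) -> np.ndarray:
        """Return the 3D array of one channel by name."""
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names!r}"
            ) from None
        return self.data[i]


@dataclass
class SectionRecord:
    """One imaged tissue section of one animal."""

    animal_id: str
    section_index: int
    stack: "ChannelStack | str | Path | None"
    marker_kind: str = "VGAT"
    ground_truth: object | None = None  # GroundTruth for synthetic sections

    def __post_init__(self) -> None:
        if self.marker_kind not in MARKER_KINDS:
            raise ValueError(
                f"marker_kind {self.marker_kind!r} not in {MARKER_KINDS}"
            )


# ---------------------------------------------------------------------------
# OME-TIFF I/O


def _voxel_from_ome(ome_xml: str) -> VoxelSize | None:
    """Extract PhysicalSizeX/Y/Z from an OME-XML string, if all present."""
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None
    for el in root.iter():
        if el.tag.endswith("Pixels"):
            try:
                return VoxelSize(
                    dx=float(el.attrib["PhysicalSizeX"]),
                    dy=float(el.attrib["PhysicalSizeY"]),
                    dz=float(el.attrib["PhysicalSizeZ"]),
                )
            except (KeyError, ValueError):
                return None
    return None


def read_stack(
    path: str | Path,
    channel_names: Sequence[str],
    voxel: VoxelSize | None = None,
) -> ChannelStack:
    """Read a TIFF / OME-TIFF z-stack as a :class:`ChannelStack`.

    Parameters
    ----------
    path
        TIFF file whose page structure encodes (c, z) planes.
    channel_names
        Names for the channels, in file order; the count must match the file.
    voxel
        Explicit voxel size.  Overrides any OME metadata; required when the
        file carries none (there is no silent default).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        arr = series.asarray()
        axes = series.axes  # e.g. 'CZYX', 'ZCYX', 'ZYX'
        meta_voxel = _voxel_from_ome(tif.ome_metadata) if tif.ome_metadata else None

    # plain multi-page TIFFs report unknown axes: treat samples as channels
    # and anonymous page stacks as z-planes
    axes = axes.replace("S", "C")
    axes = axes.replace("Q", "Z" if "Z" not in axes else "C")
    if sorted(axes) != sorted(set(axes)) or not set(axes) <= set("CZYX"):
        raise ValueError(f"unsupported TIFF axis layout {axes!r} in {path}")
    # Insert missing axes as singletons, then order as CZYX.
    for ax in "CZYX":
        if ax not in axes:
            arr = arr[np.newaxis]
            axes = ax + axes
    arr = np.transpose(arr, [axes.index(ax) for ax in "CZYX"])

    if arr.shape[0] != len(channel_names):
        raise ValueError(
            f"{path} has {arr.shape[0]} channels but {len(channel_names)} "
            f"names were given: {tuple(channel_names)!r}"
        )
    vox = voxel if voxel is not None else meta_voxel
    if vox is None:
        raise ValueError(
            f"{path} carries no voxel-size metadata and no explicit VoxelSize "
            "was supplied; refusing to guess"
        )
    return ChannelStack(
        data=arr, voxel=vox, channel_names=tuple(channel_names), provenance=str(path)
    )


def write_stack(stack: ChannelStack, path: str | Path) -> Path:
    """Write a :class:`ChannelStack` as OME-TIFF with voxel metadata.

    Round-trips bit-exactly through :func:`read_stack` for integer data and
    within float round-off for float data.
    """
    path = Path(path)
    data = stack.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": stack.voxel.dx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.voxel.dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.voxel.dz,
            "PhysicalSizeZUnit": "µm",
        },
    )
    return path


# ---------------------------------------------------------------------------
# Geometric pre-processing


def crop_xy(
    stack: ChannelStack,
    target_um: float,
    offset: tuple[int, int] | None = None,
) -> ChannelStack:
    """Crop the xy field of view to a ``target_um`` x ``target_um`` window.

    The crop spans ``floor(target_um / dx)`` x ``floor(target_um / dy)``
    pixels and is centred unless ``offset=(y0, x0)`` (top-left corner, voxel
    units) pins a specific placement.  All channels are cropped identically;
    voxel size and channel order are unchanged.
    """
    if target_um <= 0:
        raise ValueError("target_um must be positive")
    nz, ny, nx = stack.shape_zyx
    wx = int(math.floor(target_um / stack.voxel.dx))
    wy = int(math.floor(target_um / stack.voxel.dy))
    ez, ey, ex = stack.extent_um()
    if target_um > ex + 1e-9 or target_um > ey + 1e-9:
        raise ValueError(
            f"crop target {target_um} um exceeds stack extent "
            f"({ey:.2f} x {ex:.2f} um)"
        )
    if offset is None:
        y0 = (ny - wy) // 2
        x0 = (nx - wx) // 2
    else:
        y0, x0 = offset
    if y0 < 0 or x0 < 0 or y0 + wy > ny or x0 + wx > nx:
        raise ValueError(f"crop window [{y0}:{y0+wy}, {x0}:{x0+wx}] outside stack")
    return ChannelStack(
        data=stack.data[:, :, y0 : y0 + wy, x0 : x0 + wx],
        voxel=stack.voxel,
        channel_names=stack.channel_names,
        provenance=stack.provenance,
    )


def crop_top_z(
    stack: ChannelStack, depth_um: float, surface: str = "top"
) -> ChannelStack:
    """Keep only the ``depth_um`` of tissue nearest the imaging surface.

    The imaging surface is z-index 0 by convention (``surface="bottom"``
    handles stacks recorded the other way up).  ``ceil(depth_um / dz)``
    slices are kept, inclusive of a partial final slice.
    """
    if depth_um <= 0:
        raise ValueError("depth_um must be positive")
    nz = stack.shape_zyx[0]
    n = int(math.ceil(depth_um / stack.voxel.dz))
    if depth_um > nz * stack.voxel.dz + 1e-9:
        raise ValueError(
            f"depth {depth_um} um exceeds stack z extent "
            f"({nz * stack.voxel.dz:.2f} um)"
        )
    n = min(n, nz)
    if surface == "top":
        data = stack.data[:, :n]
    elif surface == "bottom":
        data = stack.data[:, nz - n :]
    else:
        raise ValueError(f"surface must be 'top' or 'bottom', got {surface!r}")
    return ChannelStack(
        data=data,
        voxel=stack.voxel,
        channel_names=stack.channel_names,
        provenance=stack.provenance,
    )
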