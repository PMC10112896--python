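"""Core image containers and TIFF I/O.

Conventions used throughout the package:

* arrays are ordered ``(z, y, x)``;
* ``x`` is the mediolateral axis (midline at ``midline_x`` micrometres),
  ``y`` is anterior-posterior, ``z`` is the optical axis;
* voxel centres sit at physical coordinate ``index * voxel_dim`` so voxel
  ``(k, j, i)`` is at ``(i*dx, j*dy, k*dz)`` micrometres in ``(x, y, z)``
  order;
* indices are 0-based and regions of interest are half-open intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import ConfigurationError, ShapeMismatchError

__all__ = ["VoxelGrid", "BinaryMask", "MultiChannelStack", "write_stack", "read_stack"]


def _check_voxel_dims(voxel_dims) -> tuple[float, float, float]:
    dims = tuple(float(d) for d in voxel_dims)
    if len(dims) != 3 or any(d <= 0 for d in dims):
        raise ConfigurationError(f"voxel_dims must be three positive numbers, got {voxel_dims!r}")
    return dims


@dataclass
class VoxelGrid:
    """One channel of a 3D stack with anisotropic voxel dimensions in µm."""

    data: np.ndarray
    voxel_dims: tuple[float, float, float]  # (dz, dy, dx) µm
    channel_role: str = "unknown"
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or 0 in self.data.shape:
            raise ConfigurationError(f"data must be a nonempty 3D array, got shape {self.data.shape}")
        if np.any(self.data < 0):
            raise ConfigurationError("data must be non-negative intensities")
        self.voxel_dims = _check_voxel_dims(self.voxel_dims)
        if self.bit_depth not in (8, 16):
            raise ConfigurationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical µm coordinates of voxel centres along a (z=0, y=1, x=2) axis."""
        return np.arange(self.data.shape[axis]) * self.voxel_dims[axis]

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        return VoxelGrid(data, self.voxel_dims, self.channel_role, self.bit_depth)


@dataclass
class BinaryMask:
    """3D boolean mask sharing the geometry of the grid it was derived from."""

    data: np.ndarray
    voxel_dims: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3 or 0 in self.data.shape:
            raise ConfigurationError(f"mask data must be a nonempty 3D array, got shape {self.data.shape}")
        self.voxel_dims = _check_voxel_dims(self.voxel_dims)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def check_matches(self, grid: VoxelGrid) -> None:
        if self.data.shape != grid.data.shape:
            raise ShapeMismatchError(
                f"mask shape {self.data.shape} does not match grid shape {grid.data.shape}"
            )


@dataclass
class MultiChannelStack:
    """A set of co-registered channels keyed by role name."""

    channels: dict[str, VoxelGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {g.data.shape for g in self.channels.values()}
        dims = {g.voxel_dims for g in self.channels.values()}
        if len(shapes) > 1 or len(dims) > 1:
            raise ShapeMismatchError("all channels must share shape and voxel_dims")

    def __getitem__(self, role: str) -> VoxelGrid:
        if role not in self.channels:
            raise KeyError(f"channel role {role!r} not present; have {sorted(self.channels)}")
        return self.channels[role]

    def __contains__(self, role: str) -> bool:
        return role in self.channels

    @property
    def roles(self) -> list[str]:
        return list(self.channels)

    @property
    def voxel_dims(self) -> tuple[float, float, float]:
        return next(iter(self.channels.values())).voxel_dims

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).data.shape


def write_stack(path, stack: MultiChannelStack) -> None:
    """Write an ImageJ-compatible multi-channel TIFF (axes ZCYX, float32).

    Voxel sizes go into the ImageJ resolution/spacing fields; the channel
    role order is recorded in the ImageJ metadata so :func:`read_stack`
    can restore it.
    """
    roles = stack.roles
    dz, dy, dx = stack.voxel_dims
    arr = np.stack([stack[r].data.astype(np.float32) for r in roles], axis=1)  # (Z, C, Y, X)
    tifffile.imwrite(
        str(path),
        arr,
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={
            "spacing": dz,
            "unit": "um",
            "axes": "ZCYX",
            "channel_roles": json.dumps(roles),
        },
    )


def read_stack(path, roles: list[str] | None = None) -> MultiChannelStack:
    """Read a multi-channel TIFF written by :func:`write_stack` (or any
    ZCYX/CZYX ImageJ hyperstack); ``roles`` overrides stored channel names."""
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        arr = series.asarray()
        axes = series.axes
        meta = tf.imagej_metadata or {}
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")

    def _res_to_um(tag, default=1.0):
        if tag is None:
            return default
        num, den = tag.value
        return den / num if num else default

    dx = _res_to_um(xres)
    dy = _res_to_um(yres)
    dz = float(meta.get("spacing", 1.0))

    if axes == "ZCYX":
        pass
    elif axes == "CZYX":
        arr = np.moveaxis(arr, 0, 1)
    elif axes in ("ZYX", "QYX", "IYX"):  # plain page stacks: treat pages as z
        arr = arr[:, None]
    elif axes == "YX":
        arr = arr[None, None]
    else:
        raise ConfigurationError(f"unsupported TIFF axes order {axes!r}")

    n_channels = arr.shape[1]
    if roles is None:
        stored = meta.get("channel_roles")
        if stored:
            roles = json.loads(stored)
        else:
            roles = [f"channel_{i}" for i in range(n_channels)]
    if len(roles) != n_channels:
        raise ConfigurationError(
            f"roles has {len(roles)} entries but the stack has {n_channels} channels"
        )
    channels = {
        role: VoxelGrid(np.clip(arr[:, i].astype(np.float64), 0, None), (dz, dy, dx), channel_role=role)
        for i, role in enumerate(roles)
    }
    return MultiChannelStack(channels)
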