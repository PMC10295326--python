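"""Core image container and stack I/O.

Everything in the pipeline moves through :class:`VoxelVolume`: a 3-D scalar
grid in ``(z, y, x)`` index order with per-axis physical voxel sizes in
millimetres.  Intensities are either 8-bit grayscale (``uint8`` / float in
``[0, 255]``) or binary ``{0, 1}``.  Voxel centres sit at
``origin + (i + 0.5) * voxel_size`` along each axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

__all__ = ["VoxelVolume", "read_stack", "write_stack"]


@dataclass
class VoxelVolume:
    """A 3-D scalar grid with physical voxel geometry.

    Parameters
    ----------
    data
        Array of shape ``(nz, ny, nx)``.
    voxel_size
        ``(dz, dy, dx)`` in mm; all components strictly positive.
    origin
        Physical coordinate of the grid corner (mm); voxel centre ``i`` lies
        at ``origin + (i + 0.5) * voxel_size``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D (z, y, x) data, got ndim={self.data.ndim}")
        if any(n < 1 for n in self.data.shape):
            raise ValueError(f"every axis must have length >= 1, got {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")
        self.origin = tuple(float(v) for v in self.origin)

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size (z, y, x) in mm."""
        return tuple(n * v for n, v in zip(self.data.shape, self.voxel_size))

    @property
    def is_isotropic(self) -> bool:
        dz, dy, dx = self.voxel_size
        return abs(dz - dy) < 1e-9 and abs(dy - dx) < 1e-9

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis (mm)."""
        n = self.data.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size[axis]

    # -- content ----------------------------------------------------------
    @property
    def is_binary(self) -> bool:
        vals = np.unique(self.data)
        return vals.size <= 2 and np.isin(vals, (0, 1)).all()

    def require_binary(self) -> np.ndarray:
        if not self.is_binary:
            raise ValueError("volume is not binary {0,1}")
        return self.data.astype(bool)

    def with_data(self, data: np.ndarray) -> "VoxelVolume":
        return replace(self, data=data)

    def astype_u8(self) -> "VoxelVolume":
        return self.with_data(np.clip(np.rint(self.data), 0, 255).astype(np.uint8))


def write_stack(path, volume: VoxelVolume) -> None:
    """Write a volume as a multi-page TIFF, one page per z-slice.

    Voxel sizes are recorded in the TIFF resolution tags (pixels per mm
    in-plane) and the ImageJ-style ``spacing`` metadata for the z step.
    """
    dz, dy, dx = volume.voxel_size
    tifffile.imwrite(
        path,
        np.asarray(volume.data),
        resolution=(1.0 / dx, 1.0 / dy),
        resolutionunit="NONE",
        metadata={"spacing": dz, "unit": "mm", "axes": "ZYX"},
        imagej=volume.data.dtype == np.uint8,
    )


def read_stack(path, voxel_size=None) -> VoxelVolume:
    """Read a multi-page TIFF into a VoxelVolume.

    If ``voxel_size`` is not given it is recovered from the tags written by
    :func:`write_stack`; a plain TIFF without tags defaults to unit voxels.
    """
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if data.ndim == 2:
            data = data[None]
        if voxel_size is None:
            dz = dy = dx = 1.0
            try:
                page = tf.pages[0]
                xres = page.tags["XResolution"].value
                yres = page.tags["YResolution"].value
                dx = xres[1] / xres[0]
                dy = yres[1] / yres[0]
                meta = tf.imagej_metadata or {}
                if not meta and tf.shaped_metadata:
                    meta = tf.shaped_metadata[0]
                dz = float(meta.get("spacing", 1.0))
            except (KeyError, TypeError, ZeroDivisionError):
                pass
            voxel_size = (dz, dy, dx)
    return VoxelVolume(data=data, voxel_size=tuple(voxel_size))
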