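"""Image-stack containers and TIFF I/O.

Arrays are stored in ``(z, y, x)`` axis order (the order ``tifffile``
reads a plane-by-plane stack), while physical voxel sizes are carried as
``(dx, dy, dz)`` in micrometres, matching the acquisition convention of
in-plane resolution first.  The default voxel size is the intravital
two-photon geometry of 0.83 x 0.83 um in plane and 5 um steps in z.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

DEFAULT_VOXEL_SIZE_UM = (0.83, 0.83, 5.0)

#: canonical channel roles for multi-channel intravital stacks
CHANNEL_ENDOTHELIUM = "endothelium"
CHANNEL_PERFUSION = "perfusion"
CHANNEL_TUMOR = "tumor"


@dataclass
class ImageStack:
    """A 3D multi-channel voxel grid with physical voxel sizes.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, nz, ny, nx)``.
    voxel_size_um
        ``(dx, dy, dz)`` in micrometres.
    channels
        Role name per channel, e.g. ``("endothelium", "perfusion")``.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM
    channels: tuple[str, ...] = (CHANNEL_ENDOTHELIUM,)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError("stack data must be (channels, z, y, x)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} channels"
            )
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent (x, y, z) in micrometres."""
        nz, ny, nx = self.shape_zyx
        dx, dy, dz = self.voxel_size_um
        return (nx * dx, ny * dy, nz * dz)

    @property
    def projected_area_mm2(self) -> float:
        """x-y footprint of the stack in mm^2 (analysis-area default)."""
        ex, ey, _ = self.extent_um
        return ex * ey / 1e6

    def channel(self, role: str) -> np.ndarray:
        """Return the 3D array for a channel role."""
        try:
            idx = self.channels.index(role)
        except ValueError:
            raise KeyError(
                f"channel {role!r} not present (have {self.channels})"
            ) from None
        return self.data[idx]

    def has_channel(self, role: str) -> bool:
        return role in self.channels

    # -- I/O ---------------------------------------------------------------

    def write_tiff(self, path: str | Path) -> None:
        """Write as a multi-series TIFF with a JSON sidecar of metadata."""
        path = Path(path)
        tifffile.imwrite(path, self.data.astype(np.float32), photometric="minisblack", metadata=None)
        sidecar = {
            "voxel_size_um": list(self.voxel_size_um),
            "channels": list(self.channels),
            "meta": self.meta,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read_tiff(cls, path: str | Path) -> "ImageStack":
        path = Path(path)
        data = tifffile.imread(path)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            return cls(
                data,
                tuple(sidecar["voxel_size_um"]),
                tuple(sidecar["channels"]),
                sidecar.get("meta", {}),
            )
        if data.ndim == 3:
            data = data[None]
        return cls(data, DEFAULT_VOXEL_SIZE_UM, tuple(f"ch{i}" for i in range(data.shape[0])))


@dataclass
class VesselMask:
    """Binary 3D mask aligned to a (possibly resampled) stack grid."""

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]
    channel: str = CHANNEL_ENDOTHELIUM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D (z, y, x)")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")

    @property
    def voxel_volume_um3(self) -> float:
        dx, dy, dz = self.voxel_size_um
        return dx * dy * dz

    @property
    def projected_area_mm2(self) -> float:
        nz, ny, nx = self.data.shape
        dx, dy, dz = self.voxel_size_um
        return nx * dx * ny * dy / 1e6

    def write_tiff(self, path: str | Path) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.data.astype(np.uint8), photometric="minisblack")
        sidecar = {"voxel_size_um": list(self.voxel_size_um), "channel": self.channel}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def read_tiff(cls, path: str | Path) -> "VesselMask":
        path = Path(path)
        data = tifffile.imread(path) > 0
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(data, tuple(sidecar["voxel_size_um"]), sidecar.get("channel", "endothelium"))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary arrays."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
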