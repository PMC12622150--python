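"""Calibrated multi-channel voxel grids.

A :class:`VoxelGrid` is the in-memory representation of one imaged field of
view: a dictionary of ``(n_z, n_y, n_x)`` intensity arrays, one per
fluorescence channel, plus the physical voxel calibration (lateral pixel
size and axial step, both in micrometres).  All geometry downstream of the
segmentation stage is computed in physical units; the convention throughout
the package is that voxel index ``i`` along an axis with spacing ``s`` sits
at physical position ``(i + 0.5) * s``.

Grids round-trip through plain multi-page TIFF (axis order ``C, Z, Y, X``)
with a JSON sidecar carrying channel names and calibration, so stacks
written by ``nucleovol simulate`` can be re-read by ``nucleovol run`` or by
any external TIFF reader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["VoxelGrid"]


@dataclass
class VoxelGrid:
    """One multi-channel z-stack with physical voxel calibration.

    Parameters
    ----------
    channels
        Mapping of channel name to a ``(n_z, n_y, n_x)`` float array.
        All channels must share one shape.
    pixel_size_xy
        Lateral pixel size in micrometres.
    z_step
        Axial slice spacing in micrometres.
    """

    channels: dict[str, np.ndarray]
    pixel_size_xy: float
    z_step: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("VoxelGrid needs at least one channel")
        shapes = {ch: np.asarray(a).shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if next(iter(shapes.values())).__len__() != 3:
            raise ValueError("channel arrays must be 3-D (z, y, x)")
        if self.pixel_size_xy <= 0 or self.z_step <= 0:
            raise ValueError("voxel calibration must be positive")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def n_z(self) -> int:
        return self.shape[0]

    @property
    def calibration(self) -> tuple[float, float]:
        """``(pixel_size_xy, z_step)`` in micrometres."""
        return (self.pixel_size_xy, self.z_step)

    @property
    def voxel_volume_um3(self) -> float:
        return self.pixel_size_xy**2 * self.z_step

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"unknown channel {name!r}; available: {sorted(self.channels)}"
            ) from None

    def scaled(self, name: str, k: float) -> "VoxelGrid":
        """Return a copy with one channel multiplied by ``k`` (for
        linearity checks)."""
        chans = {c: a.copy() for c, a in self.channels.items()}
        chans[name] = self.channel(name) * k
        return VoxelGrid(chans, self.pixel_size_xy, self.z_step, dict(self.meta))

    # -- I/O -------------------------------------------------------------
    def save_tiff(self, path: str | Path) -> Path:
        """Write a ``(C, Z, Y, X)`` TIFF plus a ``.json`` sidecar with the
        channel order and calibration."""
        path = Path(path)
        names = list(self.channels)
        data = np.stack([np.asarray(self.channels[c], dtype=np.float32) for c in names])
        tifffile.imwrite(path, data, metadata=None)
        sidecar = {
            "channels": names,
            "pixel_size_xy": self.pixel_size_xy,
            "z_step": self.z_step,
            "meta": self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
        return path

    @classmethod
    def load_tiff(cls, path: str | Path) -> "VoxelGrid":
        path = Path(path)
        sidecar_path = path.with_suffix(".json")
        if not sidecar_path.exists():
            raise FileNotFoundError(
                f"missing sidecar {sidecar_path} (channel names and calibration)"
            )
        sidecar = json.loads(sidecar_path.read_text())
        data = tifffile.imread(path)
        names = sidecar["channels"]
        if data.ndim == 3:
            # pages on disk are C*Z planes in channel-major order
            if data.shape[0] % len(names):
                raise ValueError(
                    f"TIFF has {data.shape[0]} planes, not divisible by the "
                    f"{len(names)} sidecar channels"
                )
            data = data.reshape(len(names), -1, *data.shape[1:])
        if len(names) != data.shape[0]:
            raise ValueError(
                f"sidecar lists {len(names)} channels but TIFF has {data.shape[0]}"
            )
        channels = {c: np.asarray(data[i], dtype=np.float64) for i, c in enumerate(names)}
        return cls(
            channels,
            float(sidecar["pixel_size_xy"]),
            float(sidecar["z_step"]),
            sidecar.get("meta", {}),
        )
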