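"""Core in-memory containers for volumetric microscopy data.

Arrays are indexed ``(z, y, x)`` (optionally with a leading channel axis) and
carry an anisotropic physical voxel spacing in micrometres.  The physical
coordinate of a voxel centre is ``index * spacing``; all distances, volumes and
lengths reported by the package are in physical units (µm, µm², µm³).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid", "BinaryMask"]


def _validate_spacing(spacing_um: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing_um)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing_um must be 3 positive lengths, got {spacing_um!r}")
    return spacing  # type: ignore[return-value]


@dataclass
class VoxelGrid:
    """A 3D (optionally multi-channel) intensity image with physical spacing.

    Parameters
    ----------
    values
        Intensity array, shape ``(z, y, x)`` for a single channel or
        ``(c, z, y, x)`` channel-first for a multi-channel stack.
    spacing_um
        Physical voxel size ``(dz, dy, dx)`` in µm.
    channel_names
        Channel labels, e.g. ``("DAPI", "CD31", "CFSE")``; required when
        ``values`` has a channel axis.
    """

    values: np.ndarray
    spacing_um: tuple[float, float, float]
    channel_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.spacing_um = _validate_spacing(self.spacing_um)
        if self.values.ndim == 3:
            if self.channel_names and len(self.channel_names) != 1:
                raise ValueError("3D grid may carry at most one channel name")
        elif self.values.ndim == 4:
            if not self.channel_names:
                raise ValueError("multi-channel grid requires channel_names")
            if len(self.channel_names) != self.values.shape[0]:
                raise ValueError(
                    f"{self.values.shape[0]} channels but "
                    f"{len(self.channel_names)} channel names"
                )
        else:
            raise ValueError(f"values must be 3D or 4D, got ndim={self.values.ndim}")
        self.channel_names = tuple(self.channel_names)

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return tuple(self.values.shape[-3:])  # type: ignore[return-value]

    @property
    def n_channels(self) -> int:
        return 1 if self.values.ndim == 3 else self.values.shape[0]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing_um
        return dz * dy * dx

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Return one channel as a plain 3D array."""
        if self.values.ndim == 3:
            if name_or_index in (0, *(self.channel_names or ())):
                return self.values
            raise KeyError(f"channel {name_or_index!r} not present")
        if isinstance(name_or_index, str):
            try:
                idx = self.channel_names.index(name_or_index)
            except ValueError:
                raise KeyError(
                    f"channel {name_or_index!r} not in {self.channel_names}"
                ) from None
        else:
            idx = int(name_or_index)
        return self.values[idx]


@dataclass
class BinaryMask:
    """A 3D boolean mask sharing the geometry of its source grid."""

    values: np.ndarray
    spacing_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.values.ndim}")
        self.spacing_um = _validate_spacing(self.spacing_um)

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing_um
        return dz * dy * dx

    @property
    def volume_um3(self) -> float:
        """Foreground voxel count times the voxel volume."""
        return float(self.values.sum()) * self.voxel_volume_um3

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def is_empty(self) -> bool:
        return not bool(self.values.any())

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        self._check_compatible(other)
        return BinaryMask(self.values & other.values, self.spacing_um)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        self._check_compatible(other)
        return BinaryMask(self.values | other.values, self.spacing_um)

    def __sub__(self, other: "BinaryMask") -> "BinaryMask":
        self._check_compatible(other)
        return BinaryMask(self.values & ~other.values, self.spacing_um)

    def _check_compatible(self, other: "BinaryMask") -> None:
        if self.values.shape != other.values.shape:
            raise ValueError("mask shapes differ")
        if not np.allclose(self.spacing_um, other.spacing_um):
            raise ValueError("mask spacings differ")
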