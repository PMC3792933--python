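"""Shared array containers and timing helpers.

Volumes are plain numpy arrays with an accompanying 4x4 NIfTI-style affine
(voxel index -> world mm, RAS). Time is always seconds.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimedVolumeSeries",
    "ParameterMap",
    "dce_time_vector",
    "voxel_to_world",
    "world_to_voxel",
    "default_affine",
]


def default_affine(voxel_size_mm) -> np.ndarray:
    """Axis-aligned affine with the given spacing and origin at voxel (0,0,0)."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def voxel_to_world(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    ijk = np.asarray(ijk, dtype=float)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def world_to_voxel(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    xyz = np.asarray(xyz, dtype=float)
    return xyz @ inv[:3, :3].T + inv[:3, 3]


def dce_time_vector(
    n_frames: int = 96,
    frame_interval_s: float = 4.3,
    gap_after_frame: int = 48,
    gap_s: float = 60.0,
) -> np.ndarray:
    """Frame-start times for a dynamic series acquired in two blocks.

    Frame ``i`` starts at ``i * frame_interval_s``; every frame with index
    greater than ``gap_after_frame`` is additionally delayed by ``gap_s``
    (the pause between the two sequential acquisitions), so
    ``t[gap_after_frame + 1] - t[gap_after_frame] == frame_interval_s + gap_s``.
    """
    if n_frames < 2:
        raise ValueError(f"n_frames must be >= 2, got {n_frames}")
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be positive")
    if gap_s < 0:
        raise ValueError("gap_s must be non-negative")
    t = np.arange(n_frames, dtype=float) * frame_interval_s
    if 0 <= gap_after_frame < n_frames - 1:
        t[gap_after_frame + 1:] += gap_s
    if np.any(np.diff(t) <= 0):
        raise ValueError("time vector must be strictly increasing")
    return t


@dataclass
class TimedVolumeSeries:
    """4D image (x, y, z, t) with an explicit, possibly non-uniform time axis."""

    data: np.ndarray
    times_s: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")
        if self.data.shape[3] != self.times_s.size:
            raise ValueError(
                f"time axis mismatch: {self.data.shape[3]} frames vs "
                f"{self.times_s.size} time points"
            )
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times_s must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


@dataclass
class ParameterMap:
    """Scalar 3D map with units metadata and a normalization flag.

    Undefined voxels are NaN.
    """

    data: np.ndarray
    name: str
    units: str = ""
    normalized: bool = False
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ParameterMap data must be 3D")
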