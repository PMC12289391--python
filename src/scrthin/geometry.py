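"""Detector-array geometry and the rectangular state space.

All coordinates are in meters and all distances Euclidean. The detector
array is a regular lattice; the state space is the array's bounding box
expanded by a buffer on every side (conventionally a multiple of the
detection scale sigma, so that activity centers with non-negligible
detection probability are inside it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class DetectorGrid:
    """A regular ``nx`` x ``ny`` lattice of point detectors.

    Attributes
    ----------
    coords : ndarray of shape (nx * ny, 2)
        Detector positions in meters, ordered x-fastest (column-major in
        grid indices: detector ``(a, b)`` sits at row ``a * ny + b``).
    nx, ny : int
        Lattice dimensions.
    spacing : float
        Nearest-neighbor distance in meters.
    """

    coords: np.ndarray
    nx: int
    ny: int
    spacing: float

    @property
    def n_detectors(self) -> int:
        return self.nx * self.ny

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the detector positions."""
        x, y = self.coords[:, 0], self.coords[:, 1]
        return float(x.min()), float(x.max()), float(y.min()), float(y.max())


@dataclass(frozen=True)
class StateSpace:
    """Axis-aligned rectangle over which activity centers are distributed."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float
    buffer: float = 0.0

    @property
    def area(self) -> float:
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which of the (n, 2) points lie in the rectangle."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return (
            (p[:, 0] >= self.xmin)
            & (p[:, 0] <= self.xmax)
            & (p[:, 1] >= self.ymin)
            & (p[:, 1] <= self.ymax)
        )


def build_detector_grid(
    nx: int,
    ny: int,
    spacing: float,
    origin: tuple[float, float] = (0.0, 0.0),
) -> DetectorGrid:
    """Construct a regular detector lattice.

    Detector ``(a, b)`` is placed at ``origin + (a * spacing, b * spacing)``
    for ``a in 0..nx-1``, ``b in 0..ny-1``; the bounding box therefore spans
    ``(nx - 1) * spacing`` by ``(ny - 1) * spacing`` meters.
    """
    nx, ny = int(nx), int(ny)
    if nx < 1 or ny < 1:
        raise ValueError(f"grid dimensions must be >= 1, got nx={nx}, ny={ny}")
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    ox, oy = origin
    xs = ox + spacing * np.arange(nx)
    ys = oy + spacing * np.arange(ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    coords = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    coords.setflags(write=False)
    return DetectorGrid(coords=coords, nx=nx, ny=ny, spacing=float(spacing))


def build_state_space(grid: DetectorGrid, buffer: float) -> StateSpace:
    """State-space rectangle: grid bounding box expanded by ``buffer``."""
    if buffer < 0:
        raise ValueError(f"buffer must be non-negative, got {buffer}")
    xmin, xmax, ymin, ymax = grid.bounding_box()
    return StateSpace(
        xmin=xmin - buffer,
        xmax=xmax + buffer,
        ymin=ymin - buffer,
        ymax=ymax + buffer,
        buffer=float(buffer),
    )
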