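"""Grid-based colony quantification for arrayed plate images.

Arrayed (SGA-style) colonies sit on a known lattice, so no segmentation
is needed: each colony's size is the background-subtracted integrated
intensity inside a fixed radius around its grid position.  Background
is estimated per cell as the median of a ring just outside the
integration radius, which tolerates smooth plate-wide gradients.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GridSpec", "GeometryError", "quantify_plate_image",
           "read_image", "write_image"]


class GeometryError(ValueError):
    """Grid geometry incompatible with the image."""


@dataclass(frozen=True)
class GridSpec:
    """Colony lattice: corner centers in pixel (y, x) coordinates.

    The four corners are the centers of the outermost colonies; interior
    centers are interpolated bilinearly, which reduces to an affine map
    when the corners are affine-consistent.
    """

    n_rows: int
    n_cols: int
    top_left: tuple[float, float]
    top_right: tuple[float, float]
    bottom_left: tuple[float, float]
    bottom_right: tuple[float, float]
    cell_radius: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise GeometryError("grid must have positive dimensions")
        if self.cell_radius <= 0:
            raise GeometryError("cell_radius must be positive")
        pitch = self.pitch()
        if pitch is not None and self.cell_radius >= pitch / 2.0:
            raise GeometryError(
                f"cell_radius {self.cell_radius} >= half lattice pitch "
                f"{pitch / 2.0}")

    def pitch(self) -> float | None:
        """Smallest center-to-center spacing, or None for 1x1 grids."""
        pitches = []
        if self.n_cols > 1:
            tl, tr = np.asarray(self.top_left), np.asarray(self.top_right)
            pitches.append(np.linalg.norm(tr - tl) / (self.n_cols - 1))
        if self.n_rows > 1:
            tl, bl = np.asarray(self.top_left), np.asarray(self.bottom_left)
            pitches.append(np.linalg.norm(bl - tl) / (self.n_rows - 1))
        return min(pitches) if pitches else None

    def center(self, row: int, col: int) -> tuple[float, float]:
        """Pixel (y, x) center of the colony at 1-based (row, col)."""
        if not (1 <= row <= self.n_rows and 1 <= col <= self.n_cols):
            raise GeometryError(f"position ({row}, {col}) outside grid")
        u = 0.0 if self.n_rows == 1 else (row - 1) / (self.n_rows - 1)
        v = 0.0 if self.n_cols == 1 else (col - 1) / (self.n_cols - 1)
        tl = np.asarray(self.top_left, dtype=float)
        tr = np.asarray(self.top_right, dtype=float)
        bl = np.asarray(self.bottom_left, dtype=float)
        br = np.asarray(self.bottom_right, dtype=float)
        p = ((1 - u) * (1 - v) * tl + (1 - u) * v * tr
             + u * (1 - v) * bl + u * v * br)
        return float(p[0]), float(p[1])

    @classmethod
    def regular(cls, n_rows: int, n_cols: int, origin: tuple[float, float],
                pitch: float, cell_radius: float) -> "GridSpec":
        """Axis-aligned lattice with uniform pitch, origin = top-left center."""
        oy, ox = origin
        return cls(
            n_rows=n_rows, n_cols=n_cols,
            top_left=(oy, ox),
            top_right=(oy, ox + pitch * (n_cols - 1)),
            bottom_left=(oy + pitch * (n_rows - 1), ox),
            bottom_right=(oy + pitch * (n_rows - 1), ox + pitch * (n_cols - 1)),
            cell_radius=cell_radius,
        )

    def to_json(self) -> str:
        return json.dumps({
            "n_rows": self.n_rows, "n_cols": self.n_cols,
            "top_left": list(self.top_left),
            "top_right": list(self.top_right),
            "bottom_left": list(self.bottom_left),
            "bottom_right": list(self.bottom_right),
            "cell_radius": self.cell_radius,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GridSpec":
        d = json.loads(text)
        return cls(
            n_rows=d["n_rows"], n_cols=d["n_cols"],
            top_left=tuple(d["top_left"]), top_right=tuple(d["top_right"]),
            bottom_left=tuple(d["bottom_left"]),
            bottom_right=tuple(d["bottom_right"]),
            cell_radius=d["cell_radius"],
        )


def quantify_plate_image(image: np.ndarray, grid: GridSpec,
                         ring_width: float = 3.0) -> pd.DataFrame:
    """Integrate colony intensity per grid cell.

    Per cell: background = median intensity over the ring
    ``cell_radius < r <= cell_radius + ring_width``; size = sum of
    ``max(pixel - background, 0)`` over ``r <= cell_radius``.  Returns
    a DataFrame with columns row, col, size, background.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise GeometryError("expected a 2-D grayscale image")
    radius = grid.cell_radius
    half = radius + ring_width
    records = []
    for row in range(1, grid.n_rows + 1):
        for col in range(1, grid.n_cols + 1):
            cy, cx = grid.center(row, col)
            y0, y1 = int(math.floor(cy - half)), int(math.ceil(cy + half))
            x0, x1 = int(math.floor(cx - half)), int(math.ceil(cx + half))
            if y0 < 0 or x0 < 0 or y1 >= image.shape[0] or x1 >= image.shape[1]:
                raise GeometryError(
                    f"cell ({row}, {col}) window exceeds image bounds")
            win = image[y0:y1 + 1, x0:x1 + 1]
            yy, xx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
            r2 = (yy - cy) ** 2 + (xx - cx) ** 2
            inner = r2 <= radius * radius
            ring = (r2 > radius * radius) & (r2 <= half * half)
            background = float(np.median(win[ring])) if ring.any() else 0.0
            size = float(np.clip(win[inner] - background, 0.0, None).sum())
            records.append((row, col, size, background))
    return pd.DataFrame(records, columns=["row", "col", "size", "background"])


def read_image(path) -> np.ndarray:
    import imageio.v3 as iio
    return np.asarray(iio.imread(path), dtype=np.float64)


def write_image(path, image: np.ndarray) -> None:
    """Write a 16-bit grayscale image, scaling to the dtype range."""
    import imageio.v3 as iio
    arr = np.asarray(image, dtype=np.float64)
    top = max(arr.max(), 1.0)
    scaled = np.clip(arr / top * 65535.0, 0, 65535).astype(np.uint16)
    iio.imwrite(path, scaled)
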