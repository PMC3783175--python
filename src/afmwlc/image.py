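"""AFM height images: in-memory container and plain-format I/O.

Heights are stored in nm on a regular grid with square pixels. The physical
position of pixel ``(r, c)`` is ``x = (c + 0.5) * pixel_nm``,
``y = (r + 0.5) * pixel_nm`` (origin at the top-left image corner, y growing
with the row index).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy import ndimage

from .errors import ParameterError

__all__ = ["AFMImage"]


@dataclass
class AFMImage:
    """A single-channel AFM height map.

    Parameters
    ----------
    heights:
        2D array of heights in nm (row-major, origin top-left).
    pixel_nm:
        Pixel size in nm (square pixels).
    """

    heights: np.ndarray
    pixel_nm: float

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if self.heights.ndim != 2 or self.heights.size == 0:
            raise ParameterError("heights must be a non-empty 2D array")
        if not np.all(np.isfinite(self.heights)):
            raise ParameterError("heights must be finite")
        if not self.pixel_nm > 0:
            raise ParameterError(f"pixel_nm must be > 0, got {self.pixel_nm}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape  # type: ignore[return-value]

    @property
    def extent_nm(self) -> tuple[float, float]:
        """Physical (width, height) of the image in nm."""
        rows, cols = self.heights.shape
        return cols * self.pixel_nm, rows * self.pixel_nm

    # ---- coordinate transforms -------------------------------------------------
    def xy_to_rc(self, points_nm: np.ndarray) -> np.ndarray:
        """Convert (x, y) nm coordinates to fractional (row, col) indices."""
        p = np.atleast_2d(np.asarray(points_nm, dtype=float))
        rc = np.empty_like(p)
        rc[:, 0] = p[:, 1] / self.pixel_nm - 0.5
        rc[:, 1] = p[:, 0] / self.pixel_nm - 0.5
        return rc

    def rc_to_xy(self, rc: np.ndarray) -> np.ndarray:
        """Convert fractional (row, col) indices to (x, y) nm coordinates."""
        a = np.atleast_2d(np.asarray(rc, dtype=float))
        xy = np.empty_like(a)
        xy[:, 0] = (a[:, 1] + 0.5) * self.pixel_nm
        xy[:, 1] = (a[:, 0] + 0.5) * self.pixel_nm
        return xy

    def sample(self, points_nm: np.ndarray) -> np.ndarray:
        """Bilinearly interpolated heights at (x, y) nm positions.

        Positions outside the grid are clamped to the border value.
        """
        rc = self.xy_to_rc(points_nm)
        return ndimage.map_coordinates(
            self.heights, rc.T, order=1, mode="nearest"
        )

    # ---- I/O -------------------------------------------------------------------
    def to_tiff(self, path: str | Path) -> None:
        """Write a 32-bit float TIFF plus a YAML sidecar with pixel size."""
        path = Path(path)
        tifffile.imwrite(path, self.heights.astype(np.float32))
        sidecar = path.with_suffix(path.suffix + ".yaml")
        sidecar.write_text(
            yaml.safe_dump({"pixel_nm": float(self.pixel_nm), "units": "nm"})
        )

    @classmethod
    def from_tiff(cls, path: str | Path, pixel_nm: float | None = None) -> "AFMImage":
        """Read a float TIFF; pixel size from the YAML sidecar unless given."""
        path = Path(path)
        heights = tifffile.imread(path)
        if pixel_nm is None:
            sidecar = path.with_suffix(path.suffix + ".yaml")
            if not sidecar.exists():
                raise ParameterError(
                    f"no pixel_nm given and sidecar {sidecar} not found"
                )
            meta = yaml.safe_load(sidecar.read_text())
            pixel_nm = float(meta["pixel_nm"])
        return cls(heights=np.asarray(heights, dtype=np.float64), pixel_nm=pixel_nm)

    def to_text(self, path: str | Path) -> None:
        """Write a whitespace-delimited text grid (heights in nm)."""
        np.savetxt(path, self.heights, fmt="%.6f")

    @classmethod
    def from_text(cls, path: str | Path, pixel_nm: float) -> "AFMImage":
        return cls(heights=np.loadtxt(path), pixel_nm=pixel_nm)
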