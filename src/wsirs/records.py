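"""Shared cell-level record type.

Coordinates are pixels in the 40x frame, 0-based, origin at the top-left
corner of the slide, x increasing rightward and y downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

TUMOR = "tumor"
TIL = "til"
CELL_CLASSES = (TUMOR, TIL)


def polygon_area(contour: np.ndarray) -> float:
    """Shoelace area of a closed vertex list (shape (n, 2))."""
    return Polygon(contour).area


@dataclass
class CellRecord:
    """One detected or ground-truth cell.

    Parameters
    ----------
    cell_class : {"tumor", "til"}
    x, y : float
        Nucleus center in pixels (bounding-box center for detections).
    contour : (n, 2) ndarray, optional
        Simple polygon outlining the nucleus, same frame as (x, y).
    area : float, optional
        Nucleus area in px^2; must equal the polygon area when a contour
        is present (1e-6 relative).
    grade : int, optional
        Nuclear grade 1-3, when known (synthetic ground truth).
    """

    cell_class: str
    x: float
    y: float
    contour: np.ndarray | None = None
    area: float | None = None
    grade: int | None = field(default=None)

    def __post_init__(self) -> None:
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(f"unknown cell class {self.cell_class!r}")
        if self.x < 0 or self.y < 0:
            raise ValueError(f"negative cell center ({self.x}, {self.y})")
        if self.contour is not None:
            self.contour = np.asarray(self.contour, dtype=float)
            if self.contour.ndim != 2 or self.contour.shape[1] != 2:
                raise ValueError("contour must be an (n, 2) vertex array")
            poly = Polygon(self.contour)
            if not poly.is_simple:
                raise ValueError("contour is self-intersecting")
            if self.area is None:
                self.area = poly.area
            elif abs(self.area - poly.area) > 1e-6 * max(self.area, 1.0):
                raise ValueError(
                    f"stored area {self.area} disagrees with polygon area {poly.area}"
                )
        if self.area is not None and self.area <= 0:
            raise ValueError("cell area must be positive")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x, self.y)
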