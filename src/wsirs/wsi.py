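"""Slide-level scaffolding: tissue masking, fixed-grid tiling, per-tile
cell counting, density maps and top-k tile selection.

A whole-slide image is partitioned into a fixed grid of 1,024 x 1,024-px
tiles (half-open squares). Cell detections are binned by their centers;
the tiles richest in tumor cells drive the downstream feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv
from skimage.transform import resize

from .records import TIL, TUMOR, CellRecord

DEFAULT_TILE_SIZE = 1024


@dataclass(frozen=True)
class TileGrid:
    """Fixed square tiling of a canvas.

    Tile (r, c) covers the half-open square
    [c*s, (c+1)*s) x [r*s, (r+1)*s). Partial right/bottom remainders are
    excluded so that every tile has equal area (tile-wise features compare
    absolute counts).
    """

    tile_size: int
    n_rows: int
    n_cols: int
    tissue_flags: np.ndarray  # bool, (n_rows, n_cols)

    def __post_init__(self) -> None:
        flags = np.asarray(self.tissue_flags, dtype=bool)
        if flags.shape != (self.n_rows, self.n_cols):
            raise ValueError("tissue_flags shape does not match grid dims")
        object.__setattr__(self, "tissue_flags", flags)

    @property
    def n_tiles(self) -> int:
        return self.n_rows * self.n_cols


@dataclass(frozen=True)
class TileStats:
    """Per-tile detection counts."""

    tile_id: tuple[int, int]  # (row, col)
    n_tumor: int
    n_til: int

    @property
    def tumor_pct(self) -> float:
        """Tumor fraction of detected cells in the tile; 0 when empty."""
        total = self.n_tumor + self.n_til
        return self.n_tumor / total if total else 0.0


@dataclass(frozen=True)
class TileAssignment:
    """Outcome of binning cells into a grid.

    ``stats`` covers every tile of the grid in row-major order; cells whose
    centers fall in the dropped edge remainder, outside the canvas, or in
    non-tissue tiles are tallied separately so that counts are conserved:
    sum of per-tile counts + unassigned == number of input cells.
    """

    stats: list[TileStats]
    n_dropped_edge: int
    n_out_of_canvas: int

    @property
    def n_unassigned(self) -> int:
        return self.n_dropped_edge + self.n_out_of_canvas


def upscale_raster(img: np.ndarray) -> np.ndarray:
    """Double a raster's width and height by bilinear interpolation."""
    img = np.asarray(img)
    out_shape = (img.shape[0] * 2, img.shape[1] * 2) + img.shape[2:]
    out = resize(img, out_shape, order=1, preserve_range=True, anti_aliasing=False)
    return out.astype(img.dtype)


def upscale_cells(cells: list[CellRecord]) -> list[CellRecord]:
    """Map cell records from the 20x to the 40x frame: coordinates and
    contour vertices x2, areas x4 (similarity scaling)."""
    out = []
    for c in cells:
        out.append(
            CellRecord(
                cell_class=c.cell_class,
                x=c.x * 2.0,
                y=c.y * 2.0,
                contour=None if c.contour is None else c.contour * 2.0,
                area=None if c.area is None else c.area * 4.0,
                grade=c.grade,
            )
        )
    return out


def upscale_20x_to_40x(obj, magnification: str = "20x"):
    """Rescale a 20x input (raster, cell list, or scene) to the 40x frame.

    Slides scanned at 20x are brought to the common 40x analysis frame by
    linear resizing with a scaling factor of two along both axes.
    """
    tag = getattr(obj, "magnification_tag", magnification)
    if tag != "20x":
        raise ValueError(f"input is tagged {tag!r}; only 20x inputs can be upscaled")
    if isinstance(obj, np.ndarray):
        return upscale_raster(obj)
    if isinstance(obj, list):
        return upscale_cells(obj)
    if hasattr(obj, "cells"):  # SceneGroundTruth-like
        from dataclasses import replace

        return replace(
            obj,
            cells=upscale_cells(obj.cells),
            canvas_width=obj.canvas_width * 2,
            canvas_height=obj.canvas_height * 2,
            magnification_tag="40x",
        )
    raise TypeError(f"cannot upscale object of type {type(obj)!r}")


def tissue_mask(raster: np.ndarray, s_threshold: float = 30.0) -> np.ndarray:
    """Tissue = pixels whose HSV saturation exceeds ``s_threshold``.

    Saturation is on the 8-bit 0-255 scale ((max-min)/max * 255); the
    default cutoff of 30 separates stained tissue from white/gray
    background.
    """
    raster = np.asarray(raster)
    if raster.ndim != 3 or raster.shape[2] != 3:
        raise ValueError("tissue_mask expects an RGB (H, W, 3) raster")
    sat = rgb2hsv(raster)[..., 1] * 255.0
    return sat > s_threshold


def build_tile_grid(
    canvas_width: int,
    canvas_height: int,
    mask: np.ndarray | None = None,
    tile_size: int = DEFAULT_TILE_SIZE,
    tissue_fraction_min: float = 0.05,
) -> TileGrid:
    """Build the fixed tiling of a canvas, flagging tissue tiles.

    A tile is flagged as tissue when at least ``tissue_fraction_min`` of its
    pixels are tissue in ``mask`` (all tiles are tissue when no mask is
    given). Canvas must fit at least one full tile.
    """
    n_cols = canvas_width // tile_size
    n_rows = canvas_height // tile_size
    if n_rows < 1 or n_cols < 1:
        raise ValueError(
            f"canvas {canvas_width}x{canvas_height} smaller than one "
            f"{tile_size}-px tile"
        )
    if mask is None:
        flags = np.ones((n_rows, n_cols), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        flags = np.zeros((n_rows, n_cols), dtype=bool)
        for r in range(n_rows):
            for c in range(n_cols):
                patch = mask[r * tile_size : (r + 1) * tile_size,
                             c * tile_size : (c + 1) * tile_size]
                flags[r, c] = patch.mean() >= tissue_fraction_min
    return TileGrid(tile_size=tile_size, n_rows=n_rows, n_cols=n_cols,
                    tissue_flags=flags)


def assign_cells_to_tiles(cells: list[CellRecord], grid: TileGrid) -> TileAssignment:
    """Bin cells into grid tiles by their centers (half-open intervals).

    Cells in the dropped edge remainder or outside the canvas are counted
    in the returned tallies rather than raising.
    """
    s = grid.tile_size
    tumor = np.zeros((grid.n_rows, grid.n_cols), dtype=int)
    til = np.zeros_like(tumor)
    dropped_edge = out_of_canvas = 0
    for cell in cells:
        if cell.x < 0 or cell.y < 0:
            out_of_canvas += 1
            continue
        c, r = int(cell.x // s), int(cell.y // s)
        if r >= grid.n_rows or c >= grid.n_cols:
            dropped_edge += 1
            continue
        if cell.cell_class == TUMOR:
            tumor[r, c] += 1
        else:
            til[r, c] += 1
    stats = [
        TileStats(tile_id=(r, c), n_tumor=int(tumor[r, c]), n_til=int(til[r, c]))
        for r in range(grid.n_rows)
        for c in range(grid.n_cols)
    ]
    return TileAssignment(stats=stats, n_dropped_edge=dropped_edge,
                          n_out_of_canvas=out_of_canvas)


def tissue_stats(stats: list[TileStats], grid: TileGrid) -> list[TileStats]:
    """Restrict per-tile stats to tissue tiles."""
    return [s for s in stats if grid.tissue_flags[s.tile_id]]


def density_map(stats: list[TileStats], grid: TileGrid, cell_class: str) -> np.ndarray:
    """Per-tile count matrix for one cell class; non-tissue tiles are 0."""
    if cell_class not in (TUMOR, TIL):
        raise ValueError(f"unknown cell class {cell_class!r}")
    out = np.zeros((grid.n_rows, grid.n_cols), dtype=int)
    for s in stats:
        r, c = s.tile_id
        if grid.tissue_flags[r, c]:
            out[r, c] = s.n_tumor if cell_class == TUMOR else s.n_til
    return out


@dataclass(frozen=True)
class TopTileSelection:
    """Ordered top-k tiles by tumor count; ``short`` marks slides with
    fewer than k available tissue tiles."""

    tile_ids: list[tuple[int, int]]
    short: bool


def select_top_tiles(stats: list[TileStats], k: int = 10) -> TopTileSelection:
    """Pick the k tiles with the highest tumor cell count.

    Ties are broken by row-major tile index for reproducibility. Slides
    with fewer than k tiles return all of them, flagged short. The
    returned order is the tile-feature order i = 1..k.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    ranked = sorted(stats, key=lambda s: (-s.n_tumor, s.tile_id))
    chosen = ranked[:k]
    return TopTileSelection(tile_ids=[s.tile_id for s in chosen],
                            short=len(chosen) < k)


def stats_for_tiles(stats: list[TileStats],
                    tile_ids: list[tuple[int, int]]) -> list[TileStats]:
    """Look up per-tile stats for an ordered tile-id list."""
    by_id = {s.tile_id: s for s in stats}
    return [by_id[t] for t in tile_ids]
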