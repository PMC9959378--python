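"""Foot-pressure image reconstruction on the 10×22 visualization grid.

Each of the 16 film sensors covers two vertically adjacent grid squares, so a
percent vector seeds exactly 32 cells of the foot-shaped footprint.  The
remaining footprint cells are filled by iterated synchronous passes in which
every still-empty cell that has at least one valued 8-neighbor receives the
arithmetic mean of its valued 8-neighbors (masked and empty neighbors are
excluded from the mean, not counted as zero).  The synchronous (Jacobi-style)
update makes the result independent of cell enumeration order, and the
neighbor mean obeys a maximum principle: no filled value can leave the range
spanned by the seeds.

The true sensor coordinates of the physical insole are not published; the
canonical layout below is a reconstruction of the insole outline with the
sensors grouped into heel (4), midfoot (4), metatarsal (5) and toe (3) zones,
and is fully user-overridable through the layout JSON schema.

Coordinates are 0-based with x growing right and y growing down (toes at the
top); a cell address is written ``(x, y)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .firmware import N_SENSORS, PercentVector

__all__ = [
    "GRID_WIDTH",
    "GRID_HEIGHT",
    "SensorLayout",
    "FootGrid",
    "LayoutError",
    "GridError",
    "DEFAULT_ZONES",
    "default_layout",
    "seed_grid",
    "fill_grid",
    "render_grid",
    "save_layout",
    "load_layout",
    "grid_to_csv",
]

GRID_WIDTH = 10
GRID_HEIGHT = 22

# Cell states
MASKED, EMPTY, SEEDED, FILLED = -1, 0, 1, 2

_LAYOUT_FORMAT_VERSION = 1

#: Sensor indices per anatomical zone in the canonical layout, ordered
#: heel → midfoot → metatarsal → toe.
DEFAULT_ZONES: dict[str, tuple[int, ...]] = {
    "heel": (0, 1, 2, 3),
    "midfoot": (4, 5, 6, 7),
    "metatarsal": (8, 9, 10, 11, 12),
    "toe": (13, 14, 15),
}


class LayoutError(ValueError):
    """Invalid sensor layout."""


class GridError(ValueError):
    """Invalid grid state or unfillable grid."""


Cell = tuple[int, int]


@dataclass(frozen=True)
class SensorLayout:
    """Sensor-to-cell placement on a masked grid.

    ``seeds`` maps each sensor index 0–15 to its two distinct cell addresses;
    ``footprint_mask`` is a boolean (height, width) array, True where the
    insole covers the grid.
    """

    width: int
    height: int
    seeds: dict[int, tuple[Cell, Cell]]
    footprint_mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.footprint_mask, dtype=bool)
        object.__setattr__(self, "footprint_mask", mask)
        if mask.shape != (self.height, self.width):
            raise LayoutError(
                f"mask shape {mask.shape} != (height, width)=({self.height}, {self.width})"
            )
        if sorted(self.seeds) != list(range(N_SENSORS)):
            raise LayoutError(f"seeds must cover sensor indices 0..{N_SENSORS - 1}")
        cells = [c for pair in self.seeds.values() for c in pair]
        if len(set(cells)) != 2 * N_SENSORS:
            raise LayoutError("the 32 seed cells must all be distinct")
        for x, y in cells:
            if not (0 <= x < self.width and 0 <= y < self.height):
                raise LayoutError(f"seed cell ({x}, {y}) outside the grid")
            if not mask[y, x]:
                raise LayoutError(f"seed cell ({x}, {y}) outside the footprint mask")
        if not mask.any():
            raise LayoutError("footprint mask is empty")
        _, n_components = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        if n_components != 1:
            raise LayoutError(
                f"footprint mask must be 8-connected, found {n_components} components"
            )


@dataclass
class FootGrid:
    """A (height, width) grid of cell states and percent values."""

    layout: SensorLayout
    values: np.ndarray  # float, NaN where no value
    state: np.ndarray   # int8, one of MASKED/EMPTY/SEEDED/FILLED

    @property
    def complete(self) -> bool:
        return not np.any(self.state == EMPTY)

    def valued_mask(self) -> np.ndarray:
        return (self.state == SEEDED) | (self.state == FILLED)


# ---------------------------------------------------------------------------
# Canonical layout

# Per-row inclusive column spans of the reconstructed insole outline
# (row 0 = toes, row 21 = heel).
_DEFAULT_SPANS: list[tuple[int, int]] = [
    (2, 6), (1, 7), (0, 8), (0, 9), (0, 9), (0, 9), (0, 9), (0, 9),
    (1, 9), (1, 9), (2, 9), (2, 9), (2, 8), (2, 8), (2, 8), (1, 8),
    (1, 8), (1, 8), (1, 8), (1, 8), (2, 7), (3, 6),
]

# sensor index -> top cell of its vertical two-cell pair, grouped by zone
_DEFAULT_SEED_TOPS: dict[int, Cell] = {
    # heel
    0: (2, 17), 1: (4, 17), 2: (6, 17), 3: (8, 17),
    # midfoot
    4: (3, 10), 5: (5, 10), 6: (7, 10), 7: (9, 10),
    # metatarsal
    8: (0, 4), 9: (2, 4), 10: (4, 4), 11: (6, 4), 12: (8, 4),
    # toe
    13: (2, 1), 14: (4, 1), 15: (6, 1),
}


def default_layout() -> SensorLayout:
    """The package's canonical foot-shaped 10×22 layout (see module docstring)."""
    mask = np.zeros((GRID_HEIGHT, GRID_WIDTH), dtype=bool)
    for y, (x0, x1) in enumerate(_DEFAULT_SPANS):
        mask[y, x0 : x1 + 1] = True
    seeds = {
        k: ((x, y), (x, y + 1)) for k, (x, y) in _DEFAULT_SEED_TOPS.items()
    }
    return SensorLayout(
        width=GRID_WIDTH, height=GRID_HEIGHT, seeds=seeds, footprint_mask=mask
    )


# ---------------------------------------------------------------------------
# Seeding and filling

def seed_grid(layout: SensorLayout, vector: PercentVector) -> FootGrid:
    """Write each sensor's percent value to its two cells (32 seeded cells)."""
    values = np.full((layout.height, layout.width), np.nan)
    state = np.full((layout.height, layout.width), EMPTY, dtype=np.int8)
    state[~layout.footprint_mask] = MASKED
    for sensor, pair in layout.seeds.items():
        for x, y in pair:
            values[y, x] = vector.values[sensor]
            state[y, x] = SEEDED
    return FootGrid(layout=layout, values=values, state=state)


def _neighbor_mean(values: np.ndarray, known: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell mean over known 8-neighbors and the count of such neighbors."""
    v = np.where(known, values, 0.0)
    k = known.astype(float)
    vp = np.pad(v, 1)
    kp = np.pad(k, 1)
    h, w = values.shape
    total = np.zeros((h, w))
    count = np.zeros((h, w))
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            total += vp[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w]
            count += kp[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w]
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return mean, count


def fill_grid(grid: FootGrid) -> FootGrid:
    """Complete the grid by synchronous eight-nearest-neighbor averaging.

    Each pass computes, for every still-empty footprint cell with at least one
    valued 8-neighbor, the arithmetic mean of its valued 8-neighbors; all such
    cells update simultaneously, then the next pass begins.  Terminates when
    no empty cell remains.  Cells of the footprint that cannot ever be reached
    (an 8-connected mask guarantees there are none) raise a connectivity error.
    """
    if not grid.valued_mask().any():
        raise GridError("cannot fill: grid has no valued cells")
    values = grid.values.copy()
    state = grid.state.copy()
    # each productive pass fills >= 1 cell, so width*height passes always suffice
    max_passes = grid.layout.width * grid.layout.height
    for _ in range(max_passes):
        empty = state == EMPTY
        if not empty.any():
            break
        known = (state == SEEDED) | (state == FILLED)
        mean, count = _neighbor_mean(values, known)
        fillable = empty & (count > 0)
        if not fillable.any():
            ys, xs = np.nonzero(empty)
            cells = [(int(x), int(y)) for x, y in zip(xs, ys)]
            raise GridError(
                f"footprint component with no seed cannot be filled: {cells}"
            )
        values[fillable] = mean[fillable]
        state[fillable] = FILLED
    return FootGrid(layout=grid.layout, values=values, state=state)


# ---------------------------------------------------------------------------
# Rendering and IO

def render_grid(
    grid: FootGrid,
    out_prefix: str | Path,
    palette: str = "gray",
    scale: int = 12,
) -> tuple[Path, Path]:
    """Export a completed grid as PGM (grayscale) and PNG.

    Footprint intensities are mapped linearly from percent 0–100 onto 26–255
    so that a zero-pressure footprint stays visually distinct from the masked
    background (intensity 0).  ``palette`` names a matplotlib colormap for the
    PNG; ``"gray"`` keeps it grayscale.  Output bytes are deterministic for a
    given grid, palette and scale.
    """
    if not grid.complete:
        raise GridError("render_grid requires a completed grid (run fill_grid first)")
    from matplotlib import colormaps
    from PIL import Image

    footprint = grid.layout.footprint_mask
    vals = np.where(footprint, grid.values, 0.0)
    gray = np.where(footprint, 26 + np.round(vals / 100.0 * 229), 0).astype(np.uint8)

    out_prefix = Path(out_prefix)
    pgm_path = out_prefix.with_suffix(".pgm")
    png_path = out_prefix.with_suffix(".png")

    h, w = gray.shape
    rows = "\n".join(" ".join(str(v) for v in row) for row in gray)
    pgm_path.write_text(f"P2\n{w} {h}\n255\n{rows}\n")

    big = np.kron(gray, np.ones((scale, scale), dtype=np.uint8))
    if palette == "gray":
        img = Image.fromarray(big, mode="L")
    else:
        cmap = colormaps[palette]
        rgb = (np.asarray(cmap(big / 255.0))[..., :3] * 255).astype(np.uint8)
        big_mask = np.kron(footprint, np.ones((scale, scale), dtype=bool))
        rgb[~big_mask] = 0
        img = Image.fromarray(rgb, mode="RGB")
    img.save(png_path)
    return pgm_path, png_path


def grid_to_csv(grid: FootGrid, path: str | Path) -> None:
    """Dump grid values to CSV; masked cells are left blank."""
    lines = []
    for y in range(grid.layout.height):
        row = []
        for x in range(grid.layout.width):
            if grid.state[y, x] == MASKED:
                row.append("")
            elif np.isnan(grid.values[y, x]):
                row.append("")
            else:
                row.append(f"{grid.values[y, x]:.4f}")
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def _mask_runs(mask: np.ndarray) -> list[list[list[int]]]:
    runs_per_row: list[list[list[int]]] = []
    for row in mask:
        runs: list[list[int]] = []
        x = 0
        w = len(row)
        while x < w:
            if row[x]:
                x0 = x
                while x < w and row[x]:
                    x += 1
                runs.append([x0, x - 1])
            else:
                x += 1
        runs_per_row.append(runs)
    return runs_per_row


def save_layout(layout: SensorLayout, path: str | Path) -> None:
    """Serialize a layout to JSON (mask run-length encoded per row)."""
    payload = {
        "format_version": _LAYOUT_FORMAT_VERSION,
        "width": layout.width,
        "height": layout.height,
        "mask_runs": _mask_runs(layout.footprint_mask),
        "seeds": {
            str(k): [list(c) for c in pair] for k, pair in layout.seeds.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_layout(path: str | Path) -> SensorLayout:
    """Load a layout from its JSON serialization."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != _LAYOUT_FORMAT_VERSION:
        raise LayoutError(
            f"unsupported layout format version: {payload.get('format_version')}"
        )
    mask = np.zeros((payload["height"], payload["width"]), dtype=bool)
    for y, runs in enumerate(payload["mask_runs"]):
        for x0, x1 in runs:
            mask[y, x0 : x1 + 1] = True
    seeds = {
        int(k): (tuple(pair[0]), tuple(pair[1]))
        for k, pair in payload["seeds"].items()
    }
    return SensorLayout(
        width=payload["width"],
        height=payload["height"],
        seeds=seeds,
        footprint_mask=mask,
    )
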