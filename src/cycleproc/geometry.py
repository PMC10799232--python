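"""Translation registration across cycles and grid stitching into mosaics.

Inter-cycle drift is estimated by phase correlation on the nuclear channel and
applied unchanged to every channel of the cycle; tiles are then cropped to a
common frame by the greatest translation. Stitching measures neighbour offsets
on the overlap strips of the reference cycle/channel, solves global positions
over a maximum-quality spanning tree and composes one mosaic per
(cycle, channel) with distance-weighted feathering; the layout is computed once
and reused for every mosaic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .experiment_model import GridSpec, grid_to_index, index_to_grid

logger = logging.getLogger(__name__)

__all__ = [
    "Translation",
    "PairOffset",
    "MosaicLayout",
    "estimate_translation",
    "register_cycles",
    "apply_translation",
    "crop_to_common",
    "estimate_pairwise_offsets",
    "solve_global_positions",
    "compose_mosaic",
]


@dataclass(frozen=True)
class Translation:
    """Displacement of a moving image's content relative to the reference.

    ``moving ≈ roll(reference, (dy, dx))``; aligning shifts moving by
    (−dx, −dy). ``quality`` is the normalised cross-correlation after
    alignment, in [−1, 1].
    """

    dx: float
    dy: float
    quality: float = 0.0

    @property
    def is_integer(self) -> bool:
        return float(self.dx).is_integer() and float(self.dy).is_integer()


@dataclass(frozen=True)
class PairOffset:
    """Measured displacement between two adjacent tiles: position[to] − position[from]."""

    from_position: int
    to_position: int
    dx: float
    dy: float
    quality: float
    fallback: bool = False  # True when the nominal offset was substituted


@dataclass(frozen=True)
class MosaicLayout:
    """Global top-left pixel position of every tile, shared by all channels/cycles."""

    positions: dict  # position index -> (x, y)
    mosaic_width: int
    mosaic_height: int
    tile_width: int
    tile_height: int

    def __post_init__(self) -> None:
        for pos, (x, y) in self.positions.items():
            if x < 0 or y < 0 or x + self.tile_width > self.mosaic_width or (
                y + self.tile_height > self.mosaic_height
            ):
                raise ValueError(f"tile {pos} at ({x}, {y}) outside mosaic bounds")


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(np.float64).ravel()
    b = b.astype(np.float64).ravel()
    a -= a.mean()
    b -= b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def _aligned_overlap(reference: np.ndarray, moving: np.ndarray, dx: int, dy: int):
    """Overlapping sub-arrays after undoing a content displacement of (dx, dy).

    With ``moving = roll(reference, (dy, dx))``, moving[dy + k, dx + j]
    equals reference[k, j] over the common region.
    """
    h, w = reference.shape
    ry0, ry1 = max(-dy, 0), h + min(-dy, 0)
    rx0, rx1 = max(-dx, 0), w + min(-dx, 0)
    my0, my1 = max(dy, 0), h + min(dy, 0)
    mx0, mx1 = max(dx, 0), w + min(dx, 0)
    return reference[ry0:ry1, rx0:rx1], moving[my0:my1, mx0:mx1]


def estimate_translation(
    reference: np.ndarray, moving: np.ndarray, subpixel: bool = False
) -> Translation:
    """Phase-correlation translation estimate between two same-shape images."""
    reference = np.asarray(reference, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if reference.shape != moving.shape:
        raise ValueError("reference and moving images must share a shape")
    if reference.std() == 0 or moving.std() == 0:
        raise ValueError("cannot register a constant image")

    upsample = 50 if subpixel else 1
    shift, _, _ = phase_cross_correlation(
        reference, moving, upsample_factor=upsample, normalization="phase"
    )
    # phase_cross_correlation returns the (row, col) shift registering moving
    # onto reference; the content displacement is its negation.
    dy, dx = -float(shift[0]), -float(shift[1])

    idx, idy = int(round(dx)), int(round(dy))
    ref_ov, mov_ov = _aligned_overlap(reference, moving, idx, idy)
    quality = _ncc(ref_ov, mov_ov) if ref_ov.size else 0.0
    if not subpixel:
        dx, dy = float(idx), float(idy)
    return Translation(dx=dx, dy=dy, quality=quality)


def register_cycles(
    nuclear_tiles: dict, reference_cycle: int = 1, subpixel: bool = False
) -> dict:
    """Per-cycle Translation of one position's nuclear tiles vs the reference cycle.

    The translation of the reference cycle is (0, 0) by construction; each
    cycle's translation is meant to be applied unchanged to all its channels.
    """
    if reference_cycle not in nuclear_tiles:
        raise ValueError(f"reference cycle {reference_cycle} missing from tiles")
    reference = nuclear_tiles[reference_cycle]
    out: dict = {}
    for cycle in sorted(nuclear_tiles):
        if cycle == reference_cycle:
            out[cycle] = Translation(dx=0.0, dy=0.0, quality=1.0)
        else:
            out[cycle] = estimate_translation(reference, nuclear_tiles[cycle], subpixel)
    return out


def apply_translation(image: np.ndarray, translation: Translation) -> np.ndarray:
    """Undo a content displacement (align moving onto the reference frame).

    Integer shifts are applied by circular roll (wrapped pixels are removed by
    the subsequent common-frame crop); subpixel shifts use linear
    interpolation with reflective boundaries.
    """
    image = np.asarray(image, dtype=np.float64)
    if translation.is_integer:
        return np.roll(image, (-int(translation.dy), -int(translation.dx)), axis=(0, 1))
    return ndimage.shift(
        image, (-translation.dy, -translation.dx), order=1, mode="reflect"
    )


def crop_margins(translations: dict) -> tuple[int, int]:
    """(x_margin, y_margin) = ceil of the greatest |dx| and |dy| over cycles."""
    mx = max((abs(t.dx) for t in translations.values()), default=0.0)
    my = max((abs(t.dy) for t in translations.values()), default=0.0)
    return math.ceil(mx), math.ceil(my)


def crop_to_common(tiles: dict, translations: dict) -> dict:
    """Align every (cycle, channel) tile of one position and crop to a common frame.

    Symmetric margins of ceil(max |dx|) columns and ceil(max |dy|) rows are
    removed from each side, so all outputs share a shape and physical framing.
    """
    mx, my = crop_margins(translations)
    out: dict = {}
    for (cycle, channel), image in tiles.items():
        if cycle not in translations:
            raise ValueError(f"no translation for cycle {cycle}")
        h, w = image.shape
        if 2 * mx >= w or 2 * my >= h:
            raise ValueError(
                f"crop margins ({mx}, {my}) exceed tile size ({w}x{h}); drift too large"
            )
        aligned = apply_translation(image, translations[cycle])
        out[(cycle, channel)] = aligned[my : h - my, mx : w - mx]
    return out


def estimate_pairwise_offsets(
    tiles: dict,
    grid: GridSpec,
    acq_tile_width: int | None = None,
    acq_tile_height: int | None = None,
    subpixel: bool = False,
    min_quality: float = 0.5,
) -> list[PairOffset]:
    """Measure the offset of every 4-adjacent tile pair from its overlap strips.

    ``tiles`` maps 1-based snake position index to the reference-channel,
    reference-cycle 2D image. The nominal stride comes from the acquisition
    tile size (pass it when tiles were crop-reduced after registration; the
    stage stride does not shrink with the tiles). Low-quality (featureless)
    seams fall back to the nominal offset implied by the grid overlap.
    """
    if not tiles:
        return []
    some = next(iter(tiles.values()))
    h, w = some.shape
    aw = acq_tile_width if acq_tile_width is not None else w
    ah = acq_tile_height if acq_tile_height is not None else h
    stride_x = int(round(aw * (1.0 - grid.overlap_fraction)))
    stride_y = int(round(ah * (1.0 - grid.overlap_fraction)))
    ov_x = w - stride_x  # overlap of the (possibly cropped) tiles on disk
    ov_y = h - stride_y

    offsets: list[PairOffset] = []
    for row in range(1, grid.n_rows + 1):
        for col in range(1, grid.n_cols + 1):
            pos = grid_to_index(row, col, grid)
            if col < grid.n_cols:  # horizontal neighbour
                right = grid_to_index(row, col + 1, grid)
                if ov_x < 2:
                    logger.warning("no usable x-overlap %s->%s; nominal offset", pos, right)
                    offsets.append(PairOffset(pos, right, float(stride_x), 0.0,
                                              quality=0.0, fallback=True))
                else:
                    strip_a = tiles[pos][:, w - ov_x :]
                    strip_b = tiles[right][:, :ov_x]
                    offsets.append(
                        _strip_offset(pos, right, strip_a, strip_b,
                                      nominal=(stride_x, 0),
                                      subpixel=subpixel, min_quality=min_quality)
                    )
            if row < grid.n_rows:  # vertical neighbour
                down = grid_to_index(row + 1, col, grid)
                if ov_y < 2:
                    logger.warning("no usable y-overlap %s->%s; nominal offset", pos, down)
                    offsets.append(PairOffset(pos, down, 0.0, float(stride_y),
                                              quality=0.0, fallback=True))
                else:
                    strip_a = tiles[pos][h - ov_y :, :]
                    strip_b = tiles[down][:ov_y, :]
                    offsets.append(
                        _strip_offset(pos, down, strip_a, strip_b,
                                      nominal=(0, stride_y),
                                      subpixel=subpixel, min_quality=min_quality)
                    )
    return offsets


def _strip_offset(pos_a, pos_b, strip_a, strip_b, nominal, subpixel, min_quality):
    nominal_dx, nominal_dy = nominal
    try:
        t = estimate_translation(strip_a, strip_b, subpixel=subpixel)
    except ValueError:
        logger.warning("featureless overlap %s->%s; using nominal offset", pos_a, pos_b)
        return PairOffset(pos_a, pos_b, float(nominal_dx), float(nominal_dy),
                          quality=0.0, fallback=True)
    # strip_b content displaced by (dx, dy) means tile_b origin moved by (−dx, −dy)
    # relative to nominal.
    dx = nominal_dx - t.dx
    dy = nominal_dy - t.dy
    max_dev = max(strip_a.shape[1], strip_a.shape[0]) / 2
    if t.quality < min_quality or abs(dx - nominal_dx) > max_dev or abs(dy - nominal_dy) > max_dev:
        logger.warning(
            "low-quality seam %s->%s (q=%.2f); using nominal offset", pos_a, pos_b, t.quality
        )
        return PairOffset(pos_a, pos_b, float(nominal_dx), float(nominal_dy),
                          quality=t.quality, fallback=True)
    return PairOffset(pos_a, pos_b, dx, dy, quality=t.quality)


def solve_global_positions(
    offsets: list[PairOffset],
    grid: GridSpec,
    tile_width: int,
    tile_height: int,
    reference_position: int = 1,
) -> MosaicLayout:
    """Anchor the reference tile and propagate offsets along the
    maximum-quality spanning tree; shift so all coordinates are ≥ 0."""
    n = grid.n_positions
    if n == 1:
        return MosaicLayout(
            positions={1: (0, 0)},
            mosaic_width=tile_width,
            mosaic_height=tile_height,
            tile_width=tile_width,
            tile_height=tile_height,
        )
    g = nx.Graph()
    g.add_nodes_from(range(1, n + 1))
    for off in offsets:
        g.add_edge(off.from_position, off.to_position, weight=off.quality, offset=off)
    if not nx.is_connected(g):
        raise ValueError("tile graph is disconnected; cannot solve positions")
    tree = nx.maximum_spanning_tree(g, weight="weight")

    pos: dict = {reference_position: (0.0, 0.0)}
    for parent, child in nx.bfs_edges(tree, reference_position):
        off = tree.edges[parent, child]["offset"]
        px, py = pos[parent]
        if off.from_position == parent:
            pos[child] = (px + off.dx, py + off.dy)
        else:
            pos[child] = (px - off.dx, py - off.dy)

    xs = [p[0] for p in pos.values()]
    ys = [p[1] for p in pos.values()]
    x_min, y_min = min(xs), min(ys)
    positions = {
        k: (int(round(x - x_min)), int(round(y - y_min))) for k, (x, y) in pos.items()
    }
    mosaic_w = max(x for x, _ in positions.values()) + tile_width
    mosaic_h = max(y for _, y in positions.values()) + tile_height
    return MosaicLayout(
        positions=positions,
        mosaic_width=mosaic_w,
        mosaic_height=mosaic_h,
        tile_width=tile_width,
        tile_height=tile_height,
    )


def _feather_weights(height: int, width: int) -> np.ndarray:
    rows = np.minimum(np.arange(height) + 1, height - np.arange(height))
    cols = np.minimum(np.arange(width) + 1, width - np.arange(width))
    return np.minimum.outer(rows, cols).astype(np.float64)


def compose_mosaic(tiles: dict, layout: MosaicLayout, blend: str = "feather") -> np.ndarray:
    """Place tiles at their layout positions and blend overlaps.

    ``blend="feather"`` averages overlap pixels with linear distance-to-edge
    weights (exact for identical overlap content); ``blend="first"`` lets the
    lowest position index win. Returns float64; the caller casts to uint16.
    """
    th, tw = layout.tile_height, layout.tile_width
    acc = np.zeros((layout.mosaic_height, layout.mosaic_width), dtype=np.float64)
    wsum = np.zeros_like(acc)
    weights = _feather_weights(th, tw)
    for pos in sorted(tiles):
        tile = np.asarray(tiles[pos], dtype=np.float64)
        if tile.shape != (th, tw):
            raise ValueError(
                f"tile {pos} shape {tile.shape} != layout tile shape {(th, tw)}"
            )
        if pos not in layout.positions:
            raise ValueError(f"tile {pos} missing from layout")
        x, y = layout.positions[pos]
        if blend == "feather":
            acc[y : y + th, x : x + tw] += weights * tile
            wsum[y : y + th, x : x + tw] += weights
        elif blend == "first":
            region = wsum[y : y + th, x : x + tw] == 0
            acc[y : y + th, x : x + tw][region] = tile[region]
            wsum[y : y + th, x : x + tw][region] = 1.0
        else:
            raise ValueError(f"unknown blend mode: {blend!r}")
    covered = wsum > 0
    acc[covered] /= wsum[covered]
    return acc


# re-exported for callers that only deal in grids
_ = index_to_grid
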