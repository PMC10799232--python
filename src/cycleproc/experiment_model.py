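"""Acquisition data model: grid geometry, cycles/channels, tile naming and descriptor I/O.

All user-facing indices (cycle, position, Z, channel, row, column) are 1-based,
matching the raw file naming convention ``...-position{P}_Z{ZZ}_CH{C}.tif``.
Array coordinates are 0-based and conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

__all__ = [
    "GridSpec",
    "ChannelSpec",
    "CycleSpec",
    "ExperimentDescriptor",
    "TileKey",
    "grid_to_index",
    "index_to_grid",
    "tile_filename",
    "parse_tile_filename",
    "cycle_folder_name",
    "parse_experiment",
    "parse_channel_names",
    "load_experiment",
]

BLANK = "Blank"

_TILE_RE = re.compile(
    r"^(?P<name>.+)-position(?P<pos>\d+)_Z(?P<z>\d+)_CH(?P<ch>\d+)\.tif{1,2}$"
)


class DescriptorError(ValueError):
    """Raised when an experiment descriptor is malformed or inconsistent."""


@dataclass(frozen=True)
class GridSpec:
    """Tile grid geometry with snake (boustrophedon) position ordering.

    Row 1 is enumerated left-to-right, row 2 right-to-left, and so on.
    """

    n_cols: int
    n_rows: int
    overlap_fraction: float = 0.1
    ordering: str = "snake-by-rows"
    first_row_direction: str = "left-to-right"

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1:
            raise DescriptorError("grid dimensions must be positive")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise DescriptorError("overlap_fraction must be in [0, 1)")
        if self.ordering != "snake-by-rows":
            raise DescriptorError(f"unsupported ordering: {self.ordering!r}")
        if self.first_row_direction != "left-to-right":
            raise DescriptorError(
                f"unsupported first_row_direction: {self.first_row_direction!r}"
            )

    @property
    def n_positions(self) -> int:
        return self.n_cols * self.n_rows

    def positions(self) -> Iterator[int]:
        return iter(range(1, self.n_positions + 1))


@dataclass(frozen=True)
class ChannelSpec:
    index: int
    name: str
    emission_wavelength: float
    exposure: float | None = None

    def __post_init__(self) -> None:
        if self.emission_wavelength <= 0:
            raise DescriptorError("emission_wavelength must be positive")


@dataclass(frozen=True)
class CycleSpec:
    """One acquisition cycle: its 1-based index and one reporter name per channel.

    The literal reporter ``"Blank"`` marks a channel acquired without reporter.
    """

    index: int
    reporters: tuple[str, ...]

    def is_blank(self, channel: int) -> bool:
        return self.reporters[channel - 1] == BLANK


@dataclass(frozen=True)
class TileKey:
    """Address of one raw image plane: (cycle, position, z, channel), all 1-based."""

    cycle: int
    position: int
    z: int
    channel: int


@dataclass(frozen=True)
class ExperimentDescriptor:
    """Single source of truth for acquisition geometry, optics and cycle layout."""

    name: str
    grid: GridSpec
    channels: tuple[ChannelSpec, ...]
    cycles: tuple[CycleSpec, ...]
    n_z: int
    z_step: float
    pixel_size_xy: float
    numerical_aperture: float
    tile_width: int
    tile_height: int
    refractive_index: float = 1.0
    reference_channel: int = 1
    reference_cycle: int = 1
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.n_z < 1:
            raise DescriptorError("n_z must be >= 1")
        if self.tile_width < 1 or self.tile_height < 1:
            raise DescriptorError("tile dimensions must be positive")
        if not self.channels:
            raise DescriptorError("at least one channel required")
        got = [c.index for c in self.channels]
        if got != list(range(1, len(self.channels) + 1)):
            raise DescriptorError("channel indices must be contiguous from 1")
        if not (1 <= self.reference_channel <= len(self.channels)):
            raise DescriptorError("reference_channel out of range")
        if not self.cycles:
            raise DescriptorError("at least one cycle required")
        if not (1 <= self.reference_cycle <= len(self.cycles)):
            raise DescriptorError("reference_cycle out of range")
        for cyc in self.cycles:
            if len(cyc.reporters) != len(self.channels):
                raise DescriptorError(
                    f"cycle {cyc.index}: expected {len(self.channels)} reporters, "
                    f"got {len(cyc.reporters)}"
                )
            if cyc.is_blank(self.reference_channel):
                raise DescriptorError(
                    f"cycle {cyc.index}: nuclear reference channel must not be blank"
                )

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_positions(self) -> int:
        return self.grid.n_positions

    def is_blank(self, cycle: int, channel: int) -> bool:
        return self.cycles[cycle - 1].is_blank(channel)

    def reporter(self, cycle: int, channel: int) -> str:
        return self.cycles[cycle - 1].reporters[channel - 1]

    def non_blank_pairs(self) -> list[tuple[int, int]]:
        """(cycle, channel) pairs carrying a reporter, in cycle-major order."""
        return [
            (cyc.index, ch)
            for cyc in self.cycles
            for ch in range(1, self.n_channels + 1)
            if not cyc.is_blank(ch)
        ]

    def validate_key(self, key: TileKey) -> None:
        if not (1 <= key.cycle <= self.n_cycles):
            raise DescriptorError(f"cycle {key.cycle} out of range")
        if not (1 <= key.position <= self.n_positions):
            raise DescriptorError(f"position {key.position} out of range")
        if not (1 <= key.z <= self.n_z):
            raise DescriptorError(f"z {key.z} out of range")
        if not (1 <= key.channel <= self.n_channels):
            raise DescriptorError(f"channel {key.channel} out of range")

    def tile_keys(self, cycle: int) -> Iterator[TileKey]:
        for pos in self.grid.positions():
            for z in range(1, self.n_z + 1):
                for ch in range(1, self.n_channels + 1):
                    yield TileKey(cycle=cycle, position=pos, z=z, channel=ch)


def grid_to_index(row: int, col: int, grid: GridSpec) -> int:
    """Map 1-based (row, col) to the 1-based snake-order position index.

    Odd rows run left-to-right, even rows right-to-left.
    """
    if not (1 <= row <= grid.n_rows) or not (1 <= col <= grid.n_cols):
        raise IndexError(f"(row={row}, col={col}) outside {grid.n_rows}x{grid.n_cols} grid")
    base = (row - 1) * grid.n_cols
    if row % 2 == 1:
        return base + col
    return base + (grid.n_cols - col + 1)


def index_to_grid(index: int, grid: GridSpec) -> tuple[int, int]:
    """Inverse of :func:`grid_to_index`."""
    if not (1 <= index <= grid.n_positions):
        raise IndexError(f"index {index} outside 1..{grid.n_positions}")
    row = (index - 1) // grid.n_cols + 1
    offset = (index - 1) % grid.n_cols + 1
    col = offset if row % 2 == 1 else grid.n_cols - offset + 1
    return row, col


def tile_filename(key: TileKey, experiment_name: str) -> str:
    """Raw tile file name, e.g. ``myexp_image-position4_Z01_CH4.tif``."""
    return (
        f"{experiment_name}-position{key.position}"
        f"_Z{key.z:02d}_CH{key.channel}.tif"
    )


def parse_tile_filename(filename: str, cycle: int = 1) -> TileKey:
    """Invert :func:`tile_filename`; ``cycle`` comes from the folder, not the name."""
    m = _TILE_RE.match(filename)
    if m is None:
        raise ValueError(f"not a tile file name: {filename!r}")
    return TileKey(
        cycle=cycle,
        position=int(m.group("pos")),
        z=int(m.group("z")),
        channel=int(m.group("ch")),
    )


def cycle_folder_name(cycle: int, pattern: str = "cyc{:02d}") -> str:
    return pattern.format(cycle)


_REQUIRED_KEYS = (
    "name",
    "grid",
    "channels",
    "n_z",
    "z_step",
    "pixel_size_xy",
    "numerical_aperture",
    "tile_width",
    "tile_height",
)

_GRID_REQUIRED = ("n_cols", "n_rows", "overlap_fraction")


def parse_experiment(text: str, reporters: list[list[str]] | None = None) -> ExperimentDescriptor:
    """Parse the experiment descriptor JSON.

    ``reporters`` (from channelNames.txt) overrides any ``cycles`` key in the
    JSON; one of the two must supply the cycle layout. Unknown keys are kept in
    ``descriptor.extra`` but otherwise ignored.
    """
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DescriptorError(f"descriptor is not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise DescriptorError("descriptor JSON must be an object")

    for key in _REQUIRED_KEYS:
        if key not in raw:
            raise DescriptorError(f"missing required descriptor key: {key!r}")
    grid_raw = raw["grid"]
    for key in _GRID_REQUIRED:
        if key not in grid_raw:
            raise DescriptorError(f"missing required grid key: {key!r}")

    grid = GridSpec(
        n_cols=int(grid_raw["n_cols"]),
        n_rows=int(grid_raw["n_rows"]),
        overlap_fraction=float(grid_raw["overlap_fraction"]),
        ordering=grid_raw.get("ordering", "snake-by-rows"),
        first_row_direction=grid_raw.get("first_row_direction", "left-to-right"),
    )
    channels = tuple(
        ChannelSpec(
            index=int(c["index"]),
            name=str(c["name"]),
            emission_wavelength=float(c["emission_wavelength"]),
            exposure=float(c["exposure"]) if c.get("exposure") is not None else None,
        )
        for c in raw["channels"]
    )

    if reporters is None:
        if "cycles" not in raw:
            raise DescriptorError(
                "missing required descriptor key: 'cycles' (or supply channelNames.txt)"
            )
        reporters = [list(c["reporters"]) for c in raw["cycles"]]
    cycles = tuple(
        CycleSpec(index=i + 1, reporters=tuple(reps)) for i, reps in enumerate(reporters)
    )

    known = set(_REQUIRED_KEYS) | {
        "cycles",
        "refractive_index",
        "reference_channel",
        "reference_cycle",
    }
    extra = {k: v for k, v in raw.items() if k not in known}

    return ExperimentDescriptor(
        name=str(raw["name"]),
        grid=grid,
        channels=channels,
        cycles=cycles,
        n_z=int(raw["n_z"]),
        z_step=float(raw["z_step"]),
        pixel_size_xy=float(raw["pixel_size_xy"]),
        numerical_aperture=float(raw["numerical_aperture"]),
        refractive_index=float(raw.get("refractive_index", 1.0)),
        tile_width=int(raw["tile_width"]),
        tile_height=int(raw["tile_height"]),
        reference_channel=int(raw.get("reference_channel", 1)),
        reference_cycle=int(raw.get("reference_cycle", 1)),
        extra=extra,
    )


def parse_channel_names(text: str, n_channels: int, n_cycles: int | None = None) -> list[list[str]]:
    """Parse channelNames.txt: one reporter per line, cycle-major order.

    Returns one reporter list per cycle. ``"Blank"`` entries mark channels
    acquired without reporter.
    """
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if n_channels < 1:
        raise DescriptorError("n_channels must be positive")
    if len(lines) % n_channels != 0:
        raise DescriptorError(
            f"channelNames.txt has {len(lines)} entries, not a multiple of "
            f"{n_channels} channels"
        )
    inferred = len(lines) // n_channels
    if n_cycles is not None and inferred != n_cycles:
        raise DescriptorError(
            f"channelNames.txt implies {inferred} cycles but descriptor has {n_cycles}"
        )
    return [lines[i * n_channels : (i + 1) * n_channels] for i in range(inferred)]


def nominal_origin(grid: GridSpec, tile_width: int, tile_height: int, position: int) -> tuple[int, int]:
    """Nominal top-left (x, y) of a tile in mosaic pixels, from grid overlap alone."""
    row, col = index_to_grid(position, grid)
    stride_x = int(round(tile_width * (1.0 - grid.overlap_fraction)))
    stride_y = int(round(tile_height * (1.0 - grid.overlap_fraction)))
    return (col - 1) * stride_x, (row - 1) * stride_y


def mosaic_extent(grid: GridSpec, tile_width: int, tile_height: int) -> tuple[int, int]:
    """Nominal (width, height) of the stitched mosaic plane."""
    stride_x = int(round(tile_width * (1.0 - grid.overlap_fraction)))
    stride_y = int(round(tile_height * (1.0 - grid.overlap_fraction)))
    return (
        tile_width + (grid.n_cols - 1) * stride_x,
        tile_height + (grid.n_rows - 1) * stride_y,
    )


def descriptor_to_json(desc: ExperimentDescriptor) -> str:
    """Serialise a descriptor to the documented JSON dialect."""
    payload = {
        "name": desc.name,
        "grid": {
            "n_cols": desc.grid.n_cols,
            "n_rows": desc.grid.n_rows,
            "overlap_fraction": desc.grid.overlap_fraction,
            "ordering": desc.grid.ordering,
            "first_row_direction": desc.grid.first_row_direction,
        },
        "channels": [
            {
                "index": c.index,
                "name": c.name,
                "emission_wavelength": c.emission_wavelength,
                "exposure": c.exposure,
            }
            for c in desc.channels
        ],
        "cycles": [
            {"index": c.index, "reporters": list(c.reporters)} for c in desc.cycles
        ],
        "n_z": desc.n_z,
        "z_step": desc.z_step,
        "pixel_size_xy": desc.pixel_size_xy,
        "numerical_aperture": desc.numerical_aperture,
        "refractive_index": desc.refractive_index,
        "tile_width": desc.tile_width,
        "tile_height": desc.tile_height,
        "reference_channel": desc.reference_channel,
        "reference_cycle": desc.reference_cycle,
    }
    payload.update(desc.extra)
    return json.dumps(payload, indent=2)


def load_experiment(input_dir: str | Path) -> ExperimentDescriptor:
    """Load ``Experiment.json`` (+ ``channelNames.txt`` if present) from a directory."""
    input_dir = Path(input_dir)
    json_path = input_dir / "Experiment.json"
    if not json_path.exists():
        raise DescriptorError(f"no Experiment.json in {input_dir}")
    text = json_path.read_text()
    names_path = input_dir / "channelNames.txt"
    reporters = None
    if names_path.exists():
        raw = json.loads(text)
        n_channels = len(raw.get("channels", []))
        reporters = parse_channel_names(names_path.read_text(), n_channels)
    return parse_experiment(text, reporters=reporters)
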