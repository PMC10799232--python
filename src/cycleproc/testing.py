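"""Factories for small, fully valid experiment descriptors.

Used by the ``simulate`` CLI command and throughout the test suite; channel 1
is the nuclear stain present in every cycle, the other channels are blank in
the first and last (anchor) cycles.
"""

from __future__ import annotations

from .experiment_model import (
    BLANK,
    ChannelSpec,
    CycleSpec,
    ExperimentDescriptor,
    GridSpec,
)

__all__ = ["small_descriptor", "default_reporters"]

_WAVELENGTHS = (461.0, 590.0, 670.0, 780.0)
_REPORTER_POOL = (
    "CD20", "CD3e", "CD31", "CD45RO", "CD21", "CD4", "CD8", "Ki67", "FoxP3",
)


def default_reporters(n_cycles: int, n_channels: int, nuclear_channel: int = 1):
    """Reporter grid: nuclear stain everywhere, blanks on anchor cycles."""
    reporters = []
    pool = iter(_REPORTER_POOL * 10)
    for cycle in range(1, n_cycles + 1):
        row = []
        for ch in range(1, n_channels + 1):
            if ch == nuclear_channel:
                row.append("DAPI")
            elif cycle == 1 or cycle == n_cycles:
                row.append(BLANK)
            else:
                row.append(next(pool))
        reporters.append(row)
    return reporters


def small_descriptor(
    name: str = "synthexp_image",
    n_cols: int = 2,
    n_rows: int = 2,
    overlap_fraction: float = 0.1,
    n_channels: int = 2,
    n_cycles: int = 4,
    n_z: int = 1,
    z_step: float = 1.5,
    tile_width: int = 96,
    tile_height: int = 96,
    pixel_size_xy: float = 0.325,
    numerical_aperture: float = 0.8,
    reporters: list | None = None,
) -> ExperimentDescriptor:
    """A compact but structurally complete experiment descriptor."""
    if reporters is None:
        reporters = default_reporters(n_cycles, n_channels)
    return ExperimentDescriptor(
        name=name,
        grid=GridSpec(n_cols=n_cols, n_rows=n_rows, overlap_fraction=overlap_fraction),
        channels=tuple(
            ChannelSpec(index=i + 1, name=f"CH{i + 1}",
                        emission_wavelength=_WAVELENGTHS[i % len(_WAVELENGTHS)])
            for i in range(n_channels)
        ),
        cycles=tuple(
            CycleSpec(index=i + 1, reporters=tuple(r)) for i, r in enumerate(reporters)
        ),
        n_z=n_z,
        z_step=z_step,
        pixel_size_xy=pixel_size_xy,
        numerical_aperture=numerical_aperture,
        tile_width=tile_width,
        tile_height=tile_height,
    )
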