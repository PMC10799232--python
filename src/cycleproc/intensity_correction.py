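"""Intensity corrections: shading profiles, blank-cycle background subtraction,
negative-value cleanup.

Shading profiles are estimated on the two anchor cycles (first and last) of
each channel and linearly interpolated for the cycles in between; the blank
anchor cycles likewise provide the autofluorescence fields that are
interpolated and subtracted per cycle. All intermediates are carried in
floating point — negatives produced by the subtraction are resolved by
:func:`remove_negative_values` before the final unsigned cast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "ShadingProfile",
    "BackgroundModel",
    "compute_shading_profile",
    "interpolate_profile",
    "apply_shading",
    "compute_background",
    "subtract_background",
    "remove_negative_values",
]

_EPS = 1e-6


@dataclass(frozen=True)
class ShadingProfile:
    """Per-channel multiplicative correction field for one anchor cycle."""

    field: np.ndarray  # tile-sized, strictly positive, mean 1
    channel: int
    anchor_cycle: str  # "first" | "last"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.field)) or np.any(self.field <= 0):
            raise ValueError("shading field must be finite and strictly positive")


@dataclass(frozen=True)
class BackgroundModel:
    """Blurred blank-cycle autofluorescence field for one (channel, position, anchor)."""

    field: np.ndarray
    channel: int
    position: int
    anchor_cycle: str
    blur_sigma: float = 10.0

    def __post_init__(self) -> None:
        if np.any(self.field < 0):
            raise ValueError("background field must be nonnegative")


def _gaussian(image: np.ndarray, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(
        np.asarray(image, dtype=np.float64), sigma, mode="reflect", truncate=4.0
    )


def compute_shading_profile(
    tiles: Sequence[np.ndarray],
    channel: int = 0,
    anchor_cycle: str = "first",
    sigma: float = 64.0,
    mode: str = "ratio",
) -> ShadingProfile:
    """Estimate the shading profile from all positions of one anchor cycle.

    ``mode="ratio"`` (default) follows the literal recipe: the pixelwise
    median M across positions divided by its Gaussian blur, profile =
    M / (G_σ ⊛ M). ``mode="smooth"`` uses the conventional smooth flat-field
    G_σ ⊛ M instead. Either way the profile is mean-normalised to 1.
    """
    if len(tiles) == 0:
        raise ValueError("need at least one tile")
    shapes = {t.shape for t in tiles}
    if len(shapes) != 1:
        raise ValueError(f"tiles have inconsistent shapes: {shapes}")
    median = np.median(np.stack([np.asarray(t, dtype=np.float64) for t in tiles]), axis=0)
    blurred = _gaussian(median, sigma)
    if mode == "ratio":
        floor = np.any(blurred <= _EPS)
        if floor:
            logger.warning("blurred median hit zero; applying epsilon floor")
        profile = median / np.maximum(blurred, _EPS)
    elif mode == "smooth":
        profile = blurred.copy()
    else:
        raise ValueError(f"unknown shading mode: {mode!r}")
    profile = np.maximum(profile, _EPS)
    profile /= profile.mean()
    return ShadingProfile(field=profile, channel=channel, anchor_cycle=anchor_cycle)


def interpolate_profile(
    first: ShadingProfile | np.ndarray,
    last: ShadingProfile | np.ndarray,
    cycle: int,
    n_cycles: int,
) -> np.ndarray:
    """Linear inter-cycle interpolation: first + (cycle−1)/(n_cycles−1)·(last−first)."""
    f = first.field if isinstance(first, ShadingProfile) else np.asarray(first)
    l = last.field if isinstance(last, ShadingProfile) else np.asarray(last)
    if f.shape != l.shape:
        raise ValueError("anchor profiles must share a shape")
    if not (1 <= cycle <= n_cycles):
        raise ValueError(f"cycle {cycle} outside 1..{n_cycles}")
    if n_cycles == 1:
        logger.warning("single-cycle experiment: interpolation degenerates to first anchor")
        return f.copy()
    t = (cycle - 1) / (n_cycles - 1)
    return f + t * (l - f)


def apply_shading(tile: np.ndarray, profile: np.ndarray) -> np.ndarray:
    """Divide a tile by the (strictly positive) interpolated shading field."""
    tile = np.asarray(tile, dtype=np.float64)
    profile = np.asarray(profile, dtype=np.float64)
    if tile.shape != profile.shape:
        raise ValueError(f"shape mismatch: tile {tile.shape} vs profile {profile.shape}")
    if np.any(profile <= 0):
        raise ValueError("shading profile must be strictly positive")
    return tile / profile


def compute_background(
    blank_tile: np.ndarray,
    channel: int = 0,
    position: int = 0,
    anchor_cycle: str = "first",
    sigma: float = 10.0,
) -> BackgroundModel:
    """Blur a (shading-corrected) blank-cycle tile into an autofluorescence field."""
    field = _gaussian(blank_tile, sigma)
    return BackgroundModel(
        field=np.clip(field, 0.0, None),
        channel=channel,
        position=position,
        anchor_cycle=anchor_cycle,
        blur_sigma=sigma,
    )


def subtract_background(
    tile: np.ndarray,
    first_bg: BackgroundModel | np.ndarray,
    last_bg: BackgroundModel | np.ndarray,
    cycle: int,
    n_cycles: int,
) -> np.ndarray:
    """Subtract the cycle-interpolated autofluorescence; output may go negative."""
    f = first_bg.field if isinstance(first_bg, BackgroundModel) else np.asarray(first_bg)
    l = last_bg.field if isinstance(last_bg, BackgroundModel) else np.asarray(last_bg)
    tile = np.asarray(tile, dtype=np.float64)
    if tile.shape != f.shape or tile.shape != l.shape:
        raise ValueError("tile and background fields must share a shape")
    bg = interpolate_profile(f, l, cycle, n_cycles)
    return tile - bg


def remove_negative_values(image: np.ndarray) -> np.ndarray:
    """Clip negatives to 0, then subtract the minimum positive value from every
    strictly positive pixel (zeros stay zero)."""
    out = np.asarray(image, dtype=np.float64).copy()
    out[out < 0] = 0.0
    positive = out > 0
    if not positive.any():
        logger.info("image all-zero after clipping; returned unchanged")
        return out
    m = out[positive].min()
    out[positive] -= m
    return out
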