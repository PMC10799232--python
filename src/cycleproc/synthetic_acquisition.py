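"""Synthetic cycle acquisition with known ground truth.

Generates a phantom tissue plane plus the physical nuisances the pipeline is
meant to undo — per-tile vignetting, autofluorescence drifting linearly across
cycles, per-cycle stage drift, Z defocus and shot/read noise — and writes the
result in the exact raw on-disk layout (per-cycle folders of single-plane
16-bit TIFFs, ``Experiment.json``, ``channelNames.txt``) together with a
ground-truth sidecar for downstream tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .experiment_model import (
    BLANK,
    ExperimentDescriptor,
    TileKey,
    cycle_folder_name,
    descriptor_to_json,
    mosaic_extent,
    nominal_origin,
    tile_filename,
)

__all__ = ["PhantomGroundTruth", "generate_phantom", "render_tile", "write_acquisition"]


@dataclass
class PhantomGroundTruth:
    """Everything needed to render tiles and to check every pipeline stage.

    Marker and autofluorescence fields live on the padded global plane
    (mosaic extent plus ``margin`` on every side); nuclei centres are stored
    in mosaic coordinates. Shading fields are tile-sized: vignetting is a
    property of the camera field of view, identical for every position.
    """

    descriptor: ExperimentDescriptor
    nuclei: np.ndarray  # (N, 3): cx, cy, radius in mosaic px
    marker_levels: dict  # (cycle, channel) -> (N,) per-nucleus amplitude
    marker_maps: dict  # (cycle, channel) -> 2D plane-sized field
    shading_fields: dict  # (channel, anchor) -> tile-sized positive field, mean 1
    af_fields: dict  # (channel, anchor) -> plane-sized nonnegative field
    drift_vectors: dict  # cycle -> (dx, dy) px, reference cycle = (0, 0)
    margin: int
    noise_gain: float  # Poisson scaling; 0 disables shot noise
    read_sigma: float  # Gaussian read noise in counts
    defocus_rate: float  # blur sigma px per Z plane away from focus
    z_focus: float  # 1-based focal plane index
    seed: int
    subpixel_drift: bool = False
    extras: dict = field(default_factory=dict)

    # -- anchors ---------------------------------------------------------
    @property
    def anchor_cycles(self) -> tuple[int, int]:
        return 1, self.descriptor.n_cycles

    def _interp(self, first: np.ndarray, last: np.ndarray, cycle: int) -> np.ndarray:
        n = self.descriptor.n_cycles
        if n == 1:
            return first
        t = (cycle - 1) / (n - 1)
        return first + t * (last - first)

    def shading_at(self, channel: int, cycle: int) -> np.ndarray:
        return self._interp(
            self.shading_fields[(channel, "first")],
            self.shading_fields[(channel, "last")],
            cycle,
        )

    def autofluorescence_at(self, channel: int, cycle: int) -> np.ndarray:
        return self._interp(
            self.af_fields[(channel, "first")],
            self.af_fields[(channel, "last")],
            cycle,
        )

    # -- geometry --------------------------------------------------------
    def tile_origin(self, position: int) -> tuple[int, int]:
        """Ground-truth top-left (x, y) of a tile in mosaic coordinates."""
        d = self.descriptor
        return nominal_origin(d.grid, d.tile_width, d.tile_height, position)

    def nuclei_in_tile(self, position: int) -> np.ndarray:
        """Nuclei whose centres fall inside the tile bounds, in tile coords."""
        x0, y0 = self.tile_origin(position)
        d = self.descriptor
        cx, cy = self.nuclei[:, 0], self.nuclei[:, 1]
        mask = (
            (cx >= x0)
            & (cx < x0 + d.tile_width)
            & (cy >= y0)
            & (cy < y0 + d.tile_height)
        )
        local = self.nuclei[mask].copy()
        local[:, 0] -= x0
        local[:, 1] -= y0
        return local

    def signal_plane(self, cycle: int, channel: int) -> np.ndarray:
        """Noise-free, shading-free marker + autofluorescence global plane."""
        return self.marker_maps[(cycle, channel)] + self.autofluorescence_at(channel, cycle)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], scale: float,
                  smooth_sigma: float, variation: float = 0.35) -> np.ndarray:
    """Nonnegative smooth random field with mean ~scale."""
    raw = rng.standard_normal(shape)
    raw = ndimage.gaussian_filter(raw, smooth_sigma, mode="reflect")
    std = raw.std()
    if std > 0:
        raw = raw / std
    fieldv = scale * (1.0 + variation * raw)
    return np.clip(fieldv, 0.0, None)


def _vignette(rng: np.random.Generator, height: int, width: int, strength: float) -> np.ndarray:
    """Radial vignette, strictly positive, mean-normalised to 1."""
    y, x = np.mgrid[0:height, 0:width].astype(np.float64)
    cy = (height - 1) / 2 + rng.uniform(-0.05, 0.05) * height
    cx = (width - 1) / 2 + rng.uniform(-0.05, 0.05) * width
    r2 = ((y - cy) / height) ** 2 + ((x - cx) / width) ** 2
    v = 1.0 - strength * r2 / r2.max()
    v = np.clip(v, 0.05, None)
    return v / v.mean()


def _soft_disk(shape: tuple[int, int], cx: float, cy: float, radius: float) -> np.ndarray:
    """Unit-amplitude disk with a ~1 px soft edge (keeps segmentation stable)."""
    h, w = shape
    y0 = max(int(cy - radius - 3), 0)
    y1 = min(int(cy + radius + 4), h)
    x0 = max(int(cx - radius - 3), 0)
    x1 = min(int(cx + radius + 4), w)
    out = np.zeros(shape, dtype=np.float64)
    if y1 <= y0 or x1 <= x0:
        return out
    yy, xx = np.mgrid[y0:y1, x0:x1]
    r = np.hypot(yy - cy, xx - cx)
    out[y0:y1, x0:x1] = np.clip(radius + 0.5 - r, 0.0, 1.0)
    return out


def generate_phantom(
    descriptor: ExperimentDescriptor,
    n_nuclei: int = 40,
    seed: int = 0,
    *,
    margin: int = 16,
    max_drift: int = 6,
    nuclear_amplitude: float = 3000.0,
    marker_amplitude: float = 2500.0,
    af_scale: tuple[float, float] = (300.0, 600.0),
    af_smooth_frac: float = 0.125,
    af_variation: float = 0.35,
    af_texture: float = 0.0,
    vignette_strength: tuple[float, float] = (0.35, 0.45),
    noise_gain: float = 1.0,
    read_sigma: float = 2.0,
    defocus_rate: float = 1.0,
    subpixel_drift: bool = False,
    min_radius: float = 4.0,
    max_radius: float = 8.0,
    min_separation: float | None = None,
    border_clearance: float | None = None,
) -> PhantomGroundTruth:
    """Build a reproducible phantom for ``descriptor``.

    Autofluorescence differs between the two anchor cycles (so inter-cycle
    interpolation is exercised) and drifts linearly in between, matching the
    correction model. Drift vectors are integer pixels unless
    ``subpixel_drift`` is set.
    """
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    d = descriptor
    rng = np.random.default_rng(seed)
    mosaic_w, mosaic_h = mosaic_extent(d.grid, d.tile_width, d.tile_height)
    plane_shape = (mosaic_h + 2 * margin, mosaic_w + 2 * margin)

    # nuclei: rejection-sampled to keep them apart and inside the mosaic
    if min_separation is None:
        min_separation = 2.5 * max_radius
    if border_clearance is None:
        # keep nuclei clear of the registration crop so none straddles the
        # final mosaic border
        border_clearance = max_radius + max_drift + 4
    clearance = max(border_clearance, max_radius + 2)
    nuclei = np.zeros((0, 3))
    pts: list[list[float]] = []
    attempts = 0
    while len(pts) < n_nuclei and attempts < 200 * max(n_nuclei, 1):
        attempts += 1
        r = rng.uniform(min_radius, max_radius)
        cx = rng.uniform(clearance, mosaic_w - clearance)
        cy = rng.uniform(clearance, mosaic_h - clearance)
        if all(np.hypot(cx - p[0], cy - p[1]) >= min_separation for p in pts):
            pts.append([cx, cy, r])
    if n_nuclei and len(pts) < n_nuclei:
        raise ValueError(
            f"could not place {n_nuclei} nuclei with separation {min_separation}; "
            f"placed {len(pts)}"
        )
    nuclei = np.asarray(pts, dtype=np.float64).reshape(-1, 3)

    # one soft-disk stamp per nucleus, reused for every channel map
    stamps = [
        _soft_disk(plane_shape, cx + margin, cy + margin, r) for cx, cy, r in nuclei
    ]

    marker_levels: dict = {}
    marker_maps: dict = {}
    for cyc in d.cycles:
        for ch in range(1, d.n_channels + 1):
            key = (cyc.index, ch)
            if cyc.is_blank(ch):
                marker_levels[key] = np.zeros(len(nuclei))
                marker_maps[key] = np.zeros(plane_shape)
                continue
            if ch == d.reference_channel:
                levels = np.full(len(nuclei), nuclear_amplitude)
            else:
                levels = marker_amplitude * rng.uniform(0.3, 1.0, size=len(nuclei))
            marker_levels[key] = levels
            plane = np.zeros(plane_shape)
            for lvl, stamp in zip(levels, stamps):
                plane += lvl * stamp
            marker_maps[key] = plane

    shading_fields: dict = {}
    af_fields: dict = {}
    for ch in range(1, d.n_channels + 1):
        shading_fields[(ch, "first")] = _vignette(
            rng, d.tile_height, d.tile_width, vignette_strength[0]
        )
        shading_fields[(ch, "last")] = _vignette(
            rng, d.tile_height, d.tile_width, vignette_strength[1]
        )
        smooth = max(min(plane_shape) * af_smooth_frac, 4.0)
        af_first = _smooth_field(rng, plane_shape, af_scale[0], smooth, af_variation)
        af_last = _smooth_field(rng, plane_shape, af_scale[1], smooth, af_variation)
        if af_texture > 0:
            # fine-scale tissue texture, identical in both anchors so it drifts
            # linearly like the rest of the autofluorescence; gives the
            # registration/stitching stages real content in overlap strips
            tex = _smooth_field(rng, plane_shape, af_texture, 1.2)
            af_first = af_first + tex
            af_last = af_last + tex
        af_fields[(ch, "first")] = af_first
        af_fields[(ch, "last")] = af_last

    drift_vectors: dict = {}
    for cyc in d.cycles:
        if cyc.index == d.reference_cycle:
            drift_vectors[cyc.index] = (0.0, 0.0)
        elif subpixel_drift:
            drift_vectors[cyc.index] = (
                float(rng.uniform(-max_drift, max_drift)),
                float(rng.uniform(-max_drift, max_drift)),
            )
        else:
            drift_vectors[cyc.index] = (
                float(rng.integers(-max_drift, max_drift + 1)),
                float(rng.integers(-max_drift, max_drift + 1)),
            )

    return PhantomGroundTruth(
        descriptor=d,
        nuclei=nuclei,
        marker_levels=marker_levels,
        marker_maps=marker_maps,
        shading_fields=shading_fields,
        af_fields=af_fields,
        drift_vectors=drift_vectors,
        margin=margin,
        noise_gain=noise_gain,
        read_sigma=read_sigma,
        defocus_rate=defocus_rate,
        z_focus=(d.n_z + 1) / 2.0,
        seed=seed,
        subpixel_drift=subpixel_drift,
    )


def render_tile(truth: PhantomGroundTruth, key: TileKey) -> np.ndarray:
    """Render one raw image plane as float64 counts in [0, 65535].

    Forward model: ``(marker + autofluorescence) × shading``, translated by the
    cycle's stage drift, blurred by a Gaussian growing with |z − z_focus|, then
    Poisson shot noise and Gaussian read noise.
    """
    d = truth.descriptor
    d.validate_key(key)
    plane = truth.signal_plane(key.cycle, key.channel)
    x0, y0 = truth.tile_origin(key.position)
    dx, dy = truth.drift_vectors[key.cycle]

    # stage drift moves the imaged content by (+dx, +dy) in tile coordinates
    ys = y0 + truth.margin - dy
    xs = x0 + truth.margin - dx
    if float(ys).is_integer() and float(xs).is_integer():
        ys_i, xs_i = int(ys), int(xs)
        tile = plane[ys_i : ys_i + d.tile_height, xs_i : xs_i + d.tile_width].copy()
    else:
        yy, xx = np.mgrid[0 : d.tile_height, 0 : d.tile_width].astype(np.float64)
        tile = ndimage.map_coordinates(plane, [yy + ys, xx + xs], order=1, mode="reflect")

    sigma_z = truth.defocus_rate * abs(key.z - truth.z_focus)
    if sigma_z > 0:
        tile = ndimage.gaussian_filter(tile, sigma_z, mode="reflect")

    tile = tile * truth.shading_at(key.channel, key.cycle)

    if truth.noise_gain > 0 or truth.read_sigma > 0:
        rng = np.random.default_rng(
            [truth.seed, key.cycle, key.position, key.z, key.channel]
        )
        if truth.noise_gain > 0:
            tile = truth.noise_gain * rng.poisson(
                np.clip(tile / truth.noise_gain, 0, None)
            ).astype(np.float64)
        if truth.read_sigma > 0:
            tile = tile + rng.normal(0.0, truth.read_sigma, size=tile.shape)

    return np.clip(tile, 0.0, 65535.0)


def write_acquisition(
    truth: PhantomGroundTruth,
    output_dir: str | Path,
    *,
    folder_pattern: str = "cyc{:02d}",
    save_ground_truth: bool = True,
) -> Path:
    """Write the raw layout: per-cycle folders of uint16 TIFFs + metadata files."""
    d = truth.descriptor
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    for cyc in d.cycles:
        folder = out / cycle_folder_name(cyc.index, folder_pattern)
        folder.mkdir(exist_ok=True)
        for key in d.tile_keys(cyc.index):
            tile = render_tile(truth, key)
            path = folder / tile_filename(key, d.name)
            tifffile.imwrite(path, np.round(tile).astype(np.uint16))

    (out / "Experiment.json").write_text(descriptor_to_json(d))
    lines = [rep for cyc in d.cycles for rep in cyc.reporters]
    (out / "channelNames.txt").write_text("\n".join(lines) + "\n")

    if save_ground_truth:
        save_ground_truth_sidecar(truth, out / "ground_truth.npz")
    return out


def save_ground_truth_sidecar(truth: PhantomGroundTruth, path: str | Path) -> None:
    """Persist arrays as a compressed archive plus a JSON manifest alongside."""
    arrays = {"nuclei": truth.nuclei}
    for (cyc, ch), arr in truth.marker_maps.items():
        arrays[f"marker_c{cyc}_ch{ch}"] = arr
        arrays[f"levels_c{cyc}_ch{ch}"] = truth.marker_levels[(cyc, ch)]
    for (ch, anchor), arr in truth.shading_fields.items():
        arrays[f"shading_ch{ch}_{anchor}"] = arr
    for (ch, anchor), arr in truth.af_fields.items():
        arrays[f"af_ch{ch}_{anchor}"] = arr
    np.savez_compressed(path, **arrays)
    manifest = {
        "seed": truth.seed,
        "margin": truth.margin,
        "noise_gain": truth.noise_gain,
        "read_sigma": truth.read_sigma,
        "defocus_rate": truth.defocus_rate,
        "z_focus": truth.z_focus,
        "subpixel_drift": truth.subpixel_drift,
        "drift_vectors": {str(c): list(v) for c, v in truth.drift_vectors.items()},
    }
    Path(path).with_suffix(".json").write_text(json.dumps(manifest, indent=2))


# Keep the public blank marker importable from here too; the simulator writes it.
_ = BLANK
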