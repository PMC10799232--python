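"""Stack restoration: PSF synthesis, Richardson–Lucy deconvolution, extended depth of field."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "PSFModel",
    "generate_psf",
    "richardson_lucy",
    "extended_depth_of_field",
    "focus_measure",
]


@dataclass(frozen=True)
class PSFModel:
    """3D point spread function kernel plus the optics that produced it.

    The kernel sums to 1 and is centrosymmetric in x and y.
    """

    kernel: np.ndarray
    wavelength: float  # emission, nm
    na: float
    voxel: tuple[float, float, float]  # (dx, dy, dz) in µm

    @property
    def is_delta(self) -> bool:
        peak = np.unravel_index(np.argmax(self.kernel), self.kernel.shape)
        return bool(np.isclose(self.kernel[peak], 1.0))


def generate_psf(
    wavelength: float,
    na: float,
    voxel: tuple[float, float, float],
    shape: tuple[int, int, int] = (7, 15, 15),
    refractive_index: float = 1.0,
) -> PSFModel:
    """Gaussian widefield PSF approximation.

    Lateral sigma 0.21·λ/NA and axial sigma 0.66·λ·n/NA², converted from µm to
    voxels. Shape is (z, y, x) with odd extents so the peak sits on the centre
    voxel.
    """
    if wavelength <= 0 or na <= 0 or any(v <= 0 for v in voxel):
        raise ValueError("wavelength, NA and voxel sizes must all be positive")
    if any(s < 1 or s % 2 == 0 for s in shape):
        raise ValueError("kernel shape must be odd and >= 1 in every axis")
    lam_um = wavelength * 1e-3
    sigma_xy_um = 0.21 * lam_um / na
    sigma_z_um = 0.66 * lam_um * refractive_index / na**2
    dx, dy, dz = voxel
    sig = np.array([sigma_z_um / dz, sigma_xy_um / dy, sigma_xy_um / dx])

    zz, yy, xx = [np.arange(s) - s // 2 for s in shape]
    z2 = (zz / sig[0]) ** 2
    y2 = (yy / sig[1]) ** 2
    x2 = (xx / sig[2]) ** 2
    kernel = np.exp(
        -0.5 * (z2[:, None, None] + y2[None, :, None] + x2[None, None, :])
    )
    kernel /= kernel.sum()
    return PSFModel(kernel=kernel, wavelength=wavelength, na=na, voxel=voxel)


def richardson_lucy(
    stack: np.ndarray, psf: PSFModel | np.ndarray, iterations: int = 10
) -> np.ndarray:
    """Richardson–Lucy deconvolution with reflective boundary handling.

    Multiplicative update: u ← u · ( (d / (u⊛k)) ⊛ k̄ ), with k̄ the flipped
    kernel. ``iterations=0`` returns the input unchanged; output is
    nonnegative whenever the input is.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if np.any(stack < 0):
        raise ValueError("richardson_lucy requires a nonnegative input stack")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    kernel = psf.kernel if isinstance(psf, PSFModel) else np.asarray(psf, dtype=np.float64)
    if kernel.ndim != stack.ndim:
        raise ValueError(f"kernel ndim {kernel.ndim} != stack ndim {stack.ndim}")
    if iterations == 0:
        return stack.copy()

    kernel_flip = kernel[tuple(slice(None, None, -1) for _ in range(kernel.ndim))]
    eps = 1e-12
    estimate = np.full_like(stack, max(stack.mean(), eps))
    for _ in range(iterations):
        blurred = ndimage.convolve(estimate, kernel, mode="reflect")
        ratio = stack / np.maximum(blurred, eps)
        estimate *= ndimage.convolve(ratio, kernel_flip, mode="reflect")
        np.clip(estimate, 0.0, None, out=estimate)
    return estimate


def focus_measure(image: np.ndarray, window: int = 9) -> np.ndarray:
    """Local focus score: variance of the Laplacian in a square window."""
    lap = ndimage.laplace(np.asarray(image, dtype=np.float64), mode="reflect")
    mean = ndimage.uniform_filter(lap, window, mode="reflect")
    mean_sq = ndimage.uniform_filter(lap * lap, window, mode="reflect")
    return np.clip(mean_sq - mean * mean, 0.0, None)


def extended_depth_of_field(
    stack: np.ndarray,
    window: int = 9,
    median_size: int = 5,
    mode: str = "hard",
    return_index_map: bool = False,
):
    """Project a Z-stack to a single in-focus 2D image.

    Every output pixel is taken from the slice maximising the local focus
    measure (``mode="hard"``) or focus-weight blended across slices
    (``mode="soft"``). The selected-slice index map is median filtered to
    suppress isolated slice switching.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("expected a non-empty (z, y, x) stack")
    n_z = stack.shape[0]
    if n_z == 1:
        result = stack[0].copy()
        idx = np.zeros(result.shape, dtype=np.intp)
        return (result, idx) if return_index_map else result

    scores = np.stack([focus_measure(stack[z], window) for z in range(n_z)])
    if mode == "hard":
        idx = np.argmax(scores, axis=0)
        if median_size > 1:
            idx = ndimage.median_filter(idx, size=median_size, mode="reflect")
        rows, cols = np.indices(idx.shape)
        result = stack[idx, rows, cols]
    elif mode == "soft":
        weights = scores + 1e-12
        weights /= weights.sum(axis=0, keepdims=True)
        result = (weights * stack).sum(axis=0)
        idx = np.argmax(scores, axis=0)
    else:
        raise ValueError(f"unknown EDF mode: {mode!r}")
    return (result, idx) if return_index_map else result
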