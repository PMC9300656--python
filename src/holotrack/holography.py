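"""Hologram normalization and Rayleigh-Sommerfeld back-propagation.

An inline hologram I_H(x, y, 0) records the interference of the unscattered
reference wave R with the object wave O scattered by the sample:
I_H = |R + O|^2.  With a separately recorded background |R|^2 the weak object
term is isolated as

    O(x, y, 0) ~= (I_H - |R|^2) / (2 |R|^2),

and the complex field anywhere in the sample volume is obtained by convolving
this contrast image with the Rayleigh-Sommerfeld propagator.  The convolution
is evaluated spectrally: the propagator's Fourier transform is the
angular-spectrum transfer function

    H(f; z) = exp(i z sqrt(k^2 - 4 pi^2 |f|^2)),   k = 2 pi n / lambda,

with evanescent components (k^2 < 4 pi^2 |f|^2) set to zero.  On the
propagating band |H| = 1, so per-plane spectral energy is conserved and
H(z1) H(z2) = H(z1 + z2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import ConfigError, OpticalConfig, ZGrid

__all__ = [
    "RawHologram",
    "BackgroundImage",
    "ContrastImage",
    "FieldVolume",
    "DataError",
    "ResourceError",
    "normalize_hologram",
    "propagation_kernel",
    "propagate",
    "reconstruct_volume",
]

logger = logging.getLogger(__name__)

#: Largest number of voxels reconstruct_volume will allocate by default.
DEFAULT_VOXEL_BUDGET = 400_000_000


class DataError(ValueError):
    """Input data violates a precondition (shape, sign, bit depth...)."""


class ResourceError(RuntimeError):
    """A requested reconstruction would exceed the configured memory budget."""


@dataclass(frozen=True)
class RawHologram:
    """A recorded single-plane hologram in camera counts."""

    pixels: np.ndarray
    optics: OpticalConfig

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise DataError(f"hologram must be 2D, got shape {px.shape}")
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise DataError(f"hologram must be at least 64x64, got {px.shape}")
        if np.any(px < 0):
            raise DataError("hologram contains negative pixel values")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BackgroundImage:
    """A recording of the unscattered reference intensity |R|^2."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise DataError(f"background must be 2D, got shape {px.shape}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ContrastImage:
    """Zero-centered object term O(x, y, 0) of a normalized hologram."""

    values: np.ndarray
    optics: OpticalConfig

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise DataError(f"contrast image must be 2D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise DataError("contrast image contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class FieldVolume:
    """Reconstructed complex field and its intensity over a z grid.

    ``field[iz]`` is the complex field at ``zgrid.z_values[iz]``; ``intensity``
    is exactly ``|field|**2``.  Axis order is (z, y, x).
    """

    field: np.ndarray
    zgrid: ZGrid
    optics: OpticalConfig
    intensity: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.field)
        if f.ndim != 3 or f.shape[0] != len(self.zgrid):
            raise DataError(
                f"field shape {f.shape} inconsistent with {len(self.zgrid)} z planes"
            )
        object.__setattr__(self, "field", f)
        object.__setattr__(self, "intensity", np.abs(f) ** 2)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.field.shape


def normalize_hologram(
    raw: RawHologram,
    background: BackgroundImage,
    clamp_floor: float = 1.0,
) -> ContrastImage:
    """Isolate the object term: (raw - background) / (2 * background).

    Background pixels <= 0 (dead pixels) are clamped to ``clamp_floor`` camera
    counts before the division, with a logged warning.  Raises
    :class:`DataError` on shape mismatch.
    """
    if raw.shape != background.shape:
        raise DataError(
            f"shape mismatch: hologram {raw.shape} vs background {background.shape}"
        )
    bg = np.asarray(background.pixels, dtype=float)
    n_bad = int(np.count_nonzero(bg <= 0))
    if n_bad:
        logger.warning(
            "background has %d non-positive pixels; clamping to %g counts",
            n_bad,
            clamp_floor,
        )
        bg = np.where(bg <= 0, clamp_floor, bg)
    if np.any(bg <= 0):  # clamp_floor itself non-positive
        raise DataError(
            f"background not positive after clamping ({n_bad} offending pixels)"
        )
    values = (np.asarray(raw.pixels, dtype=float) - bg) / (2.0 * bg)
    return ContrastImage(values=values, optics=raw.optics)


def _spatial_frequencies(
    shape: tuple[int, int], pixel_spacing: float
) -> tuple[np.ndarray, np.ndarray]:
    """FFT-ordered spatial frequencies (cycles/nm) for a (ny, nx) grid."""
    ny, nx = shape
    fy = np.fft.fftfreq(ny, d=pixel_spacing)[:, None]
    fx = np.fft.fftfreq(nx, d=pixel_spacing)[None, :]
    return fy, fx


def propagation_kernel(
    shape: tuple[int, int], z: float, optics: OpticalConfig
) -> np.ndarray:
    """Angular-spectrum transfer function of the RS propagator for offset z (nm).

    Returns the FFT-ordered complex grid ``exp(i z kz)`` with
    ``kz = sqrt(k^2 - 4 pi^2 (fx^2 + fy^2))`` on the propagating band and 0 on
    the evanescent band.  ``z = 0`` yields the identity on the propagating
    band; ``kernel(z) * kernel(-z) = 1`` there.
    """
    if not np.isfinite(z):
        raise ConfigError(f"z must be finite, got {z}")
    if z == 0:
        # exp(i*0*kz) = 1 for every component, evanescent included: exact identity
        return np.ones(shape, dtype=complex)
    k = optics.wavenumber
    fy, fx = _spatial_frequencies(shape, optics.pixel_spacing)
    kz_sq = k * k - (2.0 * np.pi) ** 2 * (fx * fx + fy * fy)
    propagating = kz_sq > 0
    kz = np.sqrt(np.where(propagating, kz_sq, 0.0))
    kernel = np.where(propagating, np.exp(1j * z * kz), 0.0 + 0.0j)
    return kernel


def _lowpass(shape: tuple[int, int], sigma: float, pixel_spacing: float) -> np.ndarray:
    """Gaussian low-pass in frequency space; sigma in cycles/nm."""
    fy, fx = _spatial_frequencies(shape, pixel_spacing)
    f_sq = fx * fx + fy * fy
    return np.exp(-f_sq / (2.0 * sigma * sigma))


def propagate(
    contrast: ContrastImage,
    z: float,
    lowpass_sigma: float | None = None,
    pad_factor: int = 1,
) -> np.ndarray:
    """Complex field at plane z (nm) by spectral RS propagation.

    If ``lowpass_sigma`` is given, the spectrum is multiplied by a Gaussian of
    that width (cycles/nm) before the inverse transform, suppressing
    high-spatial-frequency noise.  ``pad_factor > 1`` zero-pads the image by
    that factor to mitigate cyclic wrap-around near the edges; the returned
    plane is cropped back to the input shape.
    """
    values = contrast.values
    ny, nx = values.shape
    if pad_factor < 1 or int(pad_factor) != pad_factor:
        raise ConfigError(f"pad_factor must be a positive integer, got {pad_factor}")
    if pad_factor > 1:
        py, px = ny * (pad_factor - 1) // 2, nx * (pad_factor - 1) // 2
        values = np.pad(values, ((py, py), (px, px)))
    spectrum = np.fft.fft2(values)
    if lowpass_sigma is not None:
        spectrum *= _lowpass(values.shape, lowpass_sigma, contrast.optics.pixel_spacing)
    spectrum *= propagation_kernel(values.shape, z, contrast.optics)
    plane = np.fft.ifft2(spectrum)
    if pad_factor > 1:
        plane = plane[py : py + ny, px : px + nx]
    return plane


def reconstruct_volume(
    contrast: ContrastImage,
    zgrid: ZGrid,
    lowpass_sigma: float | None = None,
    pad_factor: int = 1,
    voxel_budget: int = DEFAULT_VOXEL_BUDGET,
) -> FieldVolume:
    """Back-propagate a contrast image to every plane of ``zgrid``.

    The result stacks the per-plane complex fields; ``intensity`` is their
    squared modulus.  A reconstruction whose voxel count exceeds
    ``voxel_budget`` raises :class:`ResourceError` before any allocation.
    """
    ny, nx = contrast.shape
    n_vox = ny * nx * len(zgrid)
    if n_vox > voxel_budget:
        raise ResourceError(
            f"reconstruction of {n_vox} voxels exceeds the budget of "
            f"{voxel_budget}; reduce the z grid or image size, or raise the budget"
        )
    values = contrast.values
    if pad_factor > 1:
        py, px = ny * (pad_factor - 1) // 2, nx * (pad_factor - 1) // 2
        values = np.pad(values, ((py, py), (px, px)))
    else:
        py = px = 0
    spectrum = np.fft.fft2(values)
    if lowpass_sigma is not None:
        spectrum = spectrum * _lowpass(
            values.shape, lowpass_sigma, contrast.optics.pixel_spacing
        )
    k = contrast.optics.wavenumber
    fy, fx = _spatial_frequencies(values.shape, contrast.optics.pixel_spacing)
    kz_sq = k * k - (2.0 * np.pi) ** 2 * (fx * fx + fy * fy)
    propagating = kz_sq > 0
    kz = np.sqrt(np.where(propagating, kz_sq, 0.0))
    spectrum_prop = np.where(propagating, spectrum, 0.0 + 0.0j)

    planes = np.empty((len(zgrid), ny, nx), dtype=complex)
    for iz, z in enumerate(zgrid.z_values):
        if z == 0:
            plane = np.fft.ifft2(spectrum)  # exact identity, evanescent included
        else:
            plane = np.fft.ifft2(spectrum_prop * np.exp(1j * z * kz))
        if pad_factor > 1:
            plane = plane[py : py + ny, px : px + nx]
        planes[iz] = plane
    return FieldVolume(field=planes, zgrid=zgrid, optics=contrast.optics)
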