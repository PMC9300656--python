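"""Optical configuration and axial reconstruction grid.

All physical quantities inside the package are carried in nanometres;
conversion to and from other units happens only at I/O boundaries.  The axial
coordinate z is measured from the hologram (focal) plane, positive toward the
sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["OpticalConfig", "ZGrid", "ConfigError"]


class ConfigError(ValueError):
    """Invalid optical or reconstruction configuration."""


@dataclass(frozen=True)
class OpticalConfig:
    """Imaging parameters needed for holographic reconstruction.

    Parameters
    ----------
    wavelength : float
        Illumination wavelength in vacuum, nm.
    refractive_index : float
        Refractive index of the sample medium (dimensionless, >= 1).
    pixel_spacing : float
        Effective pixel spacing in the sample plane, nm per pixel
        (camera pitch divided by magnification).
    """

    wavelength: float
    refractive_index: float
    pixel_spacing: float

    def __post_init__(self) -> None:
        if not self.wavelength > 0:
            raise ConfigError(f"wavelength must be > 0, got {self.wavelength}")
        if not self.refractive_index >= 1:
            raise ConfigError(
                f"refractive_index must be >= 1, got {self.refractive_index}"
            )
        if not self.pixel_spacing > 0:
            raise ConfigError(
                f"pixel_spacing must be > 0, got {self.pixel_spacing}"
            )

    @property
    def wavenumber(self) -> float:
        """Magnitude of the wavenumber in the medium, |k| = 2*pi*n/lambda (1/nm).

        Propagation direction is carried by the sign of z, not by the sign of
        k: z > 0 points from the hologram plane toward the sample.
        """
        return 2.0 * np.pi * self.refractive_index / self.wavelength


@dataclass(frozen=True)
class ZGrid:
    """Ordered axial positions (nm, relative to the hologram plane z = 0)."""

    z_values: np.ndarray
    spacing: float = field(init=False)

    def __post_init__(self) -> None:
        z = np.asarray(self.z_values, dtype=float)
        if z.ndim != 1 or z.size < 1:
            raise ConfigError("z_values must be a non-empty 1D array")
        if z.size > 1:
            dz = np.diff(z)
            if not (np.all(dz > 0) or np.all(dz < 0)):
                raise ConfigError("z_values must be strictly monotonic")
            spacing = float(abs(dz[0]))
        else:
            spacing = 0.0
        object.__setattr__(self, "z_values", z)
        object.__setattr__(self, "spacing", spacing)

    @classmethod
    def from_range(cls, z_min: float, z_max: float, z_step: float) -> "ZGrid":
        if z_step <= 0:
            raise ConfigError(f"z_step must be > 0, got {z_step}")
        n = int(np.floor((z_max - z_min) / z_step + 0.5)) + 1
        if n < 1:
            raise ConfigError("empty z range")
        return cls(z_min + z_step * np.arange(n))

    def __len__(self) -> int:
        return self.z_values.size

    def index_of_nearest(self, z: float) -> int:
        return int(np.argmin(np.abs(self.z_values - z)))
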