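"""Synthetic holograms with known ground truth.

Two generators are provided.  ``forward_hologram`` is a physics-based forward
model: each microbead is a point scatterer emitting a spherical wave
``exp(i k rho) / rho`` that interferes with a unit-amplitude plane reference
wave; the recorded image is the squared modulus of the sum, rescaled to camera
counts, optionally with Poisson shot noise.  ``render_lut_pattern`` /
``compose_scene`` instead build images from 1D radial diffraction profiles:
each profile is revolved about its center, placed on the pixel grid
zero-centered (so overlapping patterns sum), offset, rescaled and
Poisson-sampled.  The radial profiles used in tests are themselves extracted
from forward-model holograms, closing the generator/consumer loop.

Scenario builders reproduce the benchmark geometries: bead "crowding" rings,
axially displaced bead pairs, and lateral / axial step protocols.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd

from .config import OpticalConfig
from .holography import BackgroundImage, DataError, RawHologram

__all__ = [
    "SceneSpec",
    "NoiseModel",
    "StepSeries",
    "forward_hologram",
    "render_lut_pattern",
    "compose_scene",
    "build_scenarios",
    "DEFAULT_OPTICS",
]

logger = logging.getLogger(__name__)

#: Generator optics: 625-nm LED illumination, aqueous medium, 100-nm effective
#: pixel spacing (6.5-um camera pitch behind a 65x effective magnification).
DEFAULT_OPTICS = OpticalConfig(wavelength=625.0, refractive_index=1.33, pixel_spacing=100.0)

#: Scattering amplitude of one bead relative to the reference wave.
DEFAULT_BEAD_AMPLITUDE = 0.15


@dataclass(frozen=True)
class NoiseModel:
    """Camera model: rescale to counts, then optional Poisson shot noise."""

    kind: str = "poisson"  # "none" | "poisson"
    rescale_range: tuple[float, float] = (100.0, 60000.0)

    def __post_init__(self) -> None:
        if self.kind not in ("none", "poisson"):
            raise DataError(f"unknown noise kind {self.kind!r}")
        lo, hi = self.rescale_range
        if not hi > lo:
            raise DataError(f"rescale range max must exceed min, got {self.rescale_range}")


@dataclass(frozen=True)
class SceneSpec:
    """Bead positions (nm, hologram-plane origin at pixel (0, 0)) on a grid.

    ``seed`` is mandatory for any noisy render; noise-free renders are
    deterministic and seed-independent.
    """

    beads: tuple[tuple[float, float, float], ...]  # (x, y, z) nm
    shape: tuple[int, int] = (512, 512)
    seed: int | None = None
    bead_amplitude: float = DEFAULT_BEAD_AMPLITUDE

    def __post_init__(self) -> None:
        for bead in self.beads:
            if len(bead) != 3 or not all(np.isfinite(v) for v in bead):
                raise DataError(f"bead position must be a finite (x, y, z), got {bead}")


@dataclass(frozen=True)
class StepSeries:
    """A staircase displacement protocol along one axis."""

    axis: str  # "x" | "y" | "z"
    step_size: float  # nm
    n_steps: int
    frames_per_step: int = 1
    defocus: float = 10_000.0  # nm

    def __post_init__(self) -> None:
        if self.axis not in ("x", "y", "z"):
            raise DataError(f"axis must be x, y or z, got {self.axis!r}")
        if not self.step_size > 0:
            raise DataError("step_size must be > 0")


def _scatter_field(
    scene: SceneSpec, optics: OpticalConfig
) -> np.ndarray:
    """Complex object wave at the hologram plane from all beads."""
    ny, nx = scene.shape
    yy = np.arange(ny)[:, None] * optics.pixel_spacing
    xx = np.arange(nx)[None, :] * optics.pixel_spacing
    k = optics.wavenumber
    eps = optics.pixel_spacing / 2.0  # regularizes the in-focus (z ~ 0) case
    field = np.zeros((ny, nx), dtype=complex)
    for x0, y0, z0 in scene.beads:
        if not (0 <= x0 < nx * optics.pixel_spacing and 0 <= y0 < ny * optics.pixel_spacing):
            raise DataError(f"bead at ({x0}, {y0}) nm lies outside the grid")
        rho = np.sqrt((xx - x0) ** 2 + (yy - y0) ** 2 + z0**2 + eps**2)
        amp_norm = max(abs(z0), optics.wavelength)  # unit peak amplitude scale
        field += scene.bead_amplitude * amp_norm / rho * np.exp(1j * k * rho)
    return field


def _to_counts(
    intensity: np.ndarray,
    background_level: float,
    noise: NoiseModel,
    rng: np.random.Generator | None,
) -> tuple[np.ndarray, float]:
    """Affinely map relative intensity to camera counts; Poisson-sample if
    requested.  Returns (counts, background level in counts)."""
    lo, hi = noise.rescale_range
    i_min, i_max = float(intensity.min()), float(intensity.max())
    if i_max == i_min:  # uniform scene: park it mid-range
        gain, offset = 0.0, 0.5 * (lo + hi)
    else:
        gain = (hi - lo) / (i_max - i_min)
        offset = lo - gain * i_min
    counts = offset + gain * intensity
    bg_counts = offset + gain * background_level
    if noise.kind == "poisson":
        if rng is None:
            raise DataError("a seed is required for a noisy render")
        counts = rng.poisson(counts).astype(float)
    return counts, bg_counts


def forward_hologram(
    scene: SceneSpec,
    optics: OpticalConfig = DEFAULT_OPTICS,
    noise: NoiseModel = NoiseModel(kind="none"),
) -> tuple[RawHologram, BackgroundImage, pd.DataFrame]:
    """Render a scene of point-scatterer beads to a hologram in camera counts.

    Returns the hologram, the matching (noise-free) background recording, and
    a ground-truth table with columns bead_id, x_nm, y_nm, z_nm.  The camera
    is modeled as a pure gain (exposure) placing the brightest pixel at the
    top of the count range, so normalizing against the background recovers
    the physical contrast (I - 1)/2 exactly; the background emulates a
    time-averaged recording and is noise-free.
    """
    obj = _scatter_field(scene, optics)
    intensity = np.abs(1.0 + obj) ** 2
    rng = np.random.default_rng(scene.seed) if scene.seed is not None else None
    _, hi = noise.rescale_range
    gain = hi / float(intensity.max())
    counts = gain * intensity
    bg_counts = gain * 1.0
    if noise.kind == "poisson":
        if rng is None:
            raise DataError("a seed is required for a noisy render")
        counts = rng.poisson(counts).astype(float)
    holo = RawHologram(pixels=counts, optics=optics)
    background = BackgroundImage(pixels=np.full(scene.shape, bg_counts))
    truth = pd.DataFrame(
        {
            "bead_id": np.arange(len(scene.beads)),
            "x_nm": [b[0] for b in scene.beads],
            "y_nm": [b[1] for b in scene.beads],
            "z_nm": [b[2] for b in scene.beads],
        }
    )
    return holo, background, truth


def render_lut_pattern(
    profile: np.ndarray,
    center: tuple[float, float],
    grid: tuple[int, int],
    bin_width: float = 1.0,
) -> np.ndarray:
    """Revolve a 1D radial profile about ``center`` onto a pixel grid.

    ``profile[i]`` is the value at radius ``(i + 0.5) * bin_width`` pixels
    (the convention shared with :func:`holotrack.lut.radial_profile`); values
    in between are linearly interpolated and radii beyond the profile support
    map to 0.  Profiles are expected to be zero-centered so that overlapping
    patterns sum appropriately.
    """
    profile = np.asarray(profile, dtype=float)
    if not np.all(np.isfinite(profile)):
        raise DataError("profile must be finite")
    ny, nx = grid
    cx, cy = center
    if not (0 <= cx < nx and 0 <= cy < ny):
        raise DataError(f"center {center} outside grid {grid}")
    yy = np.arange(ny)[:, None] - cy
    xx = np.arange(nx)[None, :] - cx
    r = np.hypot(yy, xx)
    radii = (np.arange(profile.size) + 0.5) * bin_width
    return np.interp(r, radii, profile, left=profile[0] if profile.size else 0.0, right=0.0)


def compose_scene(
    patterns: list[np.ndarray],
    noise: NoiseModel = NoiseModel(kind="none"),
    seed: int | None = None,
    optics: OpticalConfig = DEFAULT_OPTICS,
    background_level: float = 1.0,
) -> tuple[RawHologram, BackgroundImage]:
    """Sum zero-centered patterns onto a flat offset and convert to counts.

    The summed image is offset by ``background_level``, affinely rescaled to
    the noise model's count range and, for Poisson noise, sampled with the
    given seed.  Values that would overflow the count range after noise are
    clipped with a logged count.
    """
    if not patterns:
        raise DataError("at least one pattern required")
    shape = patterns[0].shape
    for p in patterns[1:]:
        if p.shape != shape:
            raise DataError("patterns must share a grid shape")
    total = background_level + np.sum(patterns, axis=0)
    rng = np.random.default_rng(seed) if seed is not None else None
    counts, bg_counts = _to_counts(total, background_level, noise, rng if noise.kind != "none" else None)
    lo, hi = noise.rescale_range
    n_clip = int(np.count_nonzero((counts < 0) | (counts > 2 * hi)))
    if n_clip:
        logger.warning("clipping %d out-of-range pixels", n_clip)
        counts = np.clip(counts, 0, 2 * hi)
    return (
        RawHologram(pixels=counts, optics=optics),
        BackgroundImage(pixels=np.full(shape, bg_counts)),
    )


def _center_of(shape: tuple[int, int], pixel: float) -> tuple[float, float]:
    ny, nx = shape
    return (nx // 2) * pixel, (ny // 2) * pixel


def build_scenarios(
    kind: str,
    *,
    optics: OpticalConfig = DEFAULT_OPTICS,
    shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    noise: NoiseModel = NoiseModel(kind="poisson"),
    # crowding
    n_crowders: int = 8,
    r_sep: float = 8_000.0,
    defocus: float = 10_000.0,
    # axial crowding
    delta_z: float = 2_000.0,
    lateral_offset: float = 0.0,
    # steps
    steps: StepSeries | None = None,
    bead_amplitude: float = DEFAULT_BEAD_AMPLITUDE,
) -> tuple[list[RawHologram], BackgroundImage, pd.DataFrame]:
    """Build a benchmark frame sequence with its per-frame ground truth.

    kinds
    -----
    ``crowding``
        One frame: a central bead at ``defocus`` surrounded by ``n_crowders``
        beads (0-8) on a ring of radius ``r_sep`` in the same plane.
    ``axial_crowding``
        One frame: bead 1 at the center at ``defocus``; bead 2 displaced by
        ``delta_z`` axially and ``lateral_offset`` along x.
    ``xy_steps`` / ``z_steps``
        A staircase protocol described by ``steps``: the bead advances by
        ``step_size`` after every ``frames_per_step`` frames.

    Returns (frames, background, truth) with truth columns
    frame, bead_id, x_nm, y_nm, z_nm.  Deterministic given ``seed``.
    """
    cx, cy = _center_of(shape, optics.pixel_spacing)
    frames: list[RawHologram] = []
    rows: list[dict] = []
    background: BackgroundImage

    def render(beads, frame_seed, frame_idx):
        scene = SceneSpec(
            beads=tuple(beads), shape=shape, seed=frame_seed, bead_amplitude=bead_amplitude
        )
        holo, bg, _ = forward_hologram(scene, optics, noise)
        frames.append(holo)
        for bid, (x, y, z) in enumerate(beads):
            rows.append(
                {"frame": frame_idx, "bead_id": bid, "x_nm": x, "y_nm": y, "z_nm": z}
            )
        return bg

    if kind == "crowding":
        if not 0 <= n_crowders <= 8:
            raise DataError("n_crowders must be 0..8")
        beads = [(cx, cy, defocus)]
        for i in range(n_crowders):
            theta = 2.0 * np.pi * i / max(n_crowders, 1)
            beads.append(
                (cx + r_sep * np.cos(theta), cy + r_sep * np.sin(theta), defocus)
            )
        background = render(beads, seed, 0)
    elif kind == "axial_crowding":
        beads = [
            (cx, cy, defocus),
            (cx + lateral_offset, cy, defocus + delta_z),
        ]
        background = render(beads, seed, 0)
    elif kind in ("xy_steps", "z_steps"):
        if steps is None:
            steps = StepSeries(
                axis="x" if kind == "xy_steps" else "z", step_size=19.5, n_steps=10
            )
        expected_axis = "z" if kind == "z_steps" else steps.axis
        if steps.axis != expected_axis:
            raise DataError(f"{kind} requires axis {expected_axis!r}")
        frame_idx = 0
        for istep in range(steps.n_steps):
            d = istep * steps.step_size
            x, y, z = cx, cy, steps.defocus
            if steps.axis == "x":
                x += d
            elif steps.axis == "y":
                y += d
            else:
                z += d
            for _ in range(steps.frames_per_step):
                background = render([(x, y, z)], seed + frame_idx, frame_idx)
                frame_idx += 1
    else:
        raise DataError(f"unknown scenario kind {kind!r}")
    truth = pd.DataFrame(rows)
    return frames, background, truth
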