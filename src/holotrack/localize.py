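"""3D object localization in a reconstructed intensity volume.

The pipeline: a maximum-intensity projection along z plus 2D peak finding
yields in-plane candidates; a 3x3x3 Sobel-like gradient filter applied to a
narrow column around each candidate gives a coarse axial index; and an
iterative "parabolic masking" refinement of a small cuboid around the coarse
position yields the sub-voxel center.  Parabolic masking multiplies the
intensity cuboid by a nonnegative paraboloid centered on the current estimate,
moves the estimate to the intensity-weighted centroid of the product, and
repeats until the shift falls below a tolerance.

Array axis order throughout is (z, y, x); positions are reported with x along
columns and y along rows, in nm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.signal import convolve
from skimage.feature import peak_local_max

from .config import ZGrid
from .holography import (
    BackgroundImage,
    DataError,
    FieldVolume,
    RawHologram,
    normalize_hologram,
    reconstruct_volume,
)

__all__ = [
    "DetectionParams",
    "Candidate",
    "Position3D",
    "FrameResult",
    "GRADIENT_KERNEL",
    "project_max_xy",
    "find_candidates_2d",
    "gradient_z",
    "initial_z",
    "parabolic_mask_refine",
    "localize_frame",
]

logger = logging.getLogger(__name__)

# Fixed 3x3x3 Sobel-like kernel for the axial gradient, indexed (z, y, x).
# The leading z slab is the smoothing stencil, the trailing slab its negative.
_S1 = np.array([[1.0, 2.0, 1.0], [2.0, 4.0, 2.0], [1.0, 2.0, 1.0]])
GRADIENT_KERNEL = np.stack([_S1, np.zeros_like(_S1), -_S1])


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters of the localization pipeline.

    ``intensity_threshold`` is a fraction of the projection's global maximum.
    ``column_width`` and the x, y extents of ``cuboid_size`` must be odd so the
    candidate sits on the central voxel.  ``mask_tolerance`` is the centroid
    shift (in voxels) below which parabolic masking stops.
    """

    intensity_threshold: float = 0.3
    min_separation: int | None = None  # defaults to column_width
    edge_margin: int | None = None  # defaults to column_width
    column_width: int = 15
    cuboid_size: tuple[int, int, int] = (15, 15, 25)  # (x, y, z) voxels
    mask_tolerance: float = 0.01
    max_iterations: int = 100
    #: a frame is considered empty unless the projection's global maximum
    #: exceeds this multiple of its median (the shot-noise floor)
    min_peak_snr: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.intensity_threshold <= 1:
            raise DataError(
                f"intensity_threshold must be in (0, 1], got {self.intensity_threshold}"
            )
        if self.column_width % 2 != 1:
            raise DataError(f"column_width must be odd, got {self.column_width}")
        cx, cy, _ = self.cuboid_size
        if cx % 2 != 1 or cy % 2 != 1:
            raise DataError(
                f"cuboid x, y extents must be odd, got {self.cuboid_size}"
            )
        if self.max_iterations < 1:
            raise DataError("max_iterations must be >= 1")

    @property
    def sep(self) -> int:
        return self.column_width if self.min_separation is None else self.min_separation

    @property
    def margin(self) -> int:
        return self.column_width if self.edge_margin is None else self.edge_margin


@dataclass
class Candidate:
    """A detected object candidate at integer grid indices."""

    x: int
    y: int
    peak_intensity: float
    z_index: int | None = None
    excluded: bool = False
    reason: str | None = None
    flags: list[str] = dataclass_field(default_factory=list)

    def exclude(self, reason: str) -> None:
        self.excluded = True
        self.reason = reason


@dataclass(frozen=True)
class Position3D:
    """A refined object position in physical units (nm)."""

    x: float
    y: float
    z: float
    frame_index: int = 0
    candidate_id: int = 0
    n_iterations: int = 0
    converged: bool = True
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class FrameResult:
    """Localization output for one frame: refined positions plus every
    candidate that was excluded, with its machine-readable reason."""

    positions: list[Position3D]
    excluded: list[Candidate]


def project_max_xy(volume: FieldVolume) -> np.ndarray:
    """Maximum-intensity projection of the volume along z."""
    return volume.intensity.max(axis=0)


def find_candidates_2d(projection: np.ndarray, params: DetectionParams) -> list[Candidate]:
    """Local maxima of a projection above ``threshold * global max``.

    Candidates are ranked by intensity.  Of a pair closer than
    ``min_separation`` pixels the brighter is kept (flagged "near-neighbor")
    and the dimmer excluded with reason "proximity"; candidates within
    ``edge_margin`` of the image border are excluded with reason "edge".
    Excluded candidates are returned alongside the rest, never dropped.
    """
    projection = np.asarray(projection, dtype=float)
    global_max = projection.max()
    if global_max <= 0:
        return []
    noise_floor = float(np.median(projection))
    if noise_floor > 0 and global_max < params.min_peak_snr * noise_floor:
        logger.info(
            "projection maximum %.3g below %gx the noise floor %.3g: empty frame",
            global_max, params.min_peak_snr, noise_floor,
        )
        return []
    thr = params.intensity_threshold * global_max
    peaks = peak_local_max(projection, min_distance=1, threshold_abs=thr)
    if peaks.size == 0:
        logger.info("no candidates above threshold %.3g", thr)
        return []
    intensities = projection[peaks[:, 0], peaks[:, 1]]
    # deterministic ranking: intensity descending, then lowest (row, col) index
    order = np.lexsort((peaks[:, 1], peaks[:, 0], -intensities))
    candidates = [
        Candidate(x=int(peaks[i, 1]), y=int(peaks[i, 0]), peak_intensity=float(intensities[i]))
        for i in order
    ]
    # proximity: brighter of a close pair is kept but flagged
    for i, ci in enumerate(candidates):
        if ci.excluded:
            continue
        for cj in candidates[i + 1 :]:
            if cj.excluded:
                continue
            if np.hypot(ci.x - cj.x, ci.y - cj.y) < params.sep:
                cj.exclude("proximity")
                if "near-neighbor" not in ci.flags:
                    ci.flags.append("near-neighbor")
    ny, nx = projection.shape
    m = params.margin
    for c in candidates:
        if not c.excluded and (
            c.x < m or c.y < m or c.x >= nx - m or c.y >= ny - m
        ):
            c.exclude("edge")
    return candidates


def gradient_z(column: np.ndarray) -> np.ndarray:
    """Valid-region 3D convolution of an intensity column with the gradient
    kernel.  Output shape is the input shrunk by 2 on every axis; the valid
    region starts at offset (1, 1, 1) of the input.
    """
    column = np.asarray(column, dtype=float)
    if column.ndim != 3 or any(s < 3 for s in column.shape):
        raise DataError(f"column must be at least 3x3x3, got shape {column.shape}")
    return convolve(column, GRADIENT_KERNEL, mode="valid", method="direct")


def initial_z(gradient_column: np.ndarray, candidate: Candidate | None = None) -> int:
    """Coarse axial index from the central (y, x) line of a gradient column.

    The axial Sobel response to a focused object is bipolar: a positive and a
    negative lobe bracketing the intensity peak.  When both lobes are present
    (the negative extremum reaches at least a quarter of the positive one in
    magnitude) the coarse index is the rounded midpoint of the two opposite
    extrema — the zero crossing of the derivative response, i.e. the
    intensity peak.  For a unipolar line the index of its maximum is used.
    Ties break to the lowest z (``argmax`` convention).  An all-zero line
    marks the candidate excluded with reason "no axial signal".
    """
    g = np.asarray(gradient_column, dtype=float)
    cy, cx = g.shape[1] // 2, g.shape[2] // 2
    line = g[:, cy, cx]
    if np.all(line == 0):
        if candidate is not None:
            candidate.exclude("no axial signal")
        raise DataError("central gradient line is identically zero")
    i_max = int(np.argmax(line))  # first (lowest-z) maximum on ties
    i_min = int(np.argmin(line))
    if line[i_min] < 0 and -line[i_min] >= 0.25 * line[i_max] and line[i_max] > 0:
        return int(round(0.5 * (i_max + i_min)))
    return i_max


def parabolic_mask_refine(
    cuboid: np.ndarray,
    params: DetectionParams,
) -> tuple[np.ndarray, int, bool]:
    """Sub-voxel center of an intensity cuboid by iterative parabolic masking.

    The paraboloid weight at voxel offset u from the cuboid center, given the
    current center estimate c, is ``max(0, 1 - sum_i ((u_i - c_i)/a_i)^2)``
    with semi-axes a_i equal to the cuboid half-extent along each axis.  Each
    iteration moves c to the weighted intensity centroid; iteration stops when
    the Euclidean shift drops below ``mask_tolerance`` voxels or after
    ``max_iterations``.

    Returns ``(offset, n_iterations, converged)`` with ``offset`` the (z, y, x)
    displacement from the cuboid's geometric center, in voxels.  A
    non-positive weighted mass raises :class:`DataError` ("degenerate mass").
    """
    cuboid = np.asarray(cuboid, dtype=float)
    if cuboid.ndim != 3:
        raise DataError("cuboid must be 3D")
    half = np.array([(s - 1) / 2 for s in cuboid.shape], dtype=float)
    semi_axes = np.maximum(half, 1.0)
    grids = np.meshgrid(
        *(np.arange(s, dtype=float) - h for s, h in zip(cuboid.shape, half)),
        indexing="ij",
    )
    c = np.zeros(3)
    converged = False
    n_iter = 0
    for n_iter in range(1, params.max_iterations + 1):
        q = sum(((g - ci) / a) ** 2 for g, ci, a in zip(grids, c, semi_axes))
        w = np.maximum(0.0, 1.0 - q) * cuboid
        mass = w.sum()
        if mass <= 0:
            raise DataError("degenerate mass: non-positive paraboloid-weighted sum")
        new_c = np.array([float((w * g).sum() / mass) for g in grids])
        shift = float(np.linalg.norm(new_c - c))
        c = new_c
        if shift < params.mask_tolerance:
            converged = True
            break
    return c, n_iter, converged


def _extract_padded(
    volume: np.ndarray, center: tuple[int, int, int], size_zyx: tuple[int, int, int]
) -> tuple[np.ndarray, bool]:
    """Extract a (z, y, x) box centered on ``center``; parts outside the
    volume are zero-filled.  Returns (box, clipped_flag)."""
    out = np.zeros(size_zyx, dtype=float)
    clipped = False
    src, dst = [], []
    for ax in range(3):
        s = size_zyx[ax]
        h_lo = (s - 1) // 2
        lo = center[ax] - h_lo
        hi = lo + s
        lo_c, hi_c = max(lo, 0), min(hi, volume.shape[ax])
        if lo_c != lo or hi_c != hi:
            clipped = True
        src.append(slice(lo_c, hi_c))
        dst.append(slice(lo_c - lo, hi_c - lo))
    out[tuple(dst)] = volume[tuple(src)]
    return out, clipped


def _extract_column(
    volume: np.ndarray, y: int, x: int, width: int
) -> tuple[np.ndarray, bool]:
    """Full-depth (z) column of ``width`` x ``width`` pixels around (y, x),
    zero-padded where it overhangs the volume.  Returns (column, clipped)."""
    nz, ny, nx = volume.shape
    hw = (width - 1) // 2
    out = np.zeros((nz, width, width), dtype=float)
    y_lo, y_hi = y - hw, y + hw + 1
    x_lo, x_hi = x - hw, x + hw + 1
    yc_lo, yc_hi = max(y_lo, 0), min(y_hi, ny)
    xc_lo, xc_hi = max(x_lo, 0), min(x_hi, nx)
    clipped = (yc_lo, yc_hi, xc_lo, xc_hi) != (y_lo, y_hi, x_lo, x_hi)
    out[:, yc_lo - y_lo : yc_hi - y_lo, xc_lo - x_lo : xc_hi - x_lo] = volume[
        :, yc_lo:yc_hi, xc_lo:xc_hi
    ]
    return out, clipped


def localize_frame(
    hologram: RawHologram,
    background: BackgroundImage,
    zgrid: ZGrid,
    params: DetectionParams | None = None,
    lowpass_sigma: float | None = None,
    pad_factor: int = 1,
    frame_index: int = 0,
    volume: FieldVolume | None = None,
) -> FrameResult:
    """Full single-frame pipeline: normalize, back-propagate, detect, refine.

    Physical coordinates are ``(index + sub-voxel offset) * spacing``; the z
    coordinate is read off the reconstruction grid.  One failing candidate is
    flagged and reported in ``excluded``; it never aborts the frame.
    """
    if params is None:
        params = DetectionParams()
    if volume is None:
        contrast = normalize_hologram(hologram, background)
        volume = reconstruct_volume(
            contrast, zgrid, lowpass_sigma=lowpass_sigma, pad_factor=pad_factor
        )
    intensity = volume.intensity
    projection = intensity.max(axis=0)
    candidates = find_candidates_2d(projection, params)
    positions: list[Position3D] = []
    excluded: list[Candidate] = []
    px = hologram.optics.pixel_spacing
    w = params.column_width
    sx, sy, sz = params.cuboid_size
    for cid, cand in enumerate(candidates):
        if cand.excluded:
            excluded.append(cand)
            continue
        try:
            column, col_clipped = _extract_column(intensity, cand.y, cand.x, w)
            grad = gradient_z(column)
            zi = initial_z(grad, cand) + 1  # valid-region offset back to volume index
            cand.z_index = zi
            cuboid, cub_clipped = _extract_padded(
                intensity, (zi, cand.y, cand.x), (sz, sy, sx)
            )
            offset, n_iter, converged = parabolic_mask_refine(cuboid, params)
        except DataError as err:
            if not cand.excluded:
                cand.exclude(str(err))
            excluded.append(cand)
            continue
        flags = list(cand.flags)
        if col_clipped or cub_clipped:
            flags.append("clipped")
        positions.append(
            Position3D(
                x=(cand.x + offset[2]) * px,
                y=(cand.y + offset[1]) * px,
                z=zgrid.z_values[zi] + offset[0] * zgrid.spacing,
                frame_index=frame_index,
                candidate_id=cid,
                n_iterations=n_iter,
                converged=converged,
                flags=tuple(flags),
            )
        )
    return FrameResult(positions=positions, excluded=excluded)
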